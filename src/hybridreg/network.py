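"""Displacement-prediction network: dilated U-Net over a (moving, reference) pair.

The model concatenates the two z-scored input volumes channel-wise, runs an
encoder of repeated (dilated) convolutions and 2x max pooling, then a decoder
of nearest upsampling with skip-connection concatenation, and projects to one
displacement channel per spatial axis. The final projection is initialized
near zero so the untrained model predicts an (almost) identity transform,
which stabilizes early optimization.

The network is dimension-generic (2-D or 3-D) and runs on the package's own
numpy autodiff engine.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import autodiff as ad
from .grids import DisplacementField, Volume

__all__ = ["NetworkSpec", "RegistrationModel", "build_network", "predict_field"]


@dataclass
class NetworkSpec:
    """Architecture hyperparameters.

    levels: encoder depth; the grid is halved ``levels - 1`` times, so every
        input axis must be divisible by ``2**(levels-1)``.
    base_channels: channel width at the finest level; doubles per level.
    dilation_rates: one convolution per rate inside each block; rates > 1
        widen the receptive field at constant parameter count.
    dropout_p: dropout probability after each block (training mode only).
    dims: 2 or 3.
    """

    levels: int = 4
    base_channels: int = 16
    dilation_rates: List[int] = field(default_factory=lambda: [1, 2])
    dropout_p: float = 0.2
    dims: int = 2
    normalization: str = "instance"
    output_scale: float = 10.0

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if not self.dilation_rates:
            raise ValueError("dilation_rates must be nonempty")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.normalization not in ("instance", "none"):
            raise ValueError("normalization must be 'instance' or 'none'")
        if self.output_scale <= 0:
            raise ValueError("output_scale must be > 0")

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)


def _he_init(rng: np.random.Generator, cout: int, cin: int, k: int, d: int) -> np.ndarray:
    fan_in = cin * k**d
    sd = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal((cout, cin) + (k,) * d) * sd).astype(np.float32)


class RegistrationModel:
    """Parameter store + forward pass; graphs are rebuilt per call."""

    KERNEL = 3

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        d = spec.dims
        enc = [spec.base_channels * 2**i for i in range(spec.levels)]
        self.enc_channels = enc
        self.params: dict[str, ad.Tensor] = {}

        def add_conv(name, cin, cout, near_zero=False):
            if near_zero:
                # the head output is multiplied by output_scale, letting the
                # weights stay at natural magnitudes while displacements span
                # many voxels; init keeps the untrained model near-identity
                # but large enough that gradient reaches upstream layers
                w = (rng.standard_normal((cout, cin) + (self.KERNEL,) * d) * 1e-4).astype(
                    np.float32
                )
            else:
                w = _he_init(rng, cout, cin, self.KERNEL, d)
            self.params[f"{name}.w"] = ad.Tensor(w, requires_grad=True)
            self.params[f"{name}.b"] = ad.Tensor(
                np.zeros(cout, dtype=np.float32), requires_grad=True
            )
            if spec.normalization == "instance" and not near_zero:
                self.params[f"{name}.g"] = ad.Tensor(
                    np.ones(cout, dtype=np.float32), requires_grad=True
                )
                self.params[f"{name}.gb"] = ad.Tensor(
                    np.zeros(cout, dtype=np.float32), requires_grad=True
                )

        cin = 2
        for lv, cout in enumerate(enc):
            for j, _rate in enumerate(spec.dilation_rates):
                add_conv(f"enc{lv}.conv{j}", cin, cout)
                cin = cout
        for lv in range(spec.levels - 2, -1, -1):
            # upsampled features carry enc[lv+1] channels; skip adds enc[lv]
            cin = enc[lv + 1] + enc[lv]
            cout = enc[lv]
            for j, _rate in enumerate(spec.dilation_rates):
                add_conv(f"dec{lv}.conv{j}", cin, cout)
                cin = cout
        add_conv("head", enc[0], d, near_zero=True)

    # ------------------------------------------------------------------

    def parameters(self):
        return list(self.params.values())

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def check_shape(self, shape):
        div = self.spec.divisor
        for ax, n in enumerate(shape):
            if n % div:
                raise ValueError(
                    f"input axis {ax} has size {n}, not divisible by "
                    f"2**(levels-1) = {div}"
                )

    def _block(self, x, name, training, rng, dropout=False):
        for j, rate in enumerate(self.spec.dilation_rates):
            x = ad.convnd(
                x,
                self.params[f"{name}.conv{j}.w"],
                self.params[f"{name}.conv{j}.b"],
                dilation=rate,
            )
            if self.spec.normalization == "instance":
                x = ad.instance_norm(
                    x, self.params[f"{name}.conv{j}.g"], self.params[f"{name}.conv{j}.gb"]
                )
            x = ad.leaky_relu(x)
        if dropout and training and self.spec.dropout_p > 0:
            x = ad.dropout(x, self.spec.dropout_p, rng, training)
        return x

    def forward(
        self,
        moving: np.ndarray,
        reference: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> ad.Tensor:
        """Return the displacement field as a Tensor of shape (*S, dims)."""
        if moving.shape != reference.shape:
            raise ValueError(
                f"moving/reference shape mismatch: {moving.shape} vs {reference.shape}"
            )
        if moving.ndim != self.spec.dims:
            raise ValueError(f"expected {self.spec.dims}-D inputs, got {moving.ndim}-D")
        self.check_shape(moving.shape)
        if training and rng is None:
            rng = np.random.default_rng(0)
        x = ad.Tensor(
            np.stack([moving, reference]).astype(np.float32), requires_grad=False
        )
        # dropout units sit in the deepest (coarsest) blocks only: at batch
        # size 1, masking fine-scale features is too noisy to train through
        deep = max(self.spec.levels - 2, 1)
        skips = []
        for lv in range(self.spec.levels):
            x = self._block(x, f"enc{lv}", training, rng, dropout=lv >= deep)
            if lv < self.spec.levels - 1:
                skips.append(x)
                x = ad.maxpool2(x)
        for lv in range(self.spec.levels - 2, -1, -1):
            x = ad.upsample2(x)
            x = ad.concat(x, skips[lv])
            x = self._block(x, f"dec{lv}", training, rng, dropout=lv >= deep)
        head = ad.convnd(x, self.params["head.w"], self.params["head.b"])
        # (d, *S) -> (*S, d)
        d = self.spec.dims
        out = head * self.spec.output_scale
        perm = tuple(range(1, 1 + d)) + (0,)
        out_t = ad.Tensor(np.transpose(out.data, perm), (out,))
        inv = (d,) + tuple(range(d))
        out_t._backward = lambda g: out._accum(np.transpose(g, inv))
        return out_t

    # -- persistence ----------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict):
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float32)

    def save(self, path):
        import dataclasses
        import json

        meta = dict(dataclasses.asdict(self.spec), seed=self.seed)
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        np.savez(path, __spec__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "RegistrationModel":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__spec__"]))
            seed = meta.pop("seed")
            model = cls(NetworkSpec(**meta), seed)
            state = {
                k.replace("__", "."): z[k] for k in z.files if k != "__spec__"
            }
        model.load_state_dict(state)
        return model


def build_network(spec: NetworkSpec, seed: int) -> RegistrationModel:
    """Construct a seed-deterministic registration model."""
    return RegistrationModel(spec, seed)


def predict_field(model: RegistrationModel, moving: Volume, reference: Volume) -> DisplacementField:
    """Run the model in evaluation mode on a preprocessed image pair."""
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share a grid")
    out = model.forward(
        np.asarray(moving.values, dtype=np.float32),
        np.asarray(reference.values, dtype=np.float32),
        training=False,
    )
    return DisplacementField(out.data.astype(float), moving.spacing)
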
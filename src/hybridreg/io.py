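"""File formats: NIfTI-1 volumes/masks/fields, CSV landmarks, YAML run config.

Volumes and masks are 3-D NIfTI-1 with spacing in the header and the
intensity domain recorded in the ``descrip`` field. Displacement fields are
4-D NIfTI with the last axis holding the three vector components in voxel
units. Landmarks are CSV with columns ``name,x_mm,y_mm,z_mm`` and optional
gold-vector columns ``gx_mm,gy_mm,gz_mm``.
"""
from __future__ import annotations

import csv
import dataclasses
import typing
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import HU, DisplacementField, LabelMask, LandmarkSet, Volume
from .network import NetworkSpec
from .phantoms import PhantomSpec
from .simulator import SimulatorConfig
from .training import TrainConfig

__all__ = [
    "FormatError",
    "ConfigError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
    "read_landmarks",
    "write_landmarks",
    "RunConfig",
    "SplitConfig",
    "EvalConfig",
    "load_config",
    "save_config",
    "build_dataclass",
    "config_to_dict",
]


class FormatError(ValueError):
    """Malformed or unsupported on-disk data."""


class ConfigError(ValueError):
    """Invalid run-configuration document."""


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _spacing_from(img) -> tuple:
    # NIfTI-1 stores the affine as float32; snap to 6 decimals so that
    # human-scale spacings (e.g. 0.36 mm) round-trip exactly
    return tuple(round(float(np.linalg.norm(img.affine[:3, k])), 6) for k in range(3))


def _load(path) -> nib.Nifti1Image:
    try:
        return nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot read NIfTI ({exc})") from None


def read_volume(path) -> Volume:
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D scalar volume, got {data.ndim}-D")
    spacing = _spacing_from(img)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    descrip = bytes(img.header["descrip"]).decode(errors="ignore").strip("\x00")
    domain = "zscored" if "zscored" in descrip else HU
    return Volume(data.astype(float), spacing, origin, domain)


def write_volume(v: Volume, path):
    if v.ndim != 3:
        raise FormatError("only 3-D volumes are written to NIfTI; 2-D grids are in-memory")
    img = nib.Nifti1Image(np.asarray(v.values, dtype=np.float32), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    img.header["descrip"] = f"hybridreg:{v.intensity_domain}".encode()
    nib.save(img, str(path))


def read_mask(path) -> LabelMask:
    v = read_volume(path)
    vals = np.rint(v.values).astype(np.uint8)
    if not np.isin(vals, (0, 1)).all():
        raise FormatError(f"{path}: mask values must be 0/1")
    return LabelMask(vals, v.spacing, v.origin)


def write_mask(m: LabelMask, path):
    img = nib.Nifti1Image(m.values.astype(np.uint8), _affine(m.spacing, m.origin))
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(
            f"{path}: expected a 4-D field with 3 components on the last axis, "
            f"got shape {data.shape}"
        )
    return DisplacementField(data.astype(float), _spacing_from(img))


def write_field(f: DisplacementField, path):
    if f.ndim != 3:
        raise FormatError("only 3-D fields are written to NIfTI")
    img = nib.Nifti1Image(
        np.asarray(f.vectors, dtype=np.float32), _affine(f.spacing, (0, 0, 0))
    )
    img.header.set_zooms(tuple(f.spacing) + (1.0,))
    img.header["descrip"] = b"hybridreg:displacement voxel units"
    nib.save(img, str(path))


# -- landmarks ---------------------------------------------------------------

_LM_BASE = ["name", "x_mm", "y_mm", "z_mm"]
_LM_GOLD = ["gx_mm", "gy_mm", "gz_mm"]


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty landmark file") from None
        header = [h.strip() for h in header]
        if header[:4] != _LM_BASE or header[4:] not in ([], _LM_GOLD):
            raise FormatError(
                f"{path}: header must be {','.join(_LM_BASE)}[,{','.join(_LM_GOLD)}]"
            )
        has_gold = len(header) == 7
        names, pts, gold = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            name = row[0].strip()
            if name in names:
                raise FormatError(f"{path}:{lineno}: duplicate landmark name {name!r}")
            try:
                nums = [float(x) for x in row[1:]]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            names.append(name)
            pts.append(nums[:3])
            if has_gold:
                gold.append(nums[3:])
    return LandmarkSet(names, np.array(pts), np.array(gold) if has_gold else None)


def write_landmarks(l: LandmarkSet, path):
    if l.ndim != 3:
        raise FormatError("landmark CSV stores 3-D physical coordinates")
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        has_gold = l.gold_vectors_mm is not None
        writer.writerow(_LM_BASE + (_LM_GOLD if has_gold else []))
        for i, name in enumerate(l.names):
            row = [name] + [repr(float(x)) for x in l.points_mm[i]]
            if has_gold:
                row += [repr(float(x)) for x in l.gold_vectors_mm[i]]
            writer.writerow(row)


# -- run configuration -------------------------------------------------------


def build_dataclass(cls, data, path: str = ""):
    """Construct a (possibly nested) dataclass from a plain dict, rejecting
    unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown keys {unknown}")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for key, value in data.items():
        target = hints.get(key)
        origin = typing.get_origin(target)
        if origin is typing.Union:  # Optional[...]
            args = [a for a in typing.get_args(target) if a is not type(None)]
            target = args[0] if len(args) == 1 else None
        if dataclasses.is_dataclass(target) and isinstance(value, dict):
            kwargs[key] = build_dataclass(target, value, f"{path}.{key}" if path else key)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from None


def config_to_dict(obj):
    """Dataclass -> YAML-safe plain structure (tuples become lists)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: config_to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [config_to_dict(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class SplitConfig:
    """Cohort split sizes (train/validation/test)."""

    n_train: int = 8
    n_val: int = 2
    n_test: int = 4

    def __post_init__(self):
        if min(self.n_train, self.n_val, self.n_test) < 1:
            raise ValueError("all split sizes must be >= 1")


@dataclass
class EvalConfig:
    n_cases: int = 8
    nmi_bins: int = 32


@dataclass
class RunConfig:
    """Merged configuration document for a full run."""

    schema_version: int = 1
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    split: SplitConfig = field(default_factory=SplitConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self):
        if self.schema_version != 1:
            raise ConfigError(f"unsupported schema_version {self.schema_version}")


def load_config(path) -> RunConfig:
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh) or {}
    return build_dataclass(RunConfig, doc)


def save_config(cfg: RunConfig, path):
    with Path(path).open("w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
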
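import numpy as np
import pytest

from hybridreg.phantoms import PhantomSpec, desk_spec_2d, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spec2d() -> PhantomSpec:
    return desk_spec_2d()


@pytest.fixture(scope="session")
def spec3d() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom2d(spec2d):
    return generate_phantom(spec2d, seed=0)


@pytest.fixture(scope="session")
def phantom3d(spec3d):
    return generate_phantom(spec3d, seed=0)


def gradcheck(make_loss, x0, rng, eps=1e-5, n=8):
    """Max relative error between autodiff and central finite differences."""
    from hybridreg import autodiff as ad

    x = ad.Tensor(x0.copy(), requires_grad=True)
    make_loss(x).backward()
    g = x.grad
    errs = []
    for _ in range(n):
        idx = tuple(int(rng.integers(0, s)) for s in x0.shape)
        xp = x0.copy()
        xp[idx] += eps
        xm = x0.copy()
        xm[idx] -= eps
        fd = (make_loss(ad.Tensor(xp)).data - make_loss(ad.Tensor(xm)).data) / (2 * eps)
        errs.append(abs(fd - g[idx]) / max(1e-8, abs(fd), abs(g[idx])))
    return max(errs)
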
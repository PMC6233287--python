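import numpy as np
import pytest

import perpetrt as pp


@pytest.fixture(scope="session")
def sphere_phantom():
    """A mid-contrast blurred, noisy sphere used by several module tests."""
    spec = pp.PhantomSpec(shape=(28, 28, 28), spacing=(4.0, 4.0, 4.0),
                          radii_mm=20.0, peak_suv=8.0, background_suv=1.0,
                          psf_fwhm_mm=6.5, noise_sd=0.05, seed=42)
    vol, truth = pp.generate_phantom(spec)
    return vol, truth, spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_volume(rng, shape=(12, 12, 12), spacing=(4.0, 4.0, 4.0)):
    """A random positive SUV volume for property checks."""
    return pp.ScalarVolume(voxels=rng.uniform(0.1, 10.0, size=shape), spacing=spacing)


def brute_force_component(raw: np.ndarray, seed) -> np.ndarray:
    """Breadth-first 26-connected flood fill, independent of scipy labelling."""
    from collections import deque

    out = np.zeros_like(raw, dtype=bool)
    if not raw[tuple(seed)]:
        return out
    q = deque([tuple(seed)])
    out[tuple(seed)] = True
    shape = raw.shape
    while q:
        i, j, k = q.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (0 <= ni < shape[0] and 0 <= nj < shape[1]
                            and 0 <= nk < shape[2]
                            and raw[ni, nj, nk] and not out[ni, nj, nk]):
                        out[ni, nj, nk] = True
                        q.append((ni, nj, nk))
    return out


def brute_force_mask(vol: pp.ScalarVolume, voi: pp.VOI, t_suv: float) -> np.ndarray:
    """Oracle for every thresholding method: voxelwise comparison inside the
    VOI followed by a flood fill seeded at the first lexicographic maximum."""
    full = np.zeros(vol.shape, dtype=bool)
    sub = vol.voxels[voi.slices()]
    raw = sub >= t_suv
    if not raw.any():
        return full
    seed = np.unravel_index(int(np.argmax(sub)), sub.shape)
    if not raw[seed]:
        return full
    full[voi.slices()] = brute_force_component(raw, seed)
    return full
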
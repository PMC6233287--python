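"""Synthetic PET phantoms and calibration cohorts.

No imaging data accompany the delineation problem this package addresses,
so every downstream module is exercised on simulated lesions. A phantom is
an ellipsoidal lesion of uniform uptake in a uniform background, degraded
by the two effects that dominate threshold behaviour on whole-body FDG
PET: partial-volume blur (isotropic Gaussian point-spread function) and
additive Gaussian noise. The truth mask is the pre-blur ellipsoid support
— the "real" tumour — so segmentations are judged against an object the
scanner physics has genuinely degraded.

Cohort generation emulates the observed per-radiotherapy NSCLC lesion
population: SUVmax roughly 2.4–36.5 for primary tumours and 2.4–9.3 for
nodes, lesion volumes 0.26–140 cc, and expert (gold-standard) relative
thresholds drawn from the log-linear model Th = A·ln(1/SUVmax) + B with
Gaussian scatter — the structure a calibration procedure must recover.

Defaults the generator commits to (whole-body FDG PET at desk scale):
4 mm isotropic voxels, 6.5 mm PSF FWHM, background 0.8 SUV for lung
(primary) lesions and 1.8 SUV for mediastinal nodes, image noise SD 0.05
SUV, threshold scatter SD 3 (percent units). Noise is Gaussian, not
Poisson, which is adequate for studying threshold behaviour but does not
reproduce count-limited reconstruction texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, special

from .calibration import CalibrationPair
from .segmentation import ThresholdModel, DEFAULT_MODELS
from .volume_io import VOI, BinaryMask, ScalarVolume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "LesionRecord",
    "generate_phantom",
    "generate_calibration_pairs",
    "generate_cohort",
    "ball_blur_centre_fraction",
    "peak_for_target_suvmax",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Background SUV per lesion type: mediastinal blood-pool background is
#: hotter than aerated lung, which is what gives nodes their lower contrast
#: and higher expert thresholds.
DEFAULT_BACKGROUND = {"primary": 0.8, "node": 1.8}


@dataclass
class PhantomSpec:
    """Parameters of a single ellipsoidal-lesion phantom.

    ``radii_mm`` may be a scalar (sphere) or a 3-tuple (ellipsoid);
    ``center_mm`` defaults to the grid centre. ``psf_fwhm_mm`` is the
    isotropic Gaussian PSF full width at half maximum; ``noise_sd`` the
    SD of the additive Gaussian noise in SUV.
    """

    shape: Tuple[int, int, int] = (32, 32, 32)
    spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)
    radii_mm: Tuple[float, float, float] | float = 15.0
    peak_suv: float = 8.0
    background_suv: float = 0.8
    center_mm: Optional[Tuple[float, float, float]] = None
    psf_fwhm_mm: float = 6.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if np.isscalar(self.radii_mm):
            self.radii_mm = (float(self.radii_mm),) * 3
        else:
            self.radii_mm = tuple(float(r) for r in self.radii_mm)
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("lesion radii must be > 0")
        if not (self.peak_suv > self.background_suv > 0):
            raise ValueError("require peak SUV > background SUV > 0")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm_mm and noise_sd must be >= 0")
        if self.center_mm is None:
            # centre on a voxel centre so the hottest voxel samples the true
            # lesion centre; a corner-centred lesion under-reads SUVmax on
            # coarse grids
            self.center_mm = tuple((n // 2 + 0.5) * s
                                   for n, s in zip(self.shape, self.spacing))
        extent = tuple(n * s for n, s in zip(self.shape, self.spacing))
        for c, r, e in zip(self.center_mm, self.radii_mm, extent):
            if c - r < 0 or c + r > e:
                raise ValueError(
                    f"lesion (centre {self.center_mm} mm, radii {self.radii_mm} mm) "
                    f"exceeds the {extent} mm grid")


def generate_phantom(spec: PhantomSpec) -> Tuple[ScalarVolume, BinaryMask]:
    """Simulate one phantom: (blurred, noisy SUV volume, pre-blur truth mask)."""
    coords = [ (np.arange(n) + 0.5) * s for n, s in zip(spec.shape, spec.spacing) ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = spec.center_mm
    rx, ry, rz = spec.radii_mm
    support = (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
               + ((zz - cz) / rz) ** 2) <= 1.0

    vol = np.full(spec.shape, spec.background_suv, dtype=np.float64)
    vol[support] = spec.peak_suv
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing]
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = np.clip(vol, 0.0, None)
    return (ScalarVolume(voxels=vol, spacing=spec.spacing),
            BinaryMask(voxels=support, spacing=spec.spacing))


def ball_blur_centre_fraction(radius_mm: float, sigma_mm: float) -> float:
    """Centre amplitude of a unit ball after isotropic Gaussian blur.

    Closed form for the convolution of the indicator of a ball of radius R
    with an isotropic Gaussian of SD sigma, evaluated at the centre:
    erf(R/(sigma*sqrt(2))) - R*sqrt(2/pi)/sigma * exp(-R^2/(2*sigma^2)).
    Governs how much a small lesion's apparent SUVmax is suppressed by
    partial-volume blur.
    """
    if sigma_mm <= 0:
        return 1.0
    t = radius_mm / sigma_mm
    return float(special.erf(t / math.sqrt(2.0))
                 - t * math.sqrt(2.0 / math.pi) * math.exp(-0.5 * t * t))


def peak_for_target_suvmax(target_suvmax: float, background: float,
                           radius_mm: float, sigma_mm: float) -> float:
    """Pre-blur peak SUV needed so the blurred lesion's maximum hits a target.

    Inverts the centre-amplitude formula; for lesions small relative to
    the PSF the required peak grows rapidly (partial-volume effect).
    """
    c = ball_blur_centre_fraction(radius_mm, sigma_mm)
    c = max(c, 1e-6)
    return background + (target_suvmax - background) / c


@dataclass
class CohortSpec:
    """Parameters of a synthetic lesion cohort.

    ``type_mix`` gives the sampling weight of each lesion type; SUVmax and
    lesion volume are drawn from clipped lognormal distributions whose
    medians and ranges match the observed per-radiotherapy population
    (primaries: SUVmax median ~6.5 in [2.5, 36.5], volumes median ~8 cc in
    [0.26, 140]; nodes: SUVmax median ~4.6 in [2.4, 9.3], volumes median
    ~2 cc in [0.26, 25]). Gold-standard thresholds follow the generating
    ``models`` with Gaussian scatter of SD ``threshold_noise_sd`` —
    absolute percent units by default, or a fraction of the threshold when
    ``threshold_noise_relative`` is set.
    """

    n_lesions: int = 60
    type_mix: Dict[str, float] = field(default_factory=lambda: {"primary": 0.5, "node": 0.5})
    suvmax_range: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"primary": (2.5, 36.5), "node": (2.4, 9.3)})
    suvmax_median: Dict[str, float] = field(
        default_factory=lambda: {"primary": 6.5, "node": 4.6})
    suvmax_log_sd: float = 0.5
    #: "lognormal" (clipped, median/log-sd above) or "uniform" over the range
    suvmax_distribution: str = "lognormal"
    volume_range_cc: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"primary": (0.26, 140.0), "node": (0.26, 25.0)})
    volume_median_cc: Dict[str, float] = field(
        default_factory=lambda: {"primary": 8.0, "node": 2.0})
    volume_log_sd: float = 1.0
    models: Dict[str, ThresholdModel] = field(default_factory=lambda: dict(DEFAULT_MODELS))
    threshold_noise_sd: float = 3.0
    threshold_noise_relative: bool = False
    background: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    device_mix: Dict[str, float] = field(default_factory=lambda: {"old": 0.6, "new": 0.4})
    spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)
    psf_fwhm_mm: float = 6.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if not self.type_mix or sum(self.type_mix.values()) <= 0:
            raise ValueError("type_mix must name at least one lesion type with weight > 0")
        for t in self.type_mix:
            if t not in self.models:
                raise ValueError(f"no generating model for lesion type {t!r}")
        if self.threshold_noise_sd < 0:
            raise ValueError("threshold_noise_sd must be >= 0")
        if self.suvmax_distribution not in ("lognormal", "uniform"):
            raise ValueError(f"unknown suvmax_distribution {self.suvmax_distribution!r}")


@dataclass
class LesionRecord:
    """Metadata accompanying one simulated lesion."""

    lesion_id: str
    lesion_type: str
    device: str
    suvmax_target: float
    radius_mm: float
    truth_volume_cc: float
    gold_threshold_pct: float
    background_suv: float
    peak_suv: float
    seed: int


def _draw_clipped_lognormal(rng: np.random.Generator, median: float, log_sd: float,
                            lo: float, hi: float) -> float:
    v = float(np.exp(np.log(median) + rng.normal(0.0, log_sd)))
    return float(np.clip(v, lo, hi))


def _draw_suvmax(rng: np.random.Generator, spec: CohortSpec, lesion_type: str) -> float:
    lo, hi = spec.suvmax_range[lesion_type]
    if spec.suvmax_distribution == "uniform":
        return float(rng.uniform(lo, hi))
    return _draw_clipped_lognormal(rng, spec.suvmax_median[lesion_type],
                                   spec.suvmax_log_sd, lo, hi)


def _draw_types(rng: np.random.Generator, spec: CohortSpec) -> List[str]:
    types = sorted(spec.type_mix)
    w = np.array([spec.type_mix[t] for t in types], dtype=float)
    return list(rng.choice(types, size=spec.n_lesions, p=w / w.sum()))


def _gold_threshold(rng: np.random.Generator, spec: CohortSpec,
                    lesion_type: str, suvmax: float) -> float:
    model = spec.models[lesion_type]
    th = model.a * math.log(1.0 / suvmax) + model.b
    sd = spec.threshold_noise_sd * (th / 100.0 if spec.threshold_noise_relative else 1.0)
    th += rng.normal(0.0, sd) if sd > 0 else 0.0
    return float(np.clip(th, 0.1, 100.0))


def generate_calibration_pairs(spec: CohortSpec) -> List[CalibrationPair]:
    """Draw (SUVmax, gold threshold) pairs from the generating model.

    SUVmax is drawn from the per-type clipped lognormal; the threshold is
    the model prediction plus Gaussian scatter, clipped to (0, 100].
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    devices = sorted(spec.device_mix)
    wd = np.array([spec.device_mix[d] for d in devices], dtype=float)
    pairs = []
    for lesion_type in _draw_types(rng, spec):
        suvmax = _draw_suvmax(rng, spec, lesion_type)
        th = _gold_threshold(rng, spec, lesion_type, suvmax)
        device = str(rng.choice(devices, p=wd / wd.sum()))
        pairs.append(CalibrationPair(suvmax=suvmax, th_gstd=th,
                                     lesion_type=lesion_type, device=device))
    return pairs


def _grid_for_radius(radius_mm: float, spacing: Tuple[float, float, float],
                     fwhm_mm: float) -> Tuple[int, int, int]:
    # lesion + 4 sigma of blur + 8 mm margin on each side, minimum 24 voxels
    sigma = fwhm_mm * FWHM_TO_SIGMA
    return tuple(max(24, int(math.ceil((2 * radius_mm + 8 * sigma + 16.0) / s)))
                 for s in spacing)


def generate_cohort(spec: CohortSpec) -> List[Tuple[ScalarVolume, BinaryMask, LesionRecord]]:
    """Simulate a cohort of phantoms spanning the target SUVmax/volume ranges.

    Each lesion is a sphere whose pre-blur peak is calibrated (closed-form
    partial-volume inversion) so the blurred image's SUVmax lands near the
    drawn target, and whose gold-standard relative threshold is drawn from
    the generating model with scatter. Per-lesion seeds are derived from
    the cohort seed, so individual lesions are reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = spec.psf_fwhm_mm * FWHM_TO_SIGMA
    devices = sorted(spec.device_mix)
    wd = np.array([spec.device_mix[d] for d in devices], dtype=float)
    out = []
    for i, lesion_type in enumerate(_draw_types(rng, spec)):
        suvmax = _draw_suvmax(rng, spec, lesion_type)
        v_lo, v_hi = spec.volume_range_cc[lesion_type]
        vol_cc = _draw_clipped_lognormal(rng, spec.volume_median_cc[lesion_type],
                                         spec.volume_log_sd, v_lo, v_hi)
        radius = (3.0 * vol_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        bg = spec.background[lesion_type]
        peak = peak_for_target_suvmax(max(suvmax, bg * 1.05), bg, radius, sigma)
        th = _gold_threshold(rng, spec, lesion_type, suvmax)
        device = str(rng.choice(devices, p=wd / wd.sum()))
        lesion_seed = int(rng.integers(0, 2**31 - 1))
        pspec = PhantomSpec(shape=_grid_for_radius(radius, spec.spacing, spec.psf_fwhm_mm),
                            spacing=spec.spacing, radii_mm=radius, peak_suv=peak,
                            background_suv=bg, psf_fwhm_mm=spec.psf_fwhm_mm,
                            noise_sd=spec.noise_sd, seed=lesion_seed)
        volume, truth = generate_phantom(pspec)
        record = LesionRecord(lesion_id=f"lesion-{i:03d}", lesion_type=lesion_type,
                              device=device, suvmax_target=suvmax, radius_mm=radius,
                              truth_volume_cc=truth.volume_cc, gold_threshold_pct=th,
                              background_suv=bg, peak_suv=peak, seed=lesion_seed)
        out.append((volume, truth, record))
    return out
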
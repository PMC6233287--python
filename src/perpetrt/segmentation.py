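"""Thresholding segmentation methods for metabolic tumour volume delineation.

The central method is perPET-RT: an adaptive threshold, expressed as a
percentage of the lesion's SUVmax, predicted from SUVmax itself by a
log-linear model

    Th_opt(%) = A * ln(1 / SUVmax) + B

with constants (A, B) depending on lesion type (primary lung tumour vs
mediastinal lymph node). Higher-uptake lesions receive lower relative
thresholds, which is what expert volume-matched delineations of
per-radiotherapy FDG PET show.

Comparator methods from the same family are provided: fixed absolute SUV
thresholds, fixed percent-of-SUVmax thresholds, the AOV blood-pool method
(1.5x the mean SUV in a 1 cc aortic volume), the contrast-oriented method
COA (threshold affine in the 70%-isocontour mean and the background mean)
and the iterative adaptive method ADT (fixed-point update of the relative
threshold from the reciprocal lesion-to-background contrast).

Every method thresholds inclusively (SUV >= t) within a VOI and then keeps
only the 26-connected component containing the SUVmax voxel, so that
disconnected background uptake never inflates the delineated volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .volume_io import VOI, BinaryMask, ScalarVolume, mask_volume_cc, suv_max

__all__ = [
    "ThresholdModel",
    "SegmentationResult",
    "AdaptiveMethodConfig",
    "DEFAULT_MODELS",
    "threshold_absolute",
    "threshold_relative",
    "perpet_rt_threshold",
    "segment_perpet_rt",
    "aov_threshold",
    "segment_aov",
    "segment_coa",
    "segment_adt",
    "select_component",
    "ConvergenceWarning",
]

#: Lower clip for predicted relative thresholds, in percent. The log-linear
#: model is unbounded for extreme SUVmax; predictions below this floor are
#: clipped to keep the threshold physical.
THRESHOLD_FLOOR_PCT = 1.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class ConvergenceWarning(UserWarning):
    """An iterative method stopped at its iteration cap without converging."""


@dataclass
class ThresholdModel:
    """Fitted constants of the log-linear threshold model for one lesion type.

    ``a`` is the slope and ``b`` the intercept of Th(%) regressed on
    X = ln(1/SUVmax), both in threshold-percent units. Fit diagnostics are
    optional so that externally supplied constants can be carried without
    fabricating statistics.
    """

    a: float
    b: float
    lesion_type: str = "primary"
    r_squared: Optional[float] = None
    n_pairs: Optional[int] = None
    residual_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")
        if self.n_pairs is not None and self.n_pairs < 2:
            raise ValueError(f"n_pairs must be >= 2, got {self.n_pairs}")

    def predict(self, suvmax: float) -> float:
        return perpet_rt_threshold(suvmax, self)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "lesion_type": self.lesion_type,
            "r_squared": self.r_squared,
            "n_pairs": self.n_pairs,
            "residual_sd": self.residual_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        return cls(**{k: d.get(k) for k in ("a", "b", "lesion_type", "r_squared", "n_pairs", "residual_sd")})


#: Approximate default constants per lesion type. Each line is anchored
#: through two characteristic (SUVmax, expert threshold %) operating points
#: of per-radiotherapy NSCLC delineation — primaries: (6.2, 50) and
#: (10.5, 43); nodes: (4.6, 60) and (5.4, 57). These are coarse two-point
#: reconstructions, not fitted values: calibrate on your own
#: (SUVmax, gold-standard threshold) pairs whenever such data exist.
DEFAULT_MODELS = {
    "primary": ThresholdModel(a=13.29, b=74.24, lesion_type="primary"),
    "node": ThresholdModel(a=18.71, b=88.55, lesion_type="node"),
}


@dataclass
class AdaptiveMethodConfig:
    """Coefficients and controls for the COA and ADT comparator methods.

    The published calibrations are scanner-specific and are not shipped as
    fact; the defaults below are physically plausible placeholders and any
    quantitative use requires device calibration.

    coa_coeffs: (c1, c2) in ``t = c1 * mean(70% isocontour) + c2 * background``.
    adt_coeffs: (a0, a1) in the fixed-point update
        ``T_rel <- a0 + a1 * (background / contour mean)``.
    """

    coa_coeffs: Tuple[float, float] = (0.5, 0.5)
    adt_coeffs: Tuple[float, float] = (0.39, 0.45)
    adt_start: float = 0.40
    adt_tol: float = 0.005
    adt_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.adt_tol <= 0:
            raise ValueError("adt_tol must be > 0")
        if self.adt_max_iter < 1:
            raise ValueError("adt_max_iter must be >= 1")
        if not (0 < self.adt_start <= 1):
            raise ValueError("adt_start must be in (0, 1]")


@dataclass
class SegmentationResult:
    """A segmentation mask with the threshold that produced it."""

    mask: BinaryMask
    threshold_suv: float
    method: str
    threshold_pct: Optional[float] = None
    volume_cc: float = 0.0
    iterations: Optional[int] = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.threshold_suv <= 0:
            raise ValueError("threshold_suv must be > 0")
        self.volume_cc = mask_volume_cc(self.mask)


def select_component(mask: BinaryMask, seed_index) -> BinaryMask:
    """Keep only the 26-connected component of ``mask`` containing ``seed_index``."""
    seed = tuple(int(i) for i in seed_index)
    if not mask.voxels[seed]:
        raise ValueError(f"seed index {seed} is not inside the mask")
    labels, _ = ndimage.label(mask.voxels, structure=_STRUCT_26)
    return BinaryMask(voxels=labels == labels[seed], spacing=mask.spacing)


def _threshold_in_voi(vol: ScalarVolume, voi: VOI, t_suv: float, method: str,
                      threshold_pct: Optional[float] = None) -> SegmentationResult:
    voi.validate(vol.shape)
    full = np.zeros(vol.shape, dtype=bool)
    sub = vol.voxels[voi.slices()]
    raw = sub >= t_suv
    if raw.any():
        _, seed = suv_max(vol, voi)
        local_seed = tuple(s - l for s, l in zip(seed, voi.lower))
        if raw[local_seed]:
            labels, _ = ndimage.label(raw, structure=_STRUCT_26)
            raw = labels == labels[local_seed]
        else:
            # threshold above SUVmax: nothing survives
            raw = np.zeros_like(raw)
    full[voi.slices()] = raw
    mask = BinaryMask(voxels=full, spacing=vol.spacing)
    return SegmentationResult(mask=mask, threshold_suv=float(t_suv), method=method,
                              threshold_pct=threshold_pct)


def threshold_absolute(vol: ScalarVolume, voi: VOI, t_suv: float,
                       method: str = "fixed-suv") -> SegmentationResult:
    """Segment voxels with SUV >= ``t_suv`` inside the VOI (fixed SUV method)."""
    if t_suv <= 0:
        raise ValueError(f"absolute threshold must be > 0, got {t_suv}")
    return _threshold_in_voi(vol, voi, t_suv, method)


def threshold_relative(vol: ScalarVolume, voi: VOI, fraction_pct: float,
                       method: str = "fixed-pct") -> SegmentationResult:
    """Segment at ``fraction_pct`` percent of the VOI's SUVmax (isocontour method)."""
    if not (0 < fraction_pct <= 100):
        raise ValueError(f"fraction_pct must be in (0, 100], got {fraction_pct}")
    smax, _ = suv_max(vol, voi)
    if smax <= 0:
        raise ValueError("SUVmax within the VOI must be > 0 for a relative threshold")
    t_suv = fraction_pct / 100.0 * smax
    res = _threshold_in_voi(vol, voi, t_suv, method, threshold_pct=float(fraction_pct))
    return res


def perpet_rt_threshold(suvmax: float, model: ThresholdModel) -> float:
    """Optimal relative threshold (percent of SUVmax) predicted from SUVmax.

    Evaluates ``A * ln(1/SUVmax) + B`` and clips the prediction to the
    physical range (floor 1%, cap 100%).
    """
    if suvmax <= 0:
        raise ValueError(f"suvmax must be > 0, got {suvmax}")
    raw = model.a * np.log(1.0 / suvmax) + model.b
    return float(np.clip(raw, THRESHOLD_FLOOR_PCT, 100.0))


def segment_perpet_rt(vol: ScalarVolume, voi: VOI,
                      model: ThresholdModel) -> SegmentationResult:
    """perPET-RT delineation: measure SUVmax, predict the threshold, segment."""
    smax, _ = suv_max(vol, voi)
    pct = perpet_rt_threshold(smax, model)
    res = threshold_relative(vol, voi, pct, method="perpet")
    return res


def aov_threshold(aorta_mean_suv: float) -> float:
    """Blood-pool threshold: 1.5x the mean SUV of a 1 cc aortic volume."""
    if aorta_mean_suv <= 0:
        raise ValueError(f"aorta mean SUV must be > 0, got {aorta_mean_suv}")
    return 1.5 * aorta_mean_suv


def segment_aov(vol: ScalarVolume, voi: VOI, aorta_mean_suv: float) -> SegmentationResult:
    """AOV delineation: absolute threshold at 1.5x the aortic blood-pool mean."""
    return threshold_absolute(vol, voi, aov_threshold(aorta_mean_suv), method="aov")


def _contour_mean(vol: ScalarVolume, voi: VOI, fraction_pct: float) -> float:
    res = threshold_relative(vol, voi, fraction_pct, method="_contour")
    return float(vol.voxels[res.mask.voxels].mean())


def segment_coa(vol: ScalarVolume, voi: VOI, background_mean: float,
                cfg: Optional[AdaptiveMethodConfig] = None) -> SegmentationResult:
    """Contrast-oriented delineation (COA).

    The absolute threshold is an affine combination of the mean SUV inside
    the 70%-of-SUVmax isocontour and the background mean:
    ``t = c1 * m70 + c2 * background``.
    """
    cfg = cfg or AdaptiveMethodConfig()
    if background_mean < 0:
        raise ValueError("background mean must be >= 0")
    c1, c2 = cfg.coa_coeffs
    m70 = _contour_mean(vol, voi, 70.0)
    t = c1 * m70 + c2 * background_mean
    res = threshold_absolute(vol, voi, t, method="coa")
    smax, _ = suv_max(vol, voi)
    res.threshold_pct = float(100.0 * t / smax)
    return res


def segment_adt(vol: ScalarVolume, voi: VOI, background_mean: float,
                cfg: Optional[AdaptiveMethodConfig] = None) -> SegmentationResult:
    """Iterative adaptive delineation (ADT).

    Fixed-point iteration on the relative threshold: from the current
    contour's mean SUV, the next threshold fraction is
    ``a0 + a1 * (background / contour mean)`` — the reciprocal contrast
    raises the threshold for low-contrast lesions. Stops when successive
    thresholds differ by less than ``adt_tol`` (fraction units) or at
    ``adt_max_iter``, in which case the last iterate is returned with a
    :class:`ConvergenceWarning` and ``converged=False``.
    """
    cfg = cfg or AdaptiveMethodConfig()
    if background_mean < 0:
        raise ValueError("background mean must be >= 0")
    a0, a1 = cfg.adt_coeffs
    t = float(cfg.adt_start)
    converged = False
    iterations = 0
    seen: dict = {}
    for iterations in range(1, cfg.adt_max_iter + 1):
        mean_c = _contour_mean(vol, voi, 100.0 * t)
        t_new = float(np.clip(a0 + a1 * (background_mean / mean_c),
                              THRESHOLD_FLOOR_PCT / 100.0, 1.0))
        done = abs(t_new - t) < cfg.adt_tol
        t = t_new
        if done:
            converged = True
            break
        # the voxel lattice quantises the contour, so the map can enter a
        # cycle with no fixed point between voxel levels: detect and stop
        key = round(t, 9)
        if key in seen:
            break
        seen[key] = iterations
    if not converged:
        warnings.warn(
            f"ADT did not converge after {iterations} iterations "
            f"(last threshold {100 * t:.2f}% SUVmax)", ConvergenceWarning)
    res = threshold_relative(vol, voi, 100.0 * t, method="adt")
    res.iterations = iterations
    res.converged = converged
    return res
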
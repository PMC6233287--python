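"""Calibration of the log-linear threshold model.

Three steps mirror how an adaptive-threshold delineation method is
calibrated against expert contours:

1. :func:`gold_standard_threshold` — given a lesion and a target volume
   (the experts' manual delineation), find the relative threshold whose
   isocontour volume matches that target. Segmented volume is a
   non-increasing step function of the threshold, so a bisection search
   converges; ties resolve toward the higher threshold.
2. :func:`fit_threshold_model` — ordinary least squares of the
   gold-standard thresholds on X = ln(1/SUVmax), one line per lesion type,
   reporting slope A, intercept B, R^2 and the residual SD.
3. :func:`compare_lines` — nested F-tests between two calibration datasets
   (e.g. old- vs new-generation scanners, or primaries vs nodes): slopes
   are compared first; only if they are compatible are intercepts compared.
   The tests assume homoscedastic Gaussian residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .segmentation import ThresholdModel, threshold_relative
from .volume_io import VOI, ScalarVolume

__all__ = [
    "CalibrationPair",
    "LineComparisonResult",
    "UnreachableVolumeError",
    "gold_standard_threshold",
    "fit_threshold_model",
    "compare_lines",
    "read_pairs_csv",
    "write_pairs_csv",
]


class UnreachableVolumeError(ValueError):
    """The requested target volume lies outside the achievable range."""

    def __init__(self, target_cc: float, achievable: Tuple[float, float]):
        self.target_cc = target_cc
        self.achievable = achievable
        super().__init__(
            f"target volume {target_cc:.3f} cc is unreachable; achievable range is "
            f"[{achievable[0]:.3f}, {achievable[1]:.3f}] cc")


@dataclass(frozen=True)
class CalibrationPair:
    """One calibration observation: a lesion's SUVmax and its gold-standard threshold."""

    suvmax: float
    th_gstd: float
    lesion_type: str = "primary"
    device: str = "old"

    def __post_init__(self) -> None:
        if self.suvmax <= 0:
            raise ValueError(f"suvmax must be > 0, got {self.suvmax}")
        if not (0 < self.th_gstd <= 100):
            raise ValueError(f"th_gstd must be in (0, 100], got {self.th_gstd}")


@dataclass
class LineComparisonResult:
    """Outcome of the sequential slope-then-intercept comparison of two lines."""

    p_slope: float
    p_intercept: Optional[float]
    verdict: str  # different_slopes | different_intercepts | indistinguishable
    alpha: float = 0.05


def gold_standard_threshold(vol: ScalarVolume, voi: VOI, target_volume_cc: float,
                            *, max_iter: int = 40,
                            tol_cc: Optional[float] = None,
                            floor_pct: float = 1e-3) -> float:
    """Relative threshold (percent SUVmax) whose segmented volume matches a target.

    Emulates the expert procedure of sweeping thresholds until the
    isocontour volume equals the manually delineated one. Because volume
    is a non-increasing step function of the threshold, a bisection over
    (0, 100] converges; the search stops early once within ``tol_cc``
    (default: half a voxel volume) of the target and returns, among
    equally close candidates, the higher threshold.
    """
    if target_volume_cc <= 0:
        raise ValueError("target volume must be > 0")
    voi.validate(vol.shape)
    if tol_cc is None:
        tol_cc = 0.5 * float(np.prod(vol.spacing)) / 1000.0

    def vol_at(pct: float) -> float:
        return threshold_relative(vol, voi, pct, method="_gstd").volume_cc

    v_floor, v_cap = vol_at(floor_pct), vol_at(100.0)
    if target_volume_cc > v_floor + tol_cc:
        raise UnreachableVolumeError(target_volume_cc, (v_cap, v_floor))

    def sup_threshold(level_cc: float, lo: float, hi: float, iters: int) -> float:
        # highest threshold whose volume is still >= level_cc; volume is a
        # non-increasing step function of the threshold, so this boundary
        # bisection lands on the top of the matching plateau
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if vol_at(mid) >= level_cc - 1e-12:
                lo = mid
            else:
                hi = mid
        return lo

    if v_cap >= target_volume_cc:        # even the SUVmax voxel(s) are enough
        return 100.0
    half = max_iter // 2
    t_lo = sup_threshold(target_volume_cc, floor_pct, 100.0, half)
    v_lo = vol_at(t_lo)
    t_hi = min(t_lo + 100.0 * 2.0 ** (-half), 100.0)
    v_hi = vol_at(t_hi)
    err_lo = abs(v_lo - target_volume_cc)
    err_hi = abs(v_hi - target_volume_cc)
    if err_lo < err_hi - 1e-12:
        return float(t_lo)
    # first plateau below the target is at least as close: ties go to the
    # higher threshold, i.e. the top of that plateau
    return float(sup_threshold(v_hi, t_hi, 100.0, max_iter - half))


def _pairs_frame(pairs: Iterable[CalibrationPair]) -> pd.DataFrame:
    rows = [(p.suvmax, p.th_gstd, p.lesion_type, p.device) for p in pairs]
    return pd.DataFrame(rows, columns=["suvmax", "th_gstd", "lesion_type", "device"])


def fit_threshold_model(pairs: Sequence[CalibrationPair],
                        lesion_type: Optional[str] = None) -> ThresholdModel:
    """Least-squares fit of Th(%) on ln(1/SUVmax) for one lesion type.

    Requires at least 3 pairs of the requested type with at least 2
    distinct SUVmax values. Returns slope, intercept, R^2, residual SD
    (root mean square residual on n-2 degrees of freedom) and n.
    """
    sel = [p for p in pairs if lesion_type is None or p.lesion_type == lesion_type]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 calibration pairs, got {len(sel)}")
    x = np.log(1.0 / np.array([p.suvmax for p in sel]))
    y = np.array([p.th_gstd for p in sel])
    if np.unique(x).size < 2:
        raise ValueError("degenerate calibration data: all pairs share one SUVmax")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = res.params
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    r2 = float(np.clip(res.rsquared, 0.0, 1.0))
    return ThresholdModel(a=float(a), b=float(b),
                          lesion_type=lesion_type or sel[0].lesion_type,
                          r_squared=r2, n_pairs=len(sel), residual_sd=resid_sd)


def compare_lines(pairs_1: Sequence[CalibrationPair],
                  pairs_2: Sequence[CalibrationPair],
                  alpha: float = 0.05) -> LineComparisonResult:
    """Sequential F-test comparison of two calibration regression lines.

    First the slopes are compared (separate-slopes model vs common-slope
    model). If that p-value falls below ``alpha`` the lines differ and the
    intercepts are not compared. Otherwise a common slope is accepted and
    the intercepts are compared (separate-intercepts model vs a single
    line). Both tests are nested-OLS F-tests and assume homoscedastic
    Gaussian residuals.
    """
    if len(pairs_1) < 3 or len(pairs_2) < 3:
        raise ValueError("each dataset needs >= 3 pairs")
    x1 = np.log(1.0 / np.array([p.suvmax for p in pairs_1]))
    y1 = np.array([p.th_gstd for p in pairs_1])
    x2 = np.log(1.0 / np.array([p.suvmax for p in pairs_2]))
    y2 = np.array([p.th_gstd for p in pairs_2])
    if np.unique(x1).size < 2 or np.unique(x2).size < 2:
        raise ValueError("degenerate dataset: no SUVmax spread")

    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros_like(x1), np.ones_like(x2)])  # group indicator

    def rss(X: np.ndarray) -> Tuple[float, int]:
        fit = sm.OLS(y, X).fit()
        return float(fit.ssr), int(fit.df_resid)

    ones = np.ones_like(x)
    X_full = np.column_stack([ones, g, x, g * x])        # separate lines
    X_slope = np.column_stack([ones, g, x])              # common slope
    X_single = np.column_stack([ones, x])                # one line

    from scipy import stats as sps

    rss_full, df_full = rss(X_full)
    rss_slope, _ = rss(X_slope)
    if rss_full <= 0 or df_full <= 0:
        p_slope = 1.0
    else:
        f = (rss_slope - rss_full) / 1 / (rss_full / df_full)
        p_slope = float(sps.f.sf(max(f, 0.0), 1, df_full))

    if p_slope < alpha:
        return LineComparisonResult(p_slope=p_slope, p_intercept=None,
                                    verdict="different_slopes", alpha=alpha)

    rss_single, _ = rss(X_single)
    _, df_slope = rss(X_slope)
    if rss_slope <= 0 or df_slope <= 0:
        p_intercept = 1.0
    else:
        f = (rss_single - rss_slope) / 1 / (rss_slope / df_slope)
        p_intercept = float(sps.f.sf(max(f, 0.0), 1, df_slope))
    verdict = "different_intercepts" if p_intercept < alpha else "indistinguishable"
    return LineComparisonResult(p_slope=p_slope, p_intercept=p_intercept,
                                verdict=verdict, alpha=alpha)


def read_pairs_csv(path) -> List[CalibrationPair]:
    """Read calibration pairs from CSV (columns suvmax, th_gstd, lesion_type, device)."""
    df = pd.read_csv(path)
    required = {"suvmax", "th_gstd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [CalibrationPair(suvmax=float(r.suvmax), th_gstd=float(r.th_gstd),
                            lesion_type=str(getattr(r, "lesion_type", "primary")),
                            device=str(getattr(r, "device", "old")))
            for r in df.itertuples(index=False)]


def write_pairs_csv(pairs: Sequence[CalibrationPair], path) -> None:
    _pairs_frame(pairs).to_csv(path, index=False)
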
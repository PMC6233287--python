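"""Agreement metrics and statistical comparison of segmentation methods.

The agreement between a delineation and its reference is the Sørensen–Dice
coefficient DSC = 2|X∩Y| / (|X|+|Y|), summarised per method by its median,
quartiles, deciles and ranges, interpreted through the conventional bands
(poor / fair / moderate / good / very good agreement), and compared across
methods with a Friedman omnibus test followed by pairwise Wilcoxon
signed-rank tests against a reference method with Bonferroni adjustment.
The design is paired: every lesion must carry a DSC for every method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import BinaryMask, GridMismatchError

__all__ = [
    "DSCRecord",
    "MethodSummary",
    "MethodComparison",
    "dice",
    "summarize",
    "compare_methods",
    "categorize_agreement",
    "AGREEMENT_BANDS",
]


def dice(x: BinaryMask, y: BinaryMask) -> float:
    """Sørensen–Dice coefficient 2|X∩Y| / (|X|+|Y|) of two masks on one grid.

    Both masks empty is perfect agreement on absence (1.0); exactly one
    empty is complete disagreement (0.0).
    """
    if not x.same_grid(y):
        raise GridMismatchError(
            f"mask grids differ: {x.shape}@{x.spacing} vs {y.shape}@{y.spacing}")
    nx = int(np.count_nonzero(x.voxels))
    ny = int(np.count_nonzero(y.voxels))
    if nx == 0 and ny == 0:
        return 1.0
    inter = int(np.count_nonzero(x.voxels & y.voxels))
    return 2.0 * inter / (nx + ny)


@dataclass(frozen=True)
class DSCRecord:
    lesion_id: str
    method: str
    dsc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"DSC must be in [0, 1], got {self.dsc}")


@dataclass
class MethodSummary:
    """Descriptive statistics of a method's DSC distribution."""

    method: str
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    q1: float
    q3: float
    d1: float
    d9: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def interdecile(self) -> float:
        return self.d9 - self.d1

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("method", "n", "mean", "sd", "median", "min", "max", "q1", "q3", "d1", "d9")}
        d["iqr"] = self.iqr
        d["interdecile"] = self.interdecile
        return d


def summarize(records: Sequence[DSCRecord], method: str) -> MethodSummary:
    """Summarise one method's DSC values (linear-interpolation quantiles)."""
    vals = np.array([r.dsc for r in records if r.method == method], dtype=float)
    if vals.size == 0:
        raise ValueError(f"no DSC records for method {method!r}")
    q = np.quantile(vals, [0.10, 0.25, 0.50, 0.75, 0.90])
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return MethodSummary(method=method, n=int(vals.size),
                         mean=float(vals.mean()), sd=sd,
                         median=float(q[2]), min=float(vals.min()), max=float(vals.max()),
                         q1=float(q[1]), q3=float(q[3]), d1=float(q[0]), d9=float(q[4]))


@dataclass
class MethodComparison:
    """Friedman omnibus plus Bonferroni-adjusted pairwise Wilcoxon results."""

    omnibus_statistic: float
    omnibus_p: float
    reference: str
    pairwise: pd.DataFrame  # columns: method, statistic, p_raw, p_adjusted, significant
    alpha: float


def _paired_table(records: Sequence[DSCRecord]) -> pd.DataFrame:
    df = pd.DataFrame([(r.lesion_id, r.method, r.dsc) for r in records],
                      columns=["lesion_id", "method", "dsc"])
    if df.empty:
        raise ValueError("no DSC records supplied")
    table = df.pivot_table(index="lesion_id", columns="method", values="dsc",
                           aggfunc="first")
    if table.isna().any().any():
        missing = [(table.index[int(i)], table.columns[int(j)])
                   for i, j in zip(*np.where(table.isna().to_numpy()))]
        raise ValueError(f"unpaired data; missing lesion/method cells: {missing}")
    return table


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> tuple:
    d = a - b
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="zsplit")
    return float(res.statistic), float(res.pvalue)


def compare_methods(records: Sequence[DSCRecord], reference: str,
                    alpha: float = 0.05) -> MethodComparison:
    """Non-parametric paired comparison of methods' DSC distributions.

    Runs a Friedman omnibus test across all methods (same lesions in every
    column) and pairwise Wilcoxon signed-rank tests of the reference method
    against each comparator, with Bonferroni adjustment (raw p times the
    number of comparisons, capped at 1).
    """
    table = _paired_table(records)
    if reference not in table.columns:
        raise ValueError(f"reference method {reference!r} has no records")
    methods = list(table.columns)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")

    cols = [table[m].to_numpy() for m in methods]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        stat, p = 0.0, 1.0
    elif len(methods) == 2:
        stat, p = _wilcoxon_p(cols[0], cols[1])
    else:
        stat, p = stats.friedmanchisquare(*cols)

    ref = table[reference].to_numpy()
    others = [m for m in methods if m != reference]
    rows = []
    for m in others:
        w, p_raw = _wilcoxon_p(ref, table[m].to_numpy())
        p_adj = min(1.0, p_raw * len(others))
        rows.append((m, w, p_raw, p_adj, p_adj < alpha))
    pairwise = pd.DataFrame(rows, columns=["method", "statistic", "p_raw",
                                           "p_adjusted", "significant"])
    return MethodComparison(omnibus_statistic=float(stat), omnibus_p=float(p),
                            reference=reference, pairwise=pairwise, alpha=alpha)


#: Agreement bands on the rounded DSC (2 decimals): upper edge -> label.
AGREEMENT_BANDS = [
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
]


def categorize_agreement(dsc: float) -> str:
    """Map a DSC value into its qualitative agreement band.

    The value is rounded to 2 decimals first so that band edges are
    unambiguous (e.g. 0.205 rounds to 0.20 -> "poor").
    """
    if not (0.0 <= dsc <= 1.0):
        raise ValueError(f"DSC must be in [0, 1], got {dsc}")
    r = round(float(dsc), 2)
    for upper, label in AGREEMENT_BANDS:
        if r <= upper + 1e-12:
            return label
    return AGREEMENT_BANDS[-1][1]
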
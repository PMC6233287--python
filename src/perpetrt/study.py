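"""End-to-end replicate-the-design driver.

Runs the whole experimental design on synthetic data: simulate a lesion
cohort, optionally calibrate the log-linear threshold model on the
cohort's own (SUVmax, gold-standard threshold) pairs, delineate every
lesion with every configured method, score each delineation against the
gold-standard isocontour mask with the Dice coefficient, summarise per
method, and compare methods non-parametrically against the reference
(perPET-RT by default). Everything is seeded; reruns with the same
configuration produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationPair, fit_threshold_model
from .evaluation import (DSCRecord, MethodComparison, categorize_agreement,
                         compare_methods, dice, summarize)
from .phantom import CohortSpec, generate_cohort
from .segmentation import (AdaptiveMethodConfig, ThresholdModel, segment_adt,
                           segment_aov, segment_coa, segment_perpet_rt,
                           threshold_absolute, threshold_relative)
from .volume_io import VOI, suv_max

log = logging.getLogger("perpetrt.study")

__all__ = ["MethodSpec", "RunConfig", "StudyResult", "run_study", "DEFAULT_METHODS"]


@dataclass(frozen=True)
class MethodSpec:
    """One segmentation method to evaluate: a kind plus its parameter."""

    kind: str              # perpet | fixed-suv | fixed-pct | aov | coa | adt
    value: Optional[float] = None

    @property
    def label(self) -> str:
        if self.kind == "fixed-suv":
            return f"suv{self.value:g}"
        if self.kind == "fixed-pct":
            return f"pct{self.value:g}"
        return self.kind


#: The comparison battery: perPET-RT, four fixed SUV thresholds, four fixed
#: percent-of-SUVmax thresholds, and the three adaptive comparators.
DEFAULT_METHODS = (
    MethodSpec("perpet"),
    MethodSpec("fixed-suv", 2.0), MethodSpec("fixed-suv", 2.5),
    MethodSpec("fixed-suv", 3.0), MethodSpec("fixed-suv", 3.5),
    MethodSpec("fixed-pct", 40.0), MethodSpec("fixed-pct", 50.0),
    MethodSpec("fixed-pct", 60.0), MethodSpec("fixed-pct", 70.0),
    MethodSpec("aov"), MethodSpec("coa"), MethodSpec("adt"),
)

_CONFIG_KEYS = {"schema_version", "seed", "alpha", "reference", "calibrate",
                "aov_blood_suv", "methods", "cohort", "adaptive"}


@dataclass
class RunConfig:
    """Configuration of one study run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    methods: Sequence[MethodSpec] = DEFAULT_METHODS
    reference: str = "perpet"
    alpha: float = 0.05
    calibrate: bool = True
    #: mean SUV of the synthetic 1 cc aortic blood-pool sample used by AOV
    aov_blood_suv: float = 1.8
    adaptive: AdaptiveMethodConfig = field(default_factory=AdaptiveMethodConfig)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a versioned YAML config; unknown keys are errors."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        version = raw.get("schema_version", 1)
        if version != 1:
            raise ValueError(f"{path}: unsupported schema_version {version}")
        cohort_kw = dict(raw.get("cohort", {}))
        known_cohort = {f.name for f in dataclasses.fields(CohortSpec)}
        unknown = set(cohort_kw) - known_cohort
        if unknown:
            raise ValueError(f"{path}: unknown cohort keys {sorted(unknown)}")
        if "seed" in raw and "seed" not in cohort_kw:
            cohort_kw["seed"] = int(raw["seed"])
        methods = tuple(MethodSpec(kind=m["name"], value=m.get("value"))
                        for m in raw["methods"]) if "methods" in raw else DEFAULT_METHODS
        adaptive = AdaptiveMethodConfig(**raw.get("adaptive", {}))
        return cls(cohort=CohortSpec(**cohort_kw), methods=methods,
                   reference=raw.get("reference", "perpet"),
                   alpha=float(raw.get("alpha", 0.05)),
                   calibrate=bool(raw.get("calibrate", True)),
                   aov_blood_suv=float(raw.get("aov_blood_suv", 1.8)),
                   adaptive=adaptive)


@dataclass
class StudyResult:
    """Tables produced by one study run."""

    dsc: pd.DataFrame
    summaries: pd.DataFrame
    comparison: Optional[MethodComparison]
    models: Dict[str, ThresholdModel]
    n_failures: int
    seed: int

    def records(self) -> List[DSCRecord]:
        return [DSCRecord(lesion_id=r.lesion_id, method=r.method, dsc=r.dsc)
                for r in self.dsc.itertuples(index=False)]


def _fit_cohort_models(cohort, generating: Dict[str, ThresholdModel]) -> Dict[str, ThresholdModel]:
    """Calibrate per-type models on the cohort's own gold-standard thresholds."""
    pairs = []
    for volume, _truth, rec in cohort:
        smax, _ = suv_max(volume, VOI.full(volume.shape))
        pairs.append(CalibrationPair(suvmax=smax, th_gstd=rec.gold_threshold_pct,
                                     lesion_type=rec.lesion_type, device=rec.device))
    models = {}
    for lesion_type in sorted({p.lesion_type for p in pairs}):
        try:
            models[lesion_type] = fit_threshold_model(pairs, lesion_type)
        except ValueError:
            log.warning("too few %s lesions to calibrate; using generating model",
                        lesion_type)
            models[lesion_type] = generating[lesion_type]
    return models


def run_study(config: RunConfig, out_dir=None) -> StudyResult:
    """Run simulate -> (calibrate) -> segment -> evaluate -> compare.

    Per-lesion failures are logged and skipped (the comparison then runs
    on the complete-case lesions); the failure count is reported in the
    result and reflected in the CLI exit status.
    """
    cohort = generate_cohort(config.cohort)
    log.info("simulated %d lesions (seed %d)", len(cohort), config.cohort.seed)

    if config.calibrate:
        models = _fit_cohort_models(cohort, config.cohort.models)
        for t, m in models.items():
            log.info("calibrated %s model: A=%.2f B=%.2f R2=%s n=%s",
                     t, m.a, m.b, f"{m.r_squared:.3f}" if m.r_squared is not None else "-",
                     m.n_pairs)
    else:
        models = dict(config.cohort.models)

    rows = []
    failures = 0
    for volume, truth, rec in cohort:
        voi = VOI.full(volume.shape)
        try:
            gold = threshold_relative(volume, voi, rec.gold_threshold_pct,
                                      method="gold").mask
        except Exception:
            failures += 1
            log.exception("gold-standard mask failed for %s", rec.lesion_id)
            continue
        for m in config.methods:
            try:
                if m.kind == "perpet":
                    res = segment_perpet_rt(volume, voi, models[rec.lesion_type])
                elif m.kind == "fixed-suv":
                    res = threshold_absolute(volume, voi, float(m.value), method=m.label)
                elif m.kind == "fixed-pct":
                    res = threshold_relative(volume, voi, float(m.value), method=m.label)
                elif m.kind == "aov":
                    res = segment_aov(volume, voi, config.aov_blood_suv)
                elif m.kind == "coa":
                    res = segment_coa(volume, voi, rec.background_suv, config.adaptive)
                elif m.kind == "adt":
                    res = segment_adt(volume, voi, rec.background_suv, config.adaptive)
                else:
                    raise ValueError(f"unknown method kind {m.kind!r}")
                d = dice(res.mask, gold)
                rows.append({
                    "lesion_id": rec.lesion_id, "method": m.label,
                    "lesion_type": rec.lesion_type, "device": rec.device,
                    "dsc": round(d, 6),
                    "agreement": categorize_agreement(d),
                    "threshold_suv": round(res.threshold_suv, 6),
                    "threshold_pct": (round(res.threshold_pct, 6)
                                      if res.threshold_pct is not None else ""),
                    "volume_cc": round(res.volume_cc, 6),
                    "gold_volume_cc": round(gold.volume_cc, 6),
                    "converged": res.converged,
                    "seed": config.cohort.seed,
                    "version": __version__,
                })
            except Exception:
                failures += 1
                log.exception("method %s failed on %s", m.label, rec.lesion_id)

    dsc = pd.DataFrame(rows)
    if dsc.empty:
        raise RuntimeError("study produced no DSC records")
    records = [DSCRecord(lesion_id=r.lesion_id, method=r.method, dsc=r.dsc)
               for r in dsc.itertuples(index=False)]
    methods_present = list(dict.fromkeys(dsc["method"]))
    summaries = pd.DataFrame([summarize(records, m).to_dict() for m in methods_present])

    comparison = None
    complete = dsc.pivot_table(index="lesion_id", columns="method", values="dsc",
                               aggfunc="first").dropna()
    if config.reference in complete.columns and complete.shape[1] >= 2 and len(complete) >= 6:
        paired = [DSCRecord(lesion_id=str(i), method=str(m), dsc=float(complete.loc[i, m]))
                  for i in complete.index for m in complete.columns]
        comparison = compare_methods(paired, reference=config.reference,
                                     alpha=config.alpha)

    result = StudyResult(dsc=dsc, summaries=summaries, comparison=comparison,
                         models=models, n_failures=failures, seed=config.cohort.seed)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _write_outputs(result: StudyResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.dsc.to_csv(out_dir / "dsc.csv", index=False)
    result.summaries.to_csv(out_dir / "method_summaries.csv", index=False)
    # box-whisker coordinates (median, quartile box, decile whiskers) per method
    box_cols = ["method", "d1", "q1", "median", "q3", "d9", "min", "max", "n"]
    result.summaries[box_cols].to_csv(out_dir / "boxwhisker.csv", index=False)
    if result.comparison is not None:
        result.comparison.pairwise.to_csv(out_dir / "comparison.csv", index=False)
    payload = {
        "version": __version__,
        "seed": result.seed,
        "alpha": config.alpha,
        "reference": config.reference,
        "calibrated": config.calibrate,
        "n_failures": result.n_failures,
        "models": {t: m.to_dict() for t, m in result.models.items()},
        "omnibus": None if result.comparison is None else {
            "statistic": result.comparison.omnibus_statistic,
            "p_value": result.comparison.omnibus_p,
        },
    }
    (out_dir / "study.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
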
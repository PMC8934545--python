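"""Cohort selection, confusion metrics and the end-to-end experiment driver.

Implements the functional (visual-field) eligibility machinery -- reliability
limits, the modified OHTS abnormality criteria with a 10-2 pathway, severity
staging by 24-2 mean deviation -- plus sensitivity/specificity bookkeeping for
the vertical midline rule, and `run_experiment`, which drives
simulate -> normative -> regions -> cpmetrics over a synthetic cohort and
produces a structured report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cpmetrics import EyeMetrics, extract_circle_profile, eye_metrics, global_cprnfl, percentile_cutoff
from .errors import ConfigurationError, InsufficientDataError
from .normative import compute_pmap, fit_normative_model
from .regions import RuleConfig, classify_artifact_type, extract_abnormal_regions, vertical_midline_rule
from .simulate import CohortSpec, SimulatedEye, generate_cohort

# p-value categories on the perimetry printouts, most to least significant
P_LEVELS: dict[str, float] = {
    "p<0.001": 0.001,
    "p<0.005": 0.005,
    "p<0.01": 0.01,
    "p<0.05": 0.05,
    "ns": 1.0,
}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention of clinical reports)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class VFRecord:
    """Summary indices of one visual-field test."""

    test_pattern: str  # '24-2' | '10-2'
    MD: float  # dB
    MD_pcat: str = "ns"
    PSD_pcat: str = "ns"
    GHT: str = "within_normal"  # 'within_normal' | 'borderline' | 'outside_normal'
    FP_rate: float = 0.0
    FN_rate: float = 0.0
    fixation_loss_rate: float = 0.0
    abnormal_hemifield: str = "none"  # 'superior' | 'inferior' | 'none'
    date: int = 0

    def validate(self) -> None:
        for name in ("FP_rate", "FN_rate", "fixation_loss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ConfigurationError(f"{name} must lie in [0, 100], got {v}")
        if not np.isfinite(self.MD):
            raise ConfigurationError("MD must be finite")
        for name in ("MD_pcat", "PSD_pcat"):
            if getattr(self, name) not in P_LEVELS:
                raise ConfigurationError(f"unknown p category {getattr(self, name)!r}")


def _pcat_at_most(pcat: str, alpha: float) -> bool:
    return P_LEVELS[pcat] <= alpha


def vf_reliable(record: VFRecord) -> bool:
    """Reliability: FP and FN errors < 15% and fixation losses < 33% (strict)."""
    record.validate()
    return record.FP_rate < 15.0 and record.FN_rate < 15.0 and record.fixation_loss_rate < 33.0


def ohts_abnormal_242(record: VFRecord) -> bool:
    """Abnormal 24-2: GHT outside normal limits and/or PSD with P < 0.05."""
    record.validate()
    return record.GHT == "outside_normal" or _pcat_at_most(record.PSD_pcat, 0.05)


def abnormal_102(record: VFRecord) -> bool:
    """Abnormal 10-2: MD with P <= 0.05 and/or PSD with P <= 0.05."""
    record.validate()
    return _pcat_at_most(record.MD_pcat, 0.05) or _pcat_at_most(record.PSD_pcat, 0.05)


def _has_persistent_run(records: Sequence[VFRecord], abnormal_fn) -> bool:
    """Three consecutive reliable abnormal tests, same non-none hemifield."""
    recs = sorted(records, key=lambda r: r.date)
    deduped: list[VFRecord] = []
    for r in recs:
        if deduped and deduped[-1] == r:
            continue  # identical duplicate (same date and indices)
        deduped.append(r)
    for i in range(len(deduped) - 2):
        window = deduped[i : i + 3]
        if all(vf_reliable(r) and abnormal_fn(r) for r in window):
            hemis = {r.abnormal_hemifield for r in window}
            if len(hemis) == 1 and hemis != {"none"}:
                return True
    return False


def classify_eg_vf(series_242: Sequence[VFRecord], series_102: Sequence[VFRecord]) -> bool:
    """Perimetric-glaucoma call: 3 consecutive abnormal 24-2 *or* 10-2 fields.

    Each run must consist of reliable tests, abnormal under the respective
    criterion, with the abnormality in the same hemifield across the 3 tests.
    """
    if len(series_242) < 3 and len(series_102) < 3:
        raise InsufficientDataError("need at least 3 visual fields in one series")
    return _has_persistent_run(series_242, ohts_abnormal_242) or _has_persistent_run(
        series_102, abnormal_102
    )


def severity_stage(md_242: float) -> str:
    """Severity band from the 24-2 MD: EG / MG / AG.

    Early: MD of -6 dB or better; moderate: between -6 and -12 dB; advanced:
    -12 dB or worse.  Boundary values go to the milder... see docs: exactly
    -6 is EG, exactly -12 is AG.
    """
    if md_242 >= -6.0:
        return "EG"
    if md_242 > -12.0:
        return "MG"
    return "AG"


def eligibility_filter(bcva_denominator: float, spherical_equivalent_d: float) -> bool:
    """Inclusion: BCVA 20/40 or better, refraction within +-6.00 D."""
    return bcva_denominator <= 40.0 and -6.0 <= spherical_equivalent_d <= 6.0


@dataclass
class EyeEvaluation:
    """Per-eye pipeline outcome."""

    eye_id: str
    group_label: str
    necessary_condition: bool
    artifact_type: str
    midline_positive: bool
    metrics: EyeMetrics | None = None
    midline_positive_combined: bool | None = None
    mechanism: str = "none"
    md_242: float | None = None

    def __post_init__(self) -> None:
        if self.midline_positive and not self.necessary_condition:
            raise ConfigurationError("midline-positive implies the necessary condition")


@dataclass
class ConfusionMetrics:
    """Counts and rates of a binary rule against group membership."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.TN / (self.TN + self.FP) if self.TN + self.FP else float("nan")

    @property
    def sensitivity_reported(self) -> float:
        """Sensitivity rounded half-up to the nearest integer, as reported."""
        return round_half_up(self.sensitivity, 0)

    @property
    def specificity_reported(self) -> float:
        """Specificity rounded half-up to one decimal, as reported."""
        return round_half_up(self.specificity, 1)


def confusion_metrics(
    evaluations: Sequence[EyeEvaluation],
    positive_groups: Sequence[str],
    negative_groups: Sequence[str],
) -> ConfusionMetrics:
    """Tally the midline-rule calls against ground-truth group membership."""
    pos, neg = set(positive_groups), set(negative_groups)
    if pos & neg:
        raise ConfigurationError(f"groups {sorted(pos & neg)} appear on both sides")
    tp = fp = tn = fn = 0
    for ev in evaluations:
        if ev.group_label in pos:
            if ev.midline_positive:
                tp += 1
            else:
                fn += 1
        elif ev.group_label in neg:
            if ev.midline_positive:
                fp += 1
            else:
                tn += 1
        else:
            raise ConfigurationError(f"group {ev.group_label!r} in neither set")
    return ConfusionMetrics(TP=tp, FP=fp, TN=tn, FN=fn)


def make_vf_series(eye: SimulatedEye) -> tuple[list[VFRecord], list[VFRecord]]:
    """Three baseline 24-2 and 10-2 summaries consistent with an eye's labels."""
    md = eye.md_242 if eye.md_242 is not None else 0.0
    if eye.group in ("HC", "HC_norm"):
        r242 = [VFRecord("24-2", MD=md, date=d) for d in range(3)]
        r102 = [VFRecord("10-2", MD=md, date=d) for d in range(3)]
        return r242, r102
    hemi = eye.abnormal_hemifield
    r242 = [
        VFRecord(
            "24-2", MD=md, PSD_pcat="p<0.01", GHT="outside_normal",
            abnormal_hemifield=hemi, date=d,
        )
        for d in range(3)
    ]
    r102 = [
        VFRecord("10-2", MD=md / 2.0, MD_pcat="p<0.05", abnormal_hemifield=hemi, date=d)
        for d in range(3)
    ]
    return r242, r102


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Configuration of a full synthetic experiment."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    rule: RuleConfig = field(default_factory=RuleConfig)
    red_threshold: float = 1.0
    yellow_threshold: float = 5.0
    reference_group: str = "HC_norm"
    min_reference: int = 20
    cutoff_percent: float = 5.0
    make_figures: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        from .simulate import AnatomyDistribution

        cfg = cls()
        d = dict(d)
        try:
            if "cohort" in d:
                c = dict(d.pop("cohort"))
                if "anatomy" in c:
                    c["anatomy"] = AnatomyDistribution(**c["anatomy"])
                cfg.cohort = CohortSpec(**c)
            if "rule" in d:
                cfg.rule = RuleConfig(**d.pop("rule"))
            for key, value in d.items():
                if not hasattr(cfg, key):
                    raise ConfigurationError(f"unknown experiment config key {key!r}")
                setattr(cfg, key, value)
        except TypeError as exc:
            raise ConfigurationError(f"invalid experiment config: {exc}") from exc
        cfg.rule.validate()
        cfg.cohort.validate()
        return cfg


@dataclass
class ExperimentReport:
    """Structured outcome of one synthetic experiment."""

    seed: int
    config: ExperimentConfig
    evaluations: list[EyeEvaluation]
    confusion: ConfusionMetrics
    confusion_combined: ConfusionMetrics | None
    sensitivity_by_group: dict
    artifact_frequency: dict  # healthy group -> fraction meeting necessary condition
    artifact_type_table: dict  # healthy group -> {arcuate, temporal_Q, both} counts
    g_cprnfl_cutoff: float
    g_cprnfl_by_group: dict
    eyes_by_gcprnfl: list  # eye ids ordered thinnest -> thickest

    def to_dict(self) -> dict:
        conf = {
            "TP": self.confusion.TP, "FP": self.confusion.FP,
            "TN": self.confusion.TN, "FN": self.confusion.FN,
            "sensitivity_pct": self.confusion.sensitivity_reported,
            "specificity_pct": self.confusion.specificity_reported,
        }
        combined = None
        if self.confusion_combined is not None:
            cc = self.confusion_combined
            combined = {
                "TP": cc.TP, "FP": cc.FP, "TN": cc.TN, "FN": cc.FN,
                "sensitivity_pct": cc.sensitivity_reported,
                "specificity_pct": cc.specificity_reported,
            }
        return {
            "seed": self.seed,
            "rule": dataclasses.asdict(self.config.rule),
            "thresholds": {
                "red_percent": self.config.red_threshold,
                "yellow_percent": self.config.yellow_threshold,
            },
            "group_sizes": {g: int(n) for g, n in self.config.cohort.group_sizes.items()},
            "midline_rule": conf,
            "midline_rule_combined": combined,
            "sensitivity_by_group": self.sensitivity_by_group,
            "artifact_frequency": self.artifact_frequency,
            "artifact_type_table": self.artifact_type_table,
            "g_cprnfl_cutoff_um": self.g_cprnfl_cutoff,
            "eyes_by_gcprnfl": self.eyes_by_gcprnfl,
        }

    def eye_table(self) -> pd.DataFrame:
        rows = []
        for ev in self.evaluations:
            rows.append(
                {
                    "eye_id": ev.eye_id,
                    "group": ev.group_label,
                    "mechanism": ev.mechanism,
                    "md_242": ev.md_242,
                    "necessary_condition": ev.necessary_condition,
                    "artifact_type": ev.artifact_type,
                    "midline_positive": ev.midline_positive,
                    "midline_positive_combined": ev.midline_positive_combined,
                    "g_cprnfl_um": ev.metrics.g_cprnfl if ev.metrics else None,
                    "percentile_vs_norm": ev.metrics.percentile_vs_norm if ev.metrics else None,
                    "below_5th": ev.metrics.below_5th if ev.metrics else None,
                }
            )
        return pd.DataFrame(rows)


HEALTHY_GROUPS = ("HC_norm", "HC")
PATIENT_GROUPS = ("EG_VF", "MG", "AG")


def run_experiment(
    config: ExperimentConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ExperimentReport:
    """Run the full synthetic pipeline and assemble the report.

    Generates the cohort, fits the normative model(s) on the reference group,
    converts every eye to a probability map, applies the necessary condition,
    artifact taxonomy and vertical midline rule (RNFL-only and, when GCL+
    maps are simulated, the combined variant), computes circumpapillary
    metrics and the reference 5th-percentile cutoff, and tallies confusion
    metrics.  Deterministic given ``seed``.
    """
    config = config or ExperimentConfig()
    config.rule.validate()
    cohort = generate_cohort(config.cohort, seed)
    by_group: dict[str, list[SimulatedEye]] = {}
    for eye in cohort:
        by_group.setdefault(eye.group, []).append(eye)

    ref_group = config.reference_group
    if ref_group not in by_group:
        ref_group = next((g for g in HEALTHY_GROUPS if g in by_group), None)
    if ref_group is None:
        raise ConfigurationError("cohort contains no healthy reference group")
    reference = by_group[ref_group]
    model = fit_normative_model([e.thickness for e in reference], config.min_reference)
    gcl_model = None
    if all(e.gcl is not None for e in reference) and reference[0].gcl is not None:
        gcl_model = fit_normative_model([e.gcl for e in reference], config.min_reference)

    evaluations: list[EyeEvaluation] = []
    g_list: list[float] = []
    g_values: dict[str, list[float]] = {}
    for eye in cohort:
        pmap = compute_pmap(eye.thickness, model, config.red_threshold, config.yellow_threshold)
        regs = extract_abnormal_regions(pmap, config.rule)
        necessary = any(r.touches_temporal_disc for r in regs)
        art_type = classify_artifact_type(regs, pmap, config.rule)
        positive = vertical_midline_rule(pmap, config.rule) == "positive"
        combined: bool | None = None
        if gcl_model is not None and eye.gcl is not None:
            gcl_pmap = compute_pmap(eye.gcl, gcl_model, config.red_threshold, config.yellow_threshold)
            combined = vertical_midline_rule(pmap, config.rule, gcl_pmap=gcl_pmap) == "positive"
        g = global_cprnfl(extract_circle_profile(eye.thickness))
        evaluations.append(
            EyeEvaluation(
                eye_id=eye.eye_id,
                group_label=eye.group,
                necessary_condition=necessary,
                artifact_type=art_type,
                midline_positive=positive,
                midline_positive_combined=combined,
                mechanism=eye.mechanism,
                md_242=eye.md_242,
            )
        )
        g_list.append(g)
        g_values.setdefault(eye.group, []).append(g)

    reference_g = g_values[ref_group]
    cutoff = percentile_cutoff(reference_g, config.cutoff_percent)
    for ev, g in zip(evaluations, g_list):
        ev.metrics = eye_metrics(g, reference_g, config.cutoff_percent)

    pos_groups = [g for g in PATIENT_GROUPS if g in by_group]
    neg_groups = [g for g in HEALTHY_GROUPS if g in by_group]
    conf = confusion_metrics(
        [e for e in evaluations if e.group_label in pos_groups + neg_groups],
        pos_groups, neg_groups,
    ) if pos_groups and neg_groups else ConfusionMetrics(0, 0, 0, 0)
    conf_combined = None
    if gcl_model is not None and pos_groups and neg_groups:
        combined_evals = [
            dataclasses.replace(
                e,
                midline_positive=bool(e.midline_positive_combined),
                necessary_condition=e.necessary_condition or bool(e.midline_positive_combined),
            )
            for e in evaluations
            if e.group_label in pos_groups + neg_groups
        ]
        conf_combined = confusion_metrics(combined_evals, pos_groups, neg_groups)

    sens_by_group: dict[str, float] = {}
    for g in pos_groups:
        evs = [e for e in evaluations if e.group_label == g]
        hits = sum(e.midline_positive for e in evs)
        sens_by_group[g] = round_half_up(100.0 * hits / len(evs), 0) if evs else float("nan")
    mgag = [e for e in evaluations if e.group_label in ("MG", "AG")]
    if mgag:
        sens_by_group["MG_AG"] = round_half_up(
            100.0 * sum(e.midline_positive for e in mgag) / len(mgag), 0
        )

    artifact_freq: dict[str, float] = {}
    type_table: dict[str, dict[str, int]] = {}
    for g in neg_groups:
        evs = [e for e in evaluations if e.group_label == g]
        artifact_freq[g] = float(sum(e.necessary_condition for e in evs) / len(evs))
        type_table[g] = {
            t: sum(e.artifact_type == t for e in evs) for t in ("arcuate", "temporal_Q", "both")
        }

    order = sorted(
        (ev for ev in evaluations), key=lambda e: e.metrics.g_cprnfl if e.metrics else np.inf
    )
    report = ExperimentReport(
        seed=seed,
        config=config,
        evaluations=evaluations,
        confusion=conf,
        confusion_combined=conf_combined,
        sensitivity_by_group=sens_by_group,
        artifact_frequency=artifact_freq,
        artifact_type_table=type_table,
        g_cprnfl_cutoff=cutoff,
        g_cprnfl_by_group={g: list(map(float, v)) for g, v in g_values.items()},
        eyes_by_gcprnfl=[ev.eye_id for ev in order],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        report.eye_table().to_csv(out / "eyes.csv", index=False)
        if config.make_figures:
            from .plotting import gcprnfl_histograms

            gcprnfl_histograms(report.g_cprnfl_by_group, cutoff, out / "gcprnfl_histograms.png")
    return report
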
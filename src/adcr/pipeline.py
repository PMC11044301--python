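"""End-to-end study orchestration: quantify, split, derive, validate, report.

Replicates a derivation / internal-validation / external-validation
design for a threshold marker: one site's subjects are randomly split
70/30 into a derivation cohort (where zero-false-positive-rate cutoffs
are derived) and an internal validation cohort; a second site forms the
external validation cohort, where the frozen rules are re-applied.

Outputs mirror the standard reporting tables of diagnostic-accuracy
studies: a per-threshold derivation table (AUC, cutoff, metrics, paired
DeLong p versus the reference threshold), applied-cutoff tables per
cohort, a two-rule comparison table with raw confusion counts, a
baseline-characteristics table, and cross-cohort DeLong comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import stats as dstats
from .quantify import (
    ADCRProfile,
    ThresholdGrid,
    VoxelFilter,
    adc_r_profile,
    extract_brain_values,
    load_adc_volume,
)

logger = logging.getLogger("adcr")

__all__ = [
    "StudyConfig",
    "SubjectRecord",
    "ValidationReport",
    "quantify_manifest",
    "split_cohort",
    "derive_cutoffs",
    "validate_cutoffs",
    "external_rule_comparison",
    "baseline_table",
    "cross_cohort_delong",
    "run_study",
]

COHORTS = ("derivation", "internal_validation", "external_validation")

CONTINUOUS_COVARIATES = ("age", "no_flow_time_min", "low_flow_time_min")
CATEGORICAL_COVARIATES = ("female_sex", "witnessed_arrest", "shockable_rhythm")


@dataclass(frozen=True)
class StudyConfig:
    """Study-level knobs: split, grids, reference threshold, significance level."""

    split_fraction: float = 0.70
    split_seed: int = 0
    grid: ThresholdGrid = field(default_factory=ThresholdGrid.default)
    filter: VoxelFilter = field(default_factory=VoxelFilter)
    reference_threshold: float = 600.0
    alpha: float = 0.05
    scale_factor: float = 1.0
    stratified_split: bool = False
    validation_thresholds: tuple[float, ...] = (450.0, 500.0, 550.0, 600.0, 650.0)
    comparison_threshold: float = 650.0
    comparison_fixed_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.reference_threshold not in self.grid.thresholds:
            raise ValueError("reference_threshold must be on the threshold grid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "split_fraction",
            "split_seed",
            "reference_threshold",
            "alpha",
            "scale_factor",
            "stratified_split",
            "comparison_threshold",
            "comparison_fixed_cutoff",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "grid" in raw:
            g = raw["grid"]
            kwargs["grid"] = ThresholdGrid.from_range(g["start"], g["stop"], g["step"])
        if "filter" in raw:
            f = raw["filter"]
            kwargs["filter"] = VoxelFilter(lower=f["lower"], upper=f["upper"])
        if "validation_thresholds" in raw:
            kwargs["validation_thresholds"] = tuple(raw["validation_thresholds"])
        return cls(**kwargs)


@dataclass
class SubjectRecord:
    subject_id: str
    cpc: int
    profile: ADCRProfile
    cohort: str = "unassigned"
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cpc not in (1, 2, 3, 4, 5):
            raise ValueError(f"{self.subject_id}: CPC must be an integer 1-5, got {self.cpc}")

    @property
    def outcome_poor(self) -> bool:
        return self.cpc >= 3


def marker_values(records: Sequence[SubjectRecord], x: float) -> np.ndarray:
    return np.array([r.profile[x] for r in records], dtype=float)


def outcome_labels(records: Sequence[SubjectRecord]) -> np.ndarray:
    return np.array([r.outcome_poor for r in records], dtype=bool)


def _split_groups(records: Sequence[SubjectRecord], x: float) -> tuple[np.ndarray, np.ndarray]:
    v = marker_values(records, x)
    y = outcome_labels(records)
    return v[y], v[~y]  # (poor, good)


# ---------------------------------------------------------------------------
# quantification over a manifest


def quantify_manifest(
    manifest_path: str | Path,
    config: StudyConfig = StudyConfig(),
) -> list[SubjectRecord]:
    """Load every subject in a cohort manifest and compute its ADC-R profile.

    Paths in the manifest resolve relative to the manifest's directory.
    Subjects with a missing CPC are excluded with a logged count; any
    image error aborts with the subject id in the message.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "adc_path", "outcome_cpc", "cohort"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    covariate_cols = [
        c for c in manifest.columns
        if c in CONTINUOUS_COVARIATES + CATEGORICAL_COVARIATES
    ]
    records: list[SubjectRecord] = []
    n_missing_cpc = 0
    for row in manifest.itertuples(index=False):
        if pd.isna(row.outcome_cpc):
            n_missing_cpc += 1
            continue
        sid = str(row.subject_id)
        mask_path = getattr(row, "mask_path", None)
        try:
            vol = load_adc_volume(
                base / row.adc_path,
                scale_factor=config.scale_factor,
                mask_path=(base / mask_path) if isinstance(mask_path, str) else None,
            )
            values = extract_brain_values(vol, fallback_segmentation=vol.mask is None)
            profile = adc_r_profile(values, config.grid, config.filter)
        except Exception as exc:
            raise RuntimeError(f"quantification failed for subject {sid}: {exc}") from exc
        logger.debug(
            "%s: denominator=%d excluded_low=%d excluded_high=%d",
            sid, profile.denominator_count, profile.excluded_low, profile.excluded_high,
        )
        records.append(
            SubjectRecord(
                subject_id=sid,
                cpc=int(row.outcome_cpc),
                profile=profile,
                cohort=str(row.cohort),
                covariates={c: getattr(row, c) for c in covariate_cols},
            )
        )
    if n_missing_cpc:
        logger.warning("excluded %d subjects with missing CPC outcome", n_missing_cpc)
    return records


# ---------------------------------------------------------------------------
# cohort splitting


def split_cohort(
    records: Sequence[SubjectRecord],
    config: StudyConfig = StudyConfig(),
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Randomly split unassigned subjects into derivation / internal validation.

    Simple random sampling (unstratified by default): round(n * fraction)
    subjects go to derivation, the rest to internal validation,
    deterministically under ``config.split_seed``.
    """
    recs = list(records)
    if any(r.cohort != "unassigned" for r in recs):
        raise ValueError("split_cohort requires all subjects to be unassigned")
    n = len(recs)
    if n < 10:
        raise ValueError(f"refusing to split a cohort of {n} subjects (< 10)")
    rng = np.random.default_rng(config.split_seed)

    def _assign(indices: np.ndarray, n_der: int) -> None:
        perm = rng.permutation(indices)
        for i in perm[:n_der]:
            recs[i].cohort = "derivation"
        for i in perm[n_der:]:
            recs[i].cohort = "internal_validation"

    if config.stratified_split:
        y = outcome_labels(recs)
        for group in (np.flatnonzero(y), np.flatnonzero(~y)):
            _assign(group, int(round(config.split_fraction * group.size)))
    else:
        _assign(np.arange(n), int(round(config.split_fraction * n)))
    derivation = [r for r in recs if r.cohort == "derivation"]
    internal = [r for r in recs if r.cohort == "internal_validation"]
    return derivation, internal


# ---------------------------------------------------------------------------
# derivation and validation tables


def _fmt_pct(value: float, ci: tuple[float, float]) -> str:
    if np.isnan(value):
        return "NA"
    return f"{value:.1f} ({ci[0]:.1f}-{ci[1]:.1f})"


def _fmt_auc(auc: float, ci: tuple[float, float]) -> str:
    return f"{auc:.3f} ({ci[0]:.3f}-{ci[1]:.3f})"


def _performance_row(perf: dstats.DiagnosticPerformance) -> dict:
    return {
        "sensitivity": perf.sensitivity,
        "sensitivity_lo": perf.sensitivity_ci[0],
        "sensitivity_hi": perf.sensitivity_ci[1],
        "specificity": perf.specificity,
        "specificity_lo": perf.specificity_ci[0],
        "specificity_hi": perf.specificity_ci[1],
        "ppv": perf.ppv,
        "ppv_lo": perf.ppv_ci[0],
        "ppv_hi": perf.ppv_ci[1],
        "npv": perf.npv,
        "npv_lo": perf.npv_ci[0],
        "npv_hi": perf.npv_ci[1],
        "sensitivity_display": _fmt_pct(perf.sensitivity, perf.sensitivity_ci),
        "specificity_display": _fmt_pct(perf.specificity, perf.specificity_ci),
        "ppv_display": _fmt_pct(perf.ppv, perf.ppv_ci),
        "npv_display": _fmt_pct(perf.npv, perf.npv_ci),
    }


@dataclass(frozen=True)
class DerivedThreshold:
    """Everything derived for one grid threshold on the derivation cohort."""

    threshold_x: float
    roc: dstats.ROCAnalysis
    cutoff: dstats.ZeroFPRCutoff
    performance: dstats.DiagnosticPerformance
    delong_vs_reference_p: float  # NaN for the reference row itself


def derive_cutoffs(
    derivation: Sequence[SubjectRecord],
    config: StudyConfig = StudyConfig(),
) -> dict[float, DerivedThreshold]:
    """Per-threshold ROC, zero-FPR cutoff, metrics, and paired DeLong p
    against the reference threshold, on the derivation cohort only."""
    y = outcome_labels(derivation)
    if y.all() or not y.any():
        raise ValueError("derivation cohort must contain both outcomes")
    ref_x = config.reference_threshold
    ref_values = marker_values(derivation, ref_x)
    out: dict[float, DerivedThreshold] = {}
    for x in config.grid:
        poor, good = _split_groups(derivation, x)
        roc = dstats.roc_analysis(poor, good)
        cutoff = dstats.zero_fpr_cutoff(good, poor, threshold_x=x)
        counts = dstats.confusion_at_rule(marker_values(derivation, x), y, cutoff.cutoff_value)
        perf = dstats.diagnostic_metrics(counts)
        if x == ref_x:
            p = float("nan")
        else:
            p = dstats.delong_test(
                marker_values(derivation, x), ref_values, y, design="paired"
            ).p
        out[float(x)] = DerivedThreshold(
            threshold_x=float(x), roc=roc, cutoff=cutoff, performance=perf,
            delong_vs_reference_p=p,
        )
    return out


def derivation_table(derived: Mapping[float, DerivedThreshold], config: StudyConfig) -> pd.DataFrame:
    rows = []
    for x, d in derived.items():
        row = {
            "threshold_x": x,
            "auc": d.roc.auc,
            "auc_lo": d.roc.auc_ci[0],
            "auc_hi": d.roc.auc_ci[1],
            "auc_display": _fmt_auc(d.roc.auc, d.roc.auc_ci),
            "auc_band": dstats.auc_band(d.roc.auc),
            "cutoff_value": d.cutoff.cutoff_value,
            "cutoff_display": f"> {d.cutoff.cutoff_value:.1f}",
        }
        row.update(_performance_row(d.performance))
        is_ref = x == config.reference_threshold
        row["delong_p_vs_reference"] = d.delong_vs_reference_p
        row["delong_display"] = "Reference" if is_ref else _fmt_p(d.delong_vs_reference_p)
        rows.append(row)
    frame = pd.DataFrame(rows)
    # reference row first, as in the conventional table layout
    return pd.concat(
        [
            frame[frame["threshold_x"] == config.reference_threshold],
            frame[frame["threshold_x"] != config.reference_threshold],
        ],
        ignore_index=True,
    )


def _fmt_p(p: float) -> str:
    if np.isnan(p):
        return "NA"
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def validate_cutoffs(
    derived: Mapping[float, DerivedThreshold],
    cohort: Sequence[SubjectRecord],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Apply frozen derivation rules to a validation cohort.

    Specificity may now fall below 100%.  The cohort's own AUC (with CI)
    is recomputed for cross-cohort comparisons.
    """
    y = outcome_labels(cohort)
    xs = [float(x) for x in (thresholds if thresholds is not None else derived.keys())]
    rows = []
    for x in xs:
        if x not in derived:
            raise ValueError(f"threshold {x} missing from derived cutoffs")
        d = derived[x]
        if x not in cohort[0].profile.values:
            raise ValueError(f"threshold {x} missing from cohort profiles")
        v = marker_values(cohort, x)
        if y.any() and not y.all():
            roc = dstats.roc_analysis(v[y], v[~y])
            auc_fields = {
                "auc": roc.auc,
                "auc_lo": roc.auc_ci[0],
                "auc_hi": roc.auc_ci[1],
                "auc_display": _fmt_auc(roc.auc, roc.auc_ci),
            }
        else:  # single-outcome cohort: rule metrics remain, AUC undefined
            auc_fields = {"auc": np.nan, "auc_lo": np.nan, "auc_hi": np.nan,
                          "auc_display": "NA"}
        counts = dstats.confusion_at_rule(v, y, d.cutoff.cutoff_value)
        perf = dstats.diagnostic_metrics(counts)
        row = {
            "threshold_x": x,
            "cutoff_value": d.cutoff.cutoff_value,
            "cutoff_display": f"> {d.cutoff.cutoff_value:.1f}",
        }
        row.update(auc_fields)
        row.update(_performance_row(perf))
        rows.append(row)
    return pd.DataFrame(rows)


def external_rule_comparison(
    cohorts: Mapping[str, Sequence[SubjectRecord]],
    derived: Mapping[float, DerivedThreshold],
    config: StudyConfig = StudyConfig(),
) -> pd.DataFrame:
    """Compare a fixed literature rule against the derived rule at one
    threshold (default ADC-R(650): "> 10%" vs the derived "> c"), with raw
    confusion counts, in every cohort."""
    x = float(config.comparison_threshold)
    if x not in derived:
        raise ValueError(f"comparison threshold {x} not among derived cutoffs")
    rules = [
        (f"> {config.comparison_fixed_cutoff:g}%", config.comparison_fixed_cutoff),
        (f"> {derived[x].cutoff.cutoff_value:.1f}%", derived[x].cutoff.cutoff_value),
    ]
    rows = []
    for cohort_name, records in cohorts.items():
        y = outcome_labels(records)
        v = marker_values(records, x)
        for rule_label, c in rules:
            counts = dstats.confusion_at_rule(v, y, c)
            perf = dstats.diagnostic_metrics(counts)
            row = {
                "cohort": cohort_name,
                "rule": rule_label,
                "threshold_x": x,
                "fp": counts.fp,
                "fn": counts.fn,
                "tp": counts.tp,
                "tn": counts.tn,
            }
            row.update(_performance_row(perf))
            rows.append(row)
    return pd.DataFrame(rows)


def cross_cohort_delong(
    cohorts: Mapping[str, Sequence[SubjectRecord]],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Unpaired DeLong comparisons of each validation cohort against the
    derivation cohort, per threshold."""
    rows = []
    der = cohorts["derivation"]
    y_der = outcome_labels(der)
    for x in thresholds:
        v_der = marker_values(der, x)
        for other in ("internal_validation", "external_validation"):
            if other not in cohorts or not len(cohorts[other]):
                continue
            recs = cohorts[other]
            try:
                res = dstats.delong_test(
                    v_der,
                    marker_values(recs, x),
                    y_der,
                    design="unpaired",
                    labels_b=outcome_labels(recs),
                )
            except ValueError as exc:
                logger.warning("DeLong derivation vs %s at x=%g skipped: %s", other, x, exc)
                continue
            rows.append(
                {
                    "threshold_x": float(x),
                    "comparison": f"derivation_vs_{other}",
                    "auc_derivation": res.auc_a,
                    "auc_other": res.auc_b,
                    "z": res.z,
                    "p": res.p,
                    "p_display": _fmt_p(res.p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# baseline characteristics


def baseline_table(
    cohorts: Mapping[str, Sequence[SubjectRecord]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Baseline-characteristics table across the three cohorts.

    Continuous covariates: median (IQR) per cohort, Kruskal-Wallis p,
    and Bonferroni-adjusted pairwise Mann-Whitney flags versus the
    derivation cohort.  Categorical (binary) covariates: count (%) per
    cohort with a chi-square / Fisher p.  Missing covariates are skipped
    with a logged warning.
    """
    names = [c for c in COHORTS if c in cohorts and len(cohorts[c])]
    if len(names) < 2:
        raise ValueError("baseline table requires at least two cohorts")
    rows = []

    def _series(cov: str, cohort: str) -> np.ndarray:
        vals = [r.covariates.get(cov) for r in cohorts[cohort]]
        return np.array([v for v in vals if v is not None and not pd.isna(v)], dtype=float)

    available = set.intersection(*(set(r.covariates) for n in names for r in cohorts[n]))
    for cov in CONTINUOUS_COVARIATES:
        if cov not in available:
            logger.warning("baseline covariate %r missing; skipped", cov)
            continue
        series = {n: _series(cov, n) for n in names}
        row: dict = {"variable": cov, "type": "continuous"}
        for n in names:
            s = series[n]
            q1, med, q3 = np.percentile(s, [25, 50, 75])
            row[n] = f"{med:.1f} ({q1:.1f}-{q3:.1f})"
        if len(names) == 3:
            kw = dstats.kruskal_wallis_with_posthoc([series[n] for n in names], alpha=alpha)
            row["p"] = kw.p
            # pairwise indices follow the cohort order: (0,1)=der vs int, (0,2)=der vs ext
            for pc in kw.pairwise:
                if 0 in pc.groups:
                    other = names[pc.groups[1] if pc.groups[0] == 0 else pc.groups[0]]
                    row[f"flag_vs_{other}"] = bool(pc.significant)
        else:
            row["p"] = dstats.mann_whitney(series[names[0]], series[names[1]]).p
        rows.append(row)
    for cov in CATEGORICAL_COVARIATES:
        if cov not in available:
            logger.warning("baseline covariate %r missing; skipped", cov)
            continue
        series = {n: _series(cov, n) for n in names}
        row = {"variable": cov, "type": "categorical"}
        table = []
        for n in names:
            s = series[n]
            k = int(s.sum())
            row[n] = f"{k} ({100.0 * k / s.size:.1f})"  # per-cohort column percentage
            table.append([k, s.size - k])
        try:
            row["p"] = dstats.categorical_tests(np.array(table).T).p
        except ValueError:
            row["p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end study


@dataclass
class ValidationReport:
    cohort_sizes: dict[str, int]
    table1_baseline: pd.DataFrame | None
    table2_derivation: pd.DataFrame
    table3_applied: pd.DataFrame
    table4_rules: pd.DataFrame
    fig3_delong: pd.DataFrame
    profiles: pd.DataFrame
    derived: dict[float, DerivedThreshold]


def records_to_profile_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "cohort": r.cohort, "outcome_cpc": r.cpc}
        row.update({f"adc_r_{int(x)}": v for x, v in r.profile.values.items()})
        row["denominator_count"] = r.profile.denominator_count
        row["excluded_low"] = r.profile.excluded_low
        row["excluded_high"] = r.profile.excluded_high
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    manifest_path: str | Path,
    config: StudyConfig = StudyConfig(),
    out_dir: str | Path | None = None,
) -> ValidationReport:
    """Quantify -> split -> derive -> validate -> report, end to end.

    Subjects whose manifest cohort is ``external_validation`` form the
    external cohort; all ``unassigned`` subjects are split 70/30.  When
    ``out_dir`` is given, the report tables are written as CSV alongside
    a human-readable summary; reruns with identical seeds are
    byte-identical.
    """
    records = quantify_manifest(manifest_path, config)
    internal_site = [r for r in records if r.cohort == "unassigned"]
    external = [r for r in records if r.cohort == "external_validation"]
    unknown = [r for r in records if r.cohort not in ("unassigned", "external_validation")]
    if unknown:
        raise ValueError(
            f"unexpected cohort labels in manifest: {sorted({r.cohort for r in unknown})}"
        )
    derivation, internal = split_cohort(internal_site, config)
    for r in external:
        r.cohort = "external_validation"
    cohorts: dict[str, list[SubjectRecord]] = {
        "derivation": derivation,
        "internal_validation": internal,
        "external_validation": external,
    }
    sizes = {k: len(v) for k, v in cohorts.items()}
    logger.info("cohort sizes: %s", sizes)

    derived = derive_cutoffs(derivation, config)
    table2 = derivation_table(derived, config)
    applied = []
    for name in ("derivation", "internal_validation", "external_validation"):
        if not cohorts[name]:
            continue
        t = validate_cutoffs(derived, cohorts[name], config.validation_thresholds)
        t.insert(0, "cohort", name)
        applied.append(t)
    table3 = pd.concat(applied, ignore_index=True)
    table4 = external_rule_comparison(
        {k: v for k, v in cohorts.items() if v}, derived, config
    )
    fig3 = cross_cohort_delong(cohorts, config.validation_thresholds)
    have_covariates = all(r.covariates for c in cohorts.values() for r in c)
    table1 = baseline_table(cohorts, alpha=config.alpha) if have_covariates else None
    profiles = records_to_profile_frame(
        [r for name in COHORTS for r in cohorts.get(name, [])]
    )

    report = ValidationReport(
        cohort_sizes=sizes,
        table1_baseline=table1,
        table2_derivation=table2,
        table3_applied=table3,
        table4_rules=table4,
        fig3_delong=fig3,
        profiles=profiles,
        derived=derived,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir), config)
    return report


def _write_report(report: ValidationReport, out: Path, config: StudyConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.table2_derivation.to_csv(out / "table2_derivation.csv", index=False)
    report.table3_applied.to_csv(out / "table3_applied.csv", index=False)
    report.table4_rules.to_csv(out / "table4_rules.csv", index=False)
    report.fig3_delong.to_csv(out / "fig3_delong.csv", index=False)
    report.profiles.to_csv(out / "profiles.csv", index=False)
    if report.table1_baseline is not None:
        report.table1_baseline.to_csv(out / "table1_baseline.csv", index=False)
    ref = report.derived[config.reference_threshold]
    lines = [
        "Study summary",
        "=============",
        "Cohort sizes: "
        + ", ".join(f"{k}={v}" for k, v in report.cohort_sizes.items()),
        f"Reference threshold x = {config.reference_threshold:g}:",
        f"  derivation AUC {ref.roc.auc:.3f} "
        f"({ref.roc.auc_ci[0]:.3f}-{ref.roc.auc_ci[1]:.3f}) [{dstats.auc_band(ref.roc.auc)}]",
        f"  zero-FPR cutoff: ADC-R({config.reference_threshold:g}) > "
        f"{ref.cutoff.cutoff_value:.1f}%",
        f"  derivation sensitivity at 100% specificity: "
        f"{100.0 * ref.cutoff.derivation_sensitivity:.1f}%",
        "",
    ]
    (out / "summary.txt").write_text("\n".join(lines))
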
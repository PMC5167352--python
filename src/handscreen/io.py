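"""Cohort file round-tripping and the end-to-end analysis pipeline.

CSV dialect: UTF-8, comma-separated, ``.`` decimal, booleans written as
``true``/``false``, one participant per row, per-test Z-scores in fixed
``z_<testname>`` columns and questionnaire items in ``dnaa_q01`` ...
``dnaa_q22``.  Every output artefact embeds the seed and a hash of the
configuration so a run can be reproduced exactly from its own outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import frascati, normative, prevalence, screen_eval
from ._util import config_hash, round_half_up
from .frascati import DNAAResponses, NeuropsychProfile, TestScore
from .ihds import IHDSResult, on_grid
from .synthetic_cohort import (
    BATTERY,
    CohortConfig,
    ParticipantRecord,
    generate_cohort,
    sample_evaluated,
)

__all__ = [
    "CohortSchemaError",
    "CohortReadError",
    "PipelineConfig",
    "PipelineResult",
    "cohort_to_frame",
    "frame_to_records",
    "write_cohort",
    "read_cohort",
    "run_pipeline",
    "write_bundle",
    "DEFAULT_DOMAIN_MAP",
]

DEFAULT_DOMAIN_MAP: dict[str, frozenset[str]] = {name: doms for name, doms in BATTERY}

_REQUIRED_COLUMNS = (
    "id",
    "hiv_positive",
    "age",
    "education",
    "ihds_motor",
    "ihds_psychomotor",
    "ihds_memory",
    "ihds_total",
    "stratum",
    "evaluated",
)
_CLINICAL_COLUMNS = ("months_since_diagnosis", "cd4_current", "cd4_nadir", "on_art")


class CohortSchemaError(ValueError):
    """The cohort file is missing a required column."""


class CohortReadError(ValueError):
    """One or more rows violate the cohort contract."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"row {r}: {m}" for r, m in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid row(s): {lines}{more}")


def _bool_out(v: Optional[bool]) -> str | None:
    return None if v is None else ("true" if v else "false")


def cohort_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {
            "id": rec.id,
            "hiv_positive": _bool_out(rec.hiv_positive),
            "age": rec.age,
            "education": rec.education,
            "months_since_diagnosis": rec.months_since_diagnosis,
            "cd4_current": rec.cd4_current,
            "cd4_nadir": rec.cd4_nadir,
            "on_art": _bool_out(rec.on_art),
            "ihds_motor": rec.ihds.motor_speed,
            "ihds_psychomotor": rec.ihds.psychomotor_speed,
            "ihds_memory": rec.ihds.memory_recall,
            "ihds_total": rec.ihds.total,
            "stratum": rec.stratum,
            "true_class": rec.true_class,
            "evaluated": _bool_out(rec.evaluated),
        }
        z = {t.name: t.z for t in rec.profile.tests} if rec.profile else {}
        for name, _ in BATTERY:
            row[f"z_{name}"] = z.get(name)
        for i in range(22):
            row[f"dnaa_q{i + 1:02d}"] = (
                _bool_out(rec.dnaa.answers[i]) if rec.dnaa else None
            )
        row["diagnosis"] = rec.diagnosis.label if rec.diagnosis else None
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def _parse_bool(v, row: int, col: str):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, str) and v.lower() in ("true", "false"):
        return v.lower() == "true"
    raise ValueError(f"column {col!r}: {v!r} is not an ISO boolean")


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def frame_to_records(
    df: pd.DataFrame,
    domain_map: Optional[Mapping[str, frozenset[str]]] = None,
    key_items: Optional[frozenset[int]] = None,
) -> list[ParticipantRecord]:
    """Validate a cohort table and rebuild participant records.

    Row-level problems (off-grid IHDS values, evaluated rows without
    Z-scores, malformed booleans) are collected and reported together with
    1-based data row numbers in a :class:`CohortReadError`.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    domain_map = dict(domain_map or DEFAULT_DOMAIN_MAP)
    key_items = key_items or frozenset(range(1, 10))
    z_cols = [c for c in df.columns if c.startswith("z_")]

    records: list[ParticipantRecord] = []
    errors: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            for col in ("ihds_motor", "ihds_psychomotor", "ihds_memory", "ihds_total"):
                if not on_grid(float(row[col])):
                    raise ValueError(
                        f"column {col!r}: value {row[col]!r} off the 0.5 grid"
                    )
            ihds = IHDSResult(
                float(row["ihds_motor"]),
                float(row["ihds_psychomotor"]),
                float(row["ihds_memory"]),
                float(row["ihds_total"]),
            )
            evaluated = _parse_bool(row["evaluated"], pos, "evaluated")
            profile = dnaa = None
            if evaluated:
                tests = []
                for col in z_cols:
                    name = col[2:]
                    if name not in domain_map:
                        continue
                    if _is_missing(row[col]):
                        raise ValueError(f"evaluated row lacks Z-score {col!r}")
                    tests.append(
                        TestScore(name=name, z=float(row[col]), domains=domain_map[name])
                    )
                if not tests:
                    raise ValueError("evaluated row has no Z-score columns")
                profile = NeuropsychProfile(tuple(tests))
                answers = []
                for i in range(22):
                    col = f"dnaa_q{i + 1:02d}"
                    if col not in df.columns or _is_missing(row[col]):
                        raise ValueError(f"evaluated row lacks {col!r}")
                    answers.append(_parse_bool(row[col], pos, col))
                dnaa = DNAAResponses(tuple(answers), key_items)
            rec = ParticipantRecord(
                id=str(row["id"]),
                hiv_positive=_parse_bool(row["hiv_positive"], pos, "hiv_positive"),
                age=int(row["age"]),
                education=int(row["education"]),
                ihds=ihds,
                stratum=str(row["stratum"]),
                months_since_diagnosis=None
                if _is_missing(row.get("months_since_diagnosis"))
                else float(row["months_since_diagnosis"]),
                cd4_current=None
                if _is_missing(row.get("cd4_current"))
                else float(row["cd4_current"]),
                cd4_nadir=None
                if _is_missing(row.get("cd4_nadir"))
                else float(row["cd4_nadir"]),
                on_art=None
                if _is_missing(row.get("on_art"))
                else _parse_bool(row["on_art"], pos, "on_art"),
                true_class=None
                if "true_class" not in df.columns or _is_missing(row.get("true_class"))
                else str(row["true_class"]),
                evaluated=evaluated,
                profile=profile,
                dnaa=dnaa,
            )
            if profile is not None and dnaa is not None and not _is_missing(
                row.get("diagnosis")
            ):
                rec.diagnosis = frascati.classify(profile, dnaa)
            records.append(rec)
        except (ValueError, KeyError) as exc:
            errors.append((pos, str(exc)))
    if errors:
        raise CohortReadError(errors)
    return records


def read_cohort(
    path: str | Path,
    domain_map: Optional[Mapping[str, frozenset[str]]] = None,
    key_items: Optional[frozenset[int]] = None,
) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    return frame_to_records(df, domain_map=domain_map, key_items=key_items)


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fail_threshold: float = -1.0
    severe_threshold: float = -2.0
    cutoffs: tuple[float, ...] = (9.5, 10.0, 10.5, 11.0, 11.5, 12.0)
    n_boot: int = 2000
    age_bands: tuple[tuple[float, float], ...] = ((19, 34), (35, 49), (50, 80))
    education_bands: tuple[tuple[float, float], ...] = ((8, 12), (13, 16), (17, 25))

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "fail_threshold": self.fail_threshold,
            "severe_threshold": self.severe_threshold,
            "cutoffs": list(self.cutoffs),
            "n_boot": self.n_boot,
            "age_bands": [list(b) for b in self.age_bands],
            "education_bands": [list(b) for b in self.education_bands],
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: list[ParticipantRecord]
    strata: list[prevalence.StratumSpec]
    estimate: prevalence.PrevalenceEstimate
    breakdown: dict[str, prevalence.SubtypeShare]
    hand_ci: tuple[float, float]
    roc_hand: Optional[screen_eval.ROCCurve]
    table_hand: pd.DataFrame
    table_had: pd.DataFrame
    optimal: Optional[tuple[float, screen_eval.DiagnosticMetrics]]
    agreement_table: screen_eval.ConfusionTable
    phi: Optional[float]
    scaled_table: normative.ScaledScoreTable
    model: normative.NormativeModel
    t_scores: np.ndarray
    t_metrics: screen_eval.DiagnosticMetrics
    report: str


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """simulate -> stratify -> sample -> classify -> prevalence ->
    screen evaluation -> normative model, with a markdown report.

    Fully deterministic given ``config.cohort.seed``.
    """
    records = generate_cohort(config.cohort)
    sample_evaluated(records, config.cohort, strict=False)
    frascati.classify_cohort(
        records, config.fail_threshold, config.severe_threshold
    )

    strata = prevalence.strata_from_records(records)
    estimate = prevalence.adjusted_prevalence(strata)
    breakdown = (
        prevalence.subtype_breakdown(estimate) if estimate.overall > 0 else {}
    )
    hand_ci = prevalence.bootstrap_ci(
        strata, n_boot=config.n_boot, seed=config.cohort.seed
    )

    evaluated = [r for r in records if r.evaluated]
    scores = np.array([r.ihds.total for r in evaluated])
    hand = np.array([r.diagnosis.label != "NCN" for r in evaluated])
    had = np.array([r.diagnosis.label == "HAD" for r in evaluated])
    # a degenerate cohort (single class among evaluations) has no ROC curve
    roc_hand = (
        screen_eval.roc(scores, hand) if 0 < hand.sum() < hand.size else None
    )
    table_hand = screen_eval.cutoff_table(scores, hand, config.cutoffs)
    table_had = screen_eval.cutoff_table(scores, had, config.cutoffs)
    optimal = screen_eval.optimal_cutoff(roc_hand) if roc_hand else None

    pos = [r for r in evaluated if r.hiv_positive]
    both = sum(1 for r in pos if r.ihds.total <= 11 and r.diagnosis.label != "NCN")
    screen_only = sum(
        1 for r in pos if r.ihds.total <= 11 and r.diagnosis.label == "NCN"
    )
    assess_only = sum(
        1 for r in pos if r.ihds.total > 11 and r.diagnosis.label != "NCN"
    )
    neither = len(pos) - both - screen_only - assess_only
    agreement_table = screen_eval.ConfusionTable(both, screen_only, assess_only, neither)
    phi = screen_eval.agreement(agreement_table)

    screened = [r for r in records if r.hiv_positive]
    ref_totals = [r.ihds.total for r in screened]
    scaled_table = normative.build_scaled_table(ref_totals)
    model = normative.fit_normative_model(
        [scaled_table.lookup(t) for t in ref_totals],
        [r.age for r in screened],
        [r.education for r in screened],
    )
    t_scores = np.array(
        [
            normative.t_score(
                model, scaled_table.lookup(r.ihds.total), r.age, r.education
            )
            for r in evaluated
        ]
    )
    t_pos = t_scores <= normative.T_IMPAIRMENT_CUTOFF
    t_table = screen_eval.ConfusionTable(
        tp=int(np.sum(t_pos & hand)),
        fp=int(np.sum(t_pos & ~hand)),
        fn=int(np.sum(~t_pos & hand)),
        tn=int(np.sum(~t_pos & ~hand)),
    )
    t_metrics = screen_eval.diagnostic_metrics(t_table)

    result = PipelineResult(
        config=config,
        records=records,
        strata=strata,
        estimate=estimate,
        breakdown=breakdown,
        hand_ci=hand_ci,
        roc_hand=roc_hand,
        table_hand=table_hand,
        table_had=table_had,
        optimal=optimal,
        agreement_table=agreement_table,
        phi=phi,
        scaled_table=scaled_table,
        model=model,
        t_scores=t_scores,
        t_metrics=t_metrics,
        report="",
    )
    result.report = _render_report(result)
    return result


def _pct(x: Optional[float]) -> str:
    return "-" if x is None else f"{round_half_up(100 * x):.0f}%"


def _render_report(res: PipelineResult) -> str:
    cfg = res.config
    lines: list[str] = []
    lines.append("# Screening-validation report")
    lines.append("")
    lines.append(f"- seed: {cfg.cohort.seed}")
    lines.append(f"- config hash: {config_hash(cfg.to_dict())}")
    n_pos = sum(1 for r in res.records if r.hiv_positive)
    n_eval = sum(1 for r in res.records if r.evaluated)
    lines.append(f"- screened HIV-positive: {n_pos}; evaluated (incl. controls): {n_eval}")
    lines.append("")
    lines.append("## Strata")
    lines.append("")
    lines.append("| stratum | screened | evaluated | ANI | MND | HAD |")
    lines.append("|---|---|---|---|---|---|")
    for s in res.strata:
        lines.append(
            f"| {s.name} | {s.n_screened} | {s.m_evaluated} | "
            f"{s.cases.get('ANI', 0)} | {s.cases.get('MND', 0)} | "
            f"{s.cases.get('HAD', 0)} |"
        )
    lines.append("")
    lines.append("## Adjusted prevalence")
    lines.append("")
    lines.append(
        f"Overall HAND: {_pct(res.estimate.overall)} "
        f"(bootstrap 95% CI {_pct(res.hand_ci[0])}–{_pct(res.hand_ci[1])}, "
        f"N = {res.estimate.N})"
    )
    for sub, share in res.breakdown.items():
        lines.append(
            f"- {sub}: {share.absolute_pct}% of cohort "
            f"({share.share_pct}% of HAND cases)"
        )
    lines.append("")
    lines.append("## Screen accuracy (positivity: total <= cutoff)")
    lines.append("")
    if res.roc_hand is not None:
        lines.append(f"ROC AUC for HAND: {res.roc_hand.auc:.3f} "
                     f"({res.roc_hand.n_pos} HAND vs {res.roc_hand.n_neg} non-HAND)")
    else:
        lines.append("ROC undefined: evaluations contain a single class.")
    if res.optimal is not None:
        cut, m = res.optimal
        lines.append(
            f"Youden-optimal cutoff: {cut:g} "
            f"(sensitivity {_pct(m.sensitivity)}, specificity {_pct(m.specificity)}, "
            f"J = {m.youden_j:.2f})"
        )
    lines.append("")
    for title, tab in (("all HAND", res.table_hand), ("HAD only", res.table_had)):
        lines.append(f"### Cut-off table, {title}")
        lines.append("")
        lines.append("| cutoff | sensitivity | specificity | PPV | NPV | J |")
        lines.append("|---|---|---|---|---|---|")
        for _, row in tab.iterrows():
            cells = [
                f"{row['cutoff']:g}",
                *(
                    "-" if row[c] is None or pd.isna(row[c]) else f"{int(row[c])}%"
                    for c in (
                        "sensitivity_pct",
                        "specificity_pct",
                        "ppv_pct",
                        "npv_pct",
                    )
                ),
                "-" if pd.isna(row["youden_j"]) else f"{row['youden_j']:.1f}",
            ]
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    lines.append("## Screen vs assessment agreement (HIV-positive evaluations)")
    lines.append("")
    t = res.agreement_table
    lines.append(
        f"Both impaired {t.tp}, screen-only {t.fp}, assessment-only {t.fn}, "
        f"neither {t.tn} (n = {t.total})"
    )
    lines.append(
        "phi = " + ("-" if res.phi is None else f"{res.phi:.2f}")
    )
    lines.append("")
    lines.append("## Demographically adjusted T-scores")
    lines.append("")
    lines.append(
        f"Normative model on {res.model.reference_sample_size} screened "
        f"totals; residual SD {res.model.residual_sd:.2f} scaled-score units."
    )
    lines.append(
        f"Evaluated sample: mean T {res.t_scores.mean():.1f}, "
        f"SD {res.t_scores.std(ddof=1):.1f}; screening at T <= 40: "
        f"sensitivity {_pct(res.t_metrics.sensitivity)}, "
        f"specificity {_pct(res.t_metrics.specificity)}"
    )
    lines.append("")
    return "\n".join(lines)


def write_bundle(res: PipelineResult, outdir: str | Path) -> None:
    """Write the full report bundle (CSV tables, JSON summaries, report)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": res.config.cohort.seed,
        "config_hash": config_hash(res.config.to_dict()),
    }
    write_cohort(res.records, out / "cohort.csv")
    (out / "report.md").write_text(res.report)
    (out / "config.json").write_text(
        json.dumps({**meta, "config": res.config.to_dict()}, indent=2)
    )
    (out / "prevalence.json").write_text(
        json.dumps(
            {
                **meta,
                "overall": res.estimate.overall,
                "by_subtype": res.estimate.by_subtype,
                "ci95_overall": list(res.hand_ci),
                "N": res.estimate.N,
            },
            indent=2,
        )
    )
    res.table_hand.to_csv(out / "accuracy_hand.csv", index=False)
    res.table_had.to_csv(out / "accuracy_had.csv", index=False)
    if res.roc_hand is not None:
        pd.DataFrame(
            [
                {"cutoff": p.cutoff, "sensitivity": p.sensitivity, "fpr": p.fpr}
                for p in res.roc_hand.points
            ]
        ).to_csv(out / "roc_points.csv", index=False)
    raw_df, cells_df = normative.export_norm_tables(
        res.scaled_table, res.model, res.config.age_bands, res.config.education_bands
    )
    raw_df.to_csv(out / "norm_raw_scaled.csv", index=False)
    cells_df.to_csv(out / "norm_thresholds.csv", index=False)
    (out / "model.json").write_text(
        json.dumps({**meta, **res.model.to_dict()}, indent=2)
    )
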
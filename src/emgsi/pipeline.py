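"""End-to-end orchestration: preprocessing chains, reference building,
subject scoring and the validation battery.

This is the library layer behind the command-line interface; everything here
is importable and deterministic given its inputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinimetrics as cm
from .errors import DataError, DegenerateReferenceError, ExclusionError
from .io import (
    ArtifactTable,
    EmgRecording,
    EventTable,
    SCORE_COLUMNS,
    validate_scores,
)
from .montage import ALL_TASKS, JOINTS, LEGS, MUSCLES, TaskId
from .preprocess import (
    BaselineProfile,
    FilterSpec,
    cut_artifacts,
    estimate_baseline,
    highpass,
    notch,
)
from .similarity import (
    PrototypeResponseVector,
    ResponseVector,
    SiScores,
    aggregate,
    prototype_response_vector,
    response_vector,
    similarity_index,
)

logger = logging.getLogger(__name__)

#: Ipsilateral-first channel column names used in prototype CSV files.
PRV_COLUMNS = [f"{m}_ipsi" for m in MUSCLES] + [f"{m}_contra" for m in MUSCLES]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable decision of a run, echoed into the run log."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    baseline_window_s: float = 3.0
    baseline_step_s: float = 0.1
    pool_sides: bool = True
    min_tasks: int | None = None  # None = strict missing-value propagation
    alpha: float = 0.05
    roc_bootstrap: int = 2000
    roc_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass(frozen=True)
class ProcessedRecording:
    recording: EmgRecording
    events: EventTable
    baseline: BaselineProfile
    exclusions: frozenset
    log: dict


def preprocess_recording(
    rec: EmgRecording,
    events: EventTable,
    artifacts: ArtifactTable | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> ProcessedRecording:
    """Full conditioning chain: high-pass, selective notch, artifact cutting,
    baseline location."""
    if artifacts is None:
        artifacts = ArtifactTable.empty()
    filtered = notch(highpass(rec, config.filter), config.filter)
    cut_rec, cut_events, exclusions = cut_artifacts(filtered, artifacts, events)
    baseline = estimate_baseline(cut_rec, config.baseline_window_s, config.baseline_step_s)
    log = {
        "subject_id": rec.subject_id,
        "session": rec.session,
        "fir_order": config.filter.resolved_order(rec.fs),
        "notched_channels": int(rec.notch_flags.sum()),
        "n_global_cut_s": round(rec.duration_s - cut_rec.duration_s, 6),
        "n_channel_exclusions": len(exclusions),
        "baseline_rms_uv": [round(float(v), 4) for v in baseline.baseline_rms],
    }
    return ProcessedRecording(cut_rec, cut_events, baseline, exclusions, log)


def compute_response_vectors(proc: ProcessedRecording) -> dict[TaskId, ResponseVector]:
    """RVs for every task present in the event table; exclusion errors propagate."""
    return {
        task: response_vector(
            proc.recording, proc.events, task, proc.baseline, proc.exclusions
        )
        for task in proc.events.tasks
    }


# ---------------------------------------------------------------------------
# Reference prototypes


@dataclass(frozen=True)
class PrvSet:
    """The prototype vectors of one reference cohort, keyed by joint
    (pooled sides) or by (joint, physical side)."""

    prvs: dict
    pooled: bool
    provenance: str = ""

    def for_task(self, joint: str, side: str) -> PrototypeResponseVector:
        key = joint if self.pooled else (joint, side)
        if key not in self.prvs:
            raise DataError(f"no prototype for {key!r}")
        return self.prvs[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, prv in sorted(self.prvs.items(), key=lambda kv: str(kv[0])):
            row = {
                "joint": prv.joint,
                "side": prv.side if prv.side else "pooled",
                "n_reference": prv.n_reference,
            }
            row.update({c: v for c, v in zip(PRV_COLUMNS, prv.values)})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "PrvSet":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            provenance = first.lstrip("# ").removeprefix("provenance:").strip() if first.startswith("#") else ""
        df = pd.read_csv(path, comment="#")
        prvs: dict = {}
        pooled = True
        for _, row in df.iterrows():
            side = None if row["side"] == "pooled" else str(row["side"])
            prv = PrototypeResponseVector(
                values=row[PRV_COLUMNS].to_numpy(dtype=float),
                joint=str(row["joint"]),
                n_reference=int(row["n_reference"]),
                pooled=side is None,
                side=side,
            )
            if side is None:
                prvs[prv.joint] = prv
            else:
                pooled = False
                prvs[(prv.joint, side)] = prv
        return cls(prvs=prvs, pooled=pooled, provenance=provenance)


def build_reference(
    subjects: list[tuple[EmgRecording, EventTable, ArtifactTable | None]],
    config: PipelineConfig = PipelineConfig(),
    provenance: str = "",
) -> PrvSet:
    """Preprocess a reference cohort and average its RVs into prototypes.

    With side pooling (default) the left- and right-leg RVs of each joint are
    mirrored into a common ipsilateral-first frame and pooled, doubling the
    reference data per prototype; otherwise one prototype is kept per
    (joint, physical side).
    """
    if not subjects:
        raise DataError("reference cohort is empty")
    by_key: dict = {}
    magnitudes = []
    for rec, events, artifacts in subjects:
        proc = preprocess_recording(rec, events, artifacts, config)
        for task, rv in compute_response_vectors(proc).items():
            key = task.joint if config.pool_sides else (task.joint, rv.side)
            by_key.setdefault(key, []).append(rv)
            magnitudes.append(float(np.linalg.norm(rv.values)))
    prvs = {}
    for key, rvs in by_key.items():
        try:
            prvs[key] = prototype_response_vector(rvs, pool_sides=config.pool_sides)
        except DegenerateReferenceError as exc:
            raise DegenerateReferenceError(f"task {key!r}: {exc}") from exc
    logger.info(
        "built %d prototypes from %d subjects (median RV magnitude %.1f uV)",
        len(prvs), len(subjects), float(np.median(magnitudes)),
    )
    return PrvSet(prvs=prvs, pooled=config.pool_sides, provenance=provenance)


# ---------------------------------------------------------------------------
# Scoring


def score_subject(
    rec: EmgRecording,
    events: EventTable,
    artifacts: ArtifactTable | None,
    reference: PrvSet,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[SiScores, dict[TaskId, ResponseVector], dict[TaskId, str]]:
    """Score one subject against the reference prototypes.

    Returns the aggregated scores, the response vectors, and a reason map for
    any task whose similarity index is missing.
    """
    proc = preprocess_recording(rec, events, artifacts, config)
    per_task: dict[TaskId, float] = {}
    rvs: dict[TaskId, ResponseVector] = {}
    reasons: dict[TaskId, str] = {}
    for task in proc.events.tasks:
        try:
            rv = response_vector(proc.recording, proc.events, task, proc.baseline, proc.exclusions)
        except ExclusionError as exc:
            per_task[task] = float("nan")
            reasons[task] = f"excluded: {exc}"
            continue
        rvs[task] = rv
        prv = reference.for_task(task.joint, rv.side)
        si = similarity_index(rv, prv)
        per_task[task] = si
        if np.isnan(si):
            reasons[task] = "degenerate all-zero response vector"
    scores = aggregate(per_task, subject_id=rec.subject_id, min_tasks=config.min_tasks)
    return scores, rvs, reasons


def scores_to_row(scores: SiScores, session: str = "test", group: str | None = None) -> dict:
    row = {"subject_id": scores.subject_id, "session": session, "group": group}
    for task, si in scores.per_task.items():
        row[f"si_{task.joint}_{task.leg}"] = si
    row["si_leg_less"] = scores.leg_means["less"]
    row["si_leg_more"] = scores.leg_means["more"]
    row["si_total"] = scores.total_mean
    return row


def score_cohort(datasets, reference: PrvSet, config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Score a list of synthetic subject datasets into a score table.

    Carries the synthetic ordinal joint scores and GMFCS levels along so the
    validation battery can run on the result.
    """
    rows = []
    for ds in datasets:
        scores, _, reasons = score_subject(
            ds.recording, ds.events, None, reference, config
        )
        for task, reason in reasons.items():
            logger.warning("%s %s: %s", ds.recording.subject_id, task, reason)
        row = scores_to_row(scores, session=ds.recording.session, group=ds.profile.group)
        for task, val in ds.scale_scores.items():
            row[f"scale_{task.joint}_{task.leg}"] = val
        row["gmfcs"] = ds.gmfcs if ds.gmfcs is not None else np.nan
        rows.append(row)
    return validate_scores(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Validation battery

_SCORE_BLOCKS = (
    [(f"si_{j}_{leg}", f"{j} ({leg})") for leg in LEGS for j in JOINTS]
    + [("si_leg_less", "leg (less)"), ("si_leg_more", "leg (more)"), ("si_total", "total")]
)


@dataclass
class ValidationReport:
    """Validation-battery output: independent blocks plus skip reasons."""

    blocks: dict = field(default_factory=dict)  # name -> DataFrame
    skipped: dict = field(default_factory=dict)  # name -> reason
    bonferroni_alpha: float | None = None
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Validation report", "================="]
        for name, df in self.blocks.items():
            lines.append(f"\n[{name}]")
            lines.append(df.to_string(index=False))
        if self.bonferroni_alpha is not None:
            lines.append(
                f"\nBonferroni-adjusted significance threshold: {self.bonferroni_alpha:.6f}"
            )
        for name, reason in self.skipped.items():
            lines.append(f"\n[{name}] skipped: {reason}")
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "bonferroni_alpha": self.bonferroni_alpha,
            "skipped": self.skipped,
            "config": self.config,
            "blocks": {k: json.loads(v.to_json(orient="records")) for k, v in self.blocks.items()},
        }
        (out / "validation.json").write_text(json.dumps(payload, indent=1))
        for name, df in self.blocks.items():
            df.to_csv(out / f"{name}.csv", index=False)


def _scale_sum(df: pd.DataFrame, legs) -> pd.Series:
    cols = [f"scale_{j}_{leg}" for leg in legs for j in JOINTS]
    return df[cols].sum(axis=1, min_count=len(cols))


def validate(
    scores: pd.DataFrame,
    retest: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> ValidationReport:
    """Run the full clinimetric battery on a score table.

    Blocks run independently and degrade gracefully: a block whose required
    columns or groups are absent is skipped with an explicit reason. Group
    comparisons are Bonferroni-corrected as one family (8 joints + 2 legs +
    total = 11 comparisons).
    """
    scores = validate_scores(scores)
    report = ValidationReport(config=config.to_dict())
    cp = scores[scores["group"] == "CP"]
    ctrl = scores[scores["group"] == "control"]

    # -- concurrent validity: rank correlations against the ordinal scale
    try:
        target = cp if len(cp) else scores
        if _scale_sum(target, LEGS).notna().sum() < 3:
            raise DataError("fewer than 3 subjects with complete ordinal joint scores")
        rows = []
        total = cm.spearman(target["si_total"], _scale_sum(target, LEGS))
        rows.append({"score": "total", "method": total.method, "estimate": total.estimate,
                     "p_value": total.p_value, "n": total.n})
        for leg in LEGS:
            r = cm.spearman(target[f"si_leg_{leg}"], _scale_sum(target, [leg]))
            rows.append({"score": f"leg ({leg})", "method": r.method, "estimate": r.estimate,
                         "p_value": r.p_value, "n": r.n})
        for leg in LEGS:
            for j in JOINTS:
                r = cm.kendall_tau_b(target[f"si_{j}_{leg}"], target[f"scale_{j}_{leg}"])
                rows.append({"score": f"{j} ({leg})", "method": r.method, "estimate": r.estimate,
                             "p_value": r.p_value, "n": r.n})
        if target["gmfcs"].notna().sum() >= 3:
            r = cm.spearman(target["si_total"], target["gmfcs"])
            rows.append({"score": "total vs GMFCS", "method": r.method, "estimate": r.estimate,
                         "p_value": r.p_value, "n": r.n})
        report.blocks["concurrent"] = pd.DataFrame(rows)
    except (DataError, KeyError) as exc:
        report.skipped["concurrent"] = str(exc)
        logger.warning("concurrent block skipped: %s", exc)

    # -- discriminative validity: CP vs control, leg vs leg, ROC
    try:
        if not len(cp) or not len(ctrl):
            raise DataError("need both a CP and a control group")
        rows = []
        for col, label in _SCORE_BLOCKS:
            a, b = cp[col].dropna(), ctrl[col].dropna()
            r = cm.mann_whitney(a, b)
            rows.append({"score": label, "U": r.statistic, "p_value": r.p_value, "n": r.n})
        flags, adj = cm.bonferroni([row["p_value"] for row in rows], config.alpha)
        for row, flag in zip(rows, flags):
            row["significant"] = bool(flag)
        report.bonferroni_alpha = adj
        report.blocks["group_differences"] = pd.DataFrame(rows)
    except DataError as exc:
        report.skipped["group_differences"] = str(exc)
        logger.warning("group_differences block skipped: %s", exc)

    try:
        if not len(cp):
            raise DataError("no CP group for the leg comparison")
        r = cm.wilcoxon_signed_rank(cp["si_leg_less"], cp["si_leg_more"])
        report.blocks["leg_difference"] = pd.DataFrame(
            [{"comparison": "less vs more affected leg", "W": r.statistic,
              "p_value": r.p_value, "n_pairs": r.n}]
        )
    except DataError as exc:
        report.skipped["leg_difference"] = str(exc)

    try:
        si_cols = [f"si_{j}_{leg}" for leg in LEGS for j in JOINTS]
        sc_cols = [f"scale_{j}_{leg}" for leg in LEGS for j in JOINTS]
        si_long = scores[si_cols].to_numpy(dtype=float).ravel()
        sc_long = scores[sc_cols].to_numpy(dtype=float).ravel()
        keep = np.isfinite(si_long) & np.isfinite(sc_long)
        if keep.sum() < 4:
            raise DataError("too few joint observations with both SI and ordinal score")
        roc = cm.roc_youden(
            si_long[keep], sc_long[keep] == 2, n_boot=config.roc_bootstrap, seed=config.roc_seed
        )
        report.blocks["roc"] = pd.DataFrame(
            [{"auc": roc.auc, "auc_ci_low": roc.auc_ci_low, "auc_ci_high": roc.auc_ci_high,
              "cutoff": roc.cutoff, "sensitivity": roc.sensitivity,
              "specificity": roc.specificity, "n_normal": roc.n_normal,
              "n_impaired": roc.n_impaired}]
        )
    except DataError as exc:
        report.skipped["roc"] = str(exc)
        logger.warning("roc block skipped: %s", exc)

    # -- test-retest reliability
    try:
        if retest is None:
            raise DataError("single-session input; no retest scores provided")
        retest = validate_scores(retest)
        merged = scores.merge(retest, on="subject_id", suffixes=("_1", "_2"))
        rows = []
        for col, label in _SCORE_BLOCKS:
            pair = merged[[f"{col}_1", f"{col}_2"]].dropna()
            if len(pair) < 3:
                rows.append({"score": label, "n": len(pair), "icc": np.nan, "note": "too few pairs"})
                continue
            rel = cm.icc_2_1(pair.to_numpy(dtype=float))
            rows.append({"score": label, "n": rel.n, "icc": rel.icc,
                         "icc_ci_low": rel.icc_ci_low, "icc_ci_high": rel.icc_ci_high,
                         "sem": rel.sem, "mdc95": rel.mdc95,
                         "systematic_p": rel.systematic_p, "note": ""})
        report.blocks["reliability"] = pd.DataFrame(rows)
    except DataError as exc:
        report.skipped["reliability"] = str(exc)
        logger.warning("reliability block skipped: %s", exc)

    return report
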
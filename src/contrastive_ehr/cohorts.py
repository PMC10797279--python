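"""Case-control cohort construction for post-discharge depression/anxiety.

A discharge record is a *case* for a window W if a depression/anxiety event
(diagnosis in F31-F34, F39, F06.3, F40-F43, F06.4, or medication in N06A,
N05B) falls in the half-open interval (discharge, discharge + W]; it is
*excluded* if any such event falls within the 183 days up to and including
discharge (prevalent or recent illness); otherwise it is control-eligible.
Repeat records of one patient whose discharge dates chain within 7 days are
merged, keeping the latest.  Controls are matched 1:`control_ratio` to cases
by propensity score on two covariates: discharge time and days from
discharge to the outcome event (cases) or to the window end (controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .codes import OutcomeCodeSets
from .synthetic_ehr import DischargeRecord, PatientTimeline

__all__ = [
    "OutcomeCodeSets",
    "MatchConfig",
    "LabelResult",
    "MatchCandidate",
    "CaseControlDataset",
    "label_window",
    "merge_repeats",
    "propensity_match",
    "build_cohort",
    "PRIOR_EXCLUSION_DAYS",
    "MERGE_WINDOW_DAYS",
]

logger = logging.getLogger(__name__)

PRIOR_EXCLUSION_DAYS = 183  # "six months"
MERGE_WINDOW_DAYS = 7
WINDOWS = (30, 180, 365)


@dataclass(frozen=True)
class MatchConfig:
    control_ratio: int = 3
    caliper: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.control_ratio < 1:
            raise ValueError("control_ratio must be >= 1")


@dataclass(frozen=True)
class LabelResult:
    status: str  # "case" | "control" | "excluded"
    reason: str | None = None  # exclusion reason
    days_to_event: int | None = None  # cases only


def label_window(
    timeline: PatientTimeline,
    record: DischargeRecord,
    window_days: int,
    code_sets: OutcomeCodeSets | None = None,
) -> LabelResult:
    """Classify one record as case / control-eligible / excluded.

    Exclusion (an outcome event in [discharge - 183 d, discharge]) takes
    precedence over case status; events with non-matching codes are ignored.
    """
    code_sets = code_sets or OutcomeCodeSets()
    if record.patient_id != timeline.patient_id:
        raise ValueError(f"record {record.record_id} does not belong to timeline {timeline.patient_id}")
    discharge = record.discharge_date
    matching = [e for e in timeline.outcome_events if code_sets.is_outcome(e.kind, e.code)]
    if any(discharge - PRIOR_EXCLUSION_DAYS <= e.date <= discharge for e in matching):
        return LabelResult(status="excluded", reason="prior_event")
    in_window = [e.date - discharge for e in matching if discharge < e.date <= discharge + window_days]
    if in_window:
        return LabelResult(status="case", days_to_event=min(in_window))
    return LabelResult(status="control")


def merge_repeats(records: list[DischargeRecord]) -> list[DischargeRecord]:
    """Collapse runs of records whose discharge dates chain within 7 days.

    Clustering is the transitive closure of the |Δdischarge| <= 7 relation on
    date-sorted records; the latest record of each cluster is kept.
    """
    if len(records) <= 1:
        return list(records)
    ordered = sorted(records, key=lambda r: (r.discharge_date, r.record_id))
    kept: list[DischargeRecord] = []
    cluster = [ordered[0]]
    for rec in ordered[1:]:
        if rec.discharge_date - cluster[-1].discharge_date <= MERGE_WINDOW_DAYS:
            cluster.append(rec)
        else:
            kept.append(cluster[-1])
            cluster = [rec]
    kept.append(cluster[-1])
    return kept


@dataclass(frozen=True)
class MatchCandidate:
    """One record entering matching, with the two PSM covariates."""

    record_id: str
    patient_id: str
    discharge_date: float
    days_to_event_or_window_end: float
    record: DischargeRecord | None = None


@dataclass
class CaseControlDataset:
    window_days: int
    entries: list[tuple[MatchCandidate, int, int]]  # (candidate, label, match_group)
    provenance: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab, _ in self.entries], dtype=int)

    def records(self) -> list[DischargeRecord]:
        return [c.record for c, _, _ in self.entries]


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0) if len(a) > 1 and len(b) > 1 else 0.0
    if pooled == 0.0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def _auc(labels: np.ndarray, scores: np.ndarray) -> float:
    r = rankdata(scores)
    n1 = labels.sum()
    n0 = len(labels) - n1
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def propensity_match(
    cases: list[MatchCandidate],
    controls: list[MatchCandidate],
    config: MatchConfig,
    window_days: int = 365,
) -> CaseControlDataset:
    """Greedy 1:k nearest-propensity matching without replacement.

    A logistic propensity model of case status on (discharge time, days to
    event / window end) is fitted on standardized covariates; cases are
    processed in descending propensity (ties by record id) and each takes the
    `control_ratio` available controls nearest in logit, ties again broken by
    record id.  If the propensity model (near-)perfectly separates the groups
    — which happens whenever the control follow-up covariate is degenerate —
    the logit is meaningless for ranking controls and matching falls back to
    standardized euclidean distance on the raw covariates, with a warning.
    Standardized mean differences before/after matching are reported.
    """
    k = config.control_ratio
    if len(controls) < k * len(cases):
        raise ValueError(
            f"insufficient controls: need {k * len(cases)} "
            f"({k} per case x {len(cases)} cases), have {len(controls)}"
        )
    if not cases:
        return CaseControlDataset(window_days=window_days, entries=[], provenance={"n_cases": 0})

    X = np.array(
        [[c.discharge_date, c.days_to_event_or_window_end] for c in cases + controls], dtype=float
    )
    y = np.array([1] * len(cases) + [0] * len(controls))
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    model = LogisticRegression(max_iter=1000, random_state=config.seed)
    model.fit(Xs, y)
    logits = Xs @ model.coef_[0] + model.intercept_[0]
    auc = _auc(y, logits)

    degenerate = auc >= 0.99
    if degenerate:
        logger.warning(
            "propensity model nearly separates cases and controls (AUC=%.3f); "
            "falling back to covariate-distance matching", auc,
        )

    case_logits = logits[: len(cases)]
    ctrl_logits = logits[len(cases):]
    case_X = Xs[: len(cases)]
    ctrl_X = Xs[len(cases):]

    order = sorted(range(len(cases)), key=lambda i: (-case_logits[i], cases[i].record_id))
    available = set(range(len(controls)))
    entries: list[tuple[MatchCandidate, int, int]] = []
    for group, ci in enumerate(order):
        if degenerate:
            dist = np.linalg.norm(ctrl_X - case_X[ci], axis=1)
        else:
            dist = np.abs(ctrl_logits - case_logits[ci])
        cand = sorted(available, key=lambda j: (dist[j], controls[j].record_id))
        if config.caliper is not None:
            cand = [j for j in cand if dist[j] <= config.caliper]
        if len(cand) < k:
            raise ValueError(
                f"insufficient controls for case {cases[ci].record_id}: "
                f"need {k}, have {len(cand)} within caliper"
            )
        chosen = cand[:k]
        available.difference_update(chosen)
        entries.append((cases[ci], 1, group))
        entries.extend((controls[j], 0, group) for j in chosen)

    matched_controls = np.array(
        [[c.discharge_date, c.days_to_event_or_window_end] for c, lab, _ in entries if lab == 0]
    )
    case_cov = X[: len(cases)]
    ctrl_cov = X[len(cases):]
    report = {
        "propensity_auc": auc,
        "degenerate_fallback": bool(degenerate),
        "smd_before": {
            "discharge_date": _smd(case_cov[:, 0], ctrl_cov[:, 0]),
            "days_to_event_or_window_end": _smd(case_cov[:, 1], ctrl_cov[:, 1]),
        },
        "smd_after": {
            "discharge_date": _smd(case_cov[:, 0], matched_controls[:, 0]),
            "days_to_event_or_window_end": _smd(case_cov[:, 1], matched_controls[:, 1]),
        },
    }
    return CaseControlDataset(
        window_days=window_days,
        entries=entries,
        provenance={"match_report": report, "n_cases": len(cases), "n_controls_matched": k * len(cases)},
    )


def build_cohort(
    timelines: list[PatientTimeline],
    window_days: int,
    match_config: MatchConfig | None = None,
    code_sets: OutcomeCodeSets | None = None,
) -> CaseControlDataset:
    """Merge repeats, label, and match, with full provenance accounting.

    Every input record is classified exactly once as merged-away, excluded,
    case, or control-eligible; eligible controls then split into matched and
    unmatched.  Counts for each category are recorded in `provenance`.
    """
    match_config = match_config or MatchConfig()
    code_sets = code_sets or OutcomeCodeSets()
    n_input = 0
    n_merged_away = 0
    counts = {"excluded:prior_event": 0}
    cases: list[MatchCandidate] = []
    controls: list[MatchCandidate] = []
    for tl in timelines:
        n_input += len(tl.admissions)
        kept = merge_repeats(tl.admissions)
        n_merged_away += len(tl.admissions) - len(kept)
        for rec in kept:
            res = label_window(tl, rec, window_days, code_sets)
            if res.status == "excluded":
                counts[f"excluded:{res.reason}"] = counts.get(f"excluded:{res.reason}", 0) + 1
                continue
            cand = MatchCandidate(
                record_id=rec.record_id,
                patient_id=rec.patient_id,
                discharge_date=float(rec.discharge_date),
                days_to_event_or_window_end=float(
                    res.days_to_event if res.status == "case" else window_days
                ),
                record=rec,
            )
            (cases if res.status == "case" else controls).append(cand)

    dataset = propensity_match(cases, controls, match_config, window_days=window_days)
    dataset.provenance.update(
        {
            "n_input_records": n_input,
            "n_merged_away": n_merged_away,
            "n_excluded": counts,
            "n_cases": len(cases),
            "n_controls_eligible": len(controls),
            "n_controls_unmatched": len(controls) - match_config.control_ratio * len(cases),
            "window_days": window_days,
        }
    )
    return dataset
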
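"""Labelling windows, record merging, and propensity matching."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from contrastive_ehr.cohorts import (
    CaseControlDataset,
    MatchCandidate,
    MatchConfig,
    OutcomeCodeSets,
    build_cohort,
    label_window,
    merge_repeats,
    propensity_match,
)
from contrastive_ehr.synthetic_ehr import (
    DischargeRecord,
    OutcomeEvent,
    PatientTimeline,
    SyntheticConfig,
    generate_timelines,
)


def make_record(rid: str, pid: str = "p0", discharge: int = 1000, admit: int | None = None):
    return DischargeRecord(
        record_id=rid, patient_id=pid, admit_date=admit if admit is not None else discharge - 5,
        discharge_date=discharge, age=64.0, sex="F", marital_status="married",
        labs=[("lab_00", 1.0)], history_tokens=["h001"],
        diagnosis_codes=["E11.9"], medication_codes=["A10BA02"],
    )


def make_timeline(records, events):
    return PatientTimeline(patient_id=records[0].patient_id, admissions=records, outcome_events=events)


# -- labelling ----------------------------------------------------------
def test_depression_diagnosis_100_days_out_is_a_365_day_case():
    rec = make_record("r1")
    tl = make_timeline([rec], [OutcomeEvent(date=1100, kind="diagnosis", code="F32.1")])
    res = label_window(tl, rec, 365)
    assert res.status == "case" and res.days_to_event == 100


def test_same_event_is_outside_a_30_day_window():
    rec = make_record("r1")
    tl = make_timeline([rec], [OutcomeEvent(date=1100, kind="diagnosis", code="F32.1")])
    assert label_window(tl, rec, 30).status == "control"


def test_antidepressant_100_days_before_discharge_excludes_the_record():
    rec = make_record("r1")
    tl = make_timeline([rec], [OutcomeEvent(date=900, kind="medication", code="N06AB03")])
    res = label_window(tl, rec, 365)
    assert res.status == "excluded" and res.reason == "prior_event"


def test_window_boundaries_are_half_open_on_the_left():
    rec = make_record("r1")
    # event exactly at discharge counts as prior (inclusive right edge of the
    # exclusion interval), not as a case
    tl = make_timeline([rec], [OutcomeEvent(date=1000, kind="diagnosis", code="F33.1")])
    assert label_window(tl, rec, 365).status == "excluded"
    # event exactly at discharge + W is still inside the window
    tl2 = make_timeline([rec], [OutcomeEvent(date=1365, kind="diagnosis", code="F33.1")])
    assert label_window(tl2, rec, 365).status == "case"
    # one day past the prior-exclusion horizon is ignored
    tl3 = make_timeline([rec], [OutcomeEvent(date=1000 - 184, kind="diagnosis", code="F33.1")])
    assert label_window(tl3, rec, 365).status == "control"


@pytest.mark.parametrize(
    "kind,code,is_outcome",
    [
        ("diagnosis", "F06.3", True),
        ("diagnosis", "f063", True),  # dot-tolerant, case-insensitive
        ("diagnosis", "F41.1", True),
        ("diagnosis", "F20.0", False),  # schizophrenia: not in the sets
        ("diagnosis", "E11.9", False),
        ("medication", "N06AX11", True),
        ("medication", "n05ba01", True),
        ("medication", "N05A L01", False),  # antipsychotic prefix N05A only via N05B
        ("medication", "A10BA02", False),
    ],
)
def test_code_set_prefix_matching(kind, code, is_outcome):
    assert OutcomeCodeSets().is_outcome(kind, code.replace(" ", "")) is is_outcome


def test_non_matching_codes_are_ignored_by_the_labeller():
    rec = make_record("r1")
    tl = make_timeline([rec], [OutcomeEvent(date=1100, kind="diagnosis", code="E11.9")])
    assert label_window(tl, rec, 365).status == "control"


def test_record_must_belong_to_timeline():
    rec = make_record("r1", pid="p1")
    tl = make_timeline([make_record("r2", pid="p2")], [])
    with pytest.raises(ValueError):
        label_window(tl, rec, 365)


# -- merging ------------------------------------------------------------
def test_merge_keeps_latest_of_each_week_cluster():
    recs = [make_record("a", discharge=1000), make_record("b", discharge=1003), make_record("c", discharge=1020)]
    kept = merge_repeats(recs)
    assert [r.record_id for r in kept] == ["b", "c"]


def test_merge_single_record_unchanged():
    recs = [make_record("a")]
    assert merge_repeats(recs) == recs


def test_merge_applies_transitive_closure():
    recs = [make_record("a", discharge=1000), make_record("b", discharge=1006), make_record("c", discharge=1012)]
    kept = merge_repeats(recs)
    assert [r.record_id for r in kept] == ["c"]


# -- matching -----------------------------------------------------------
def candidates(n, prefix, rng, days=None):
    return [
        MatchCandidate(
            record_id=f"{prefix}{i:03d}", patient_id=f"{prefix}{i:03d}",
            discharge_date=float(rng.integers(0, 1000)),
            days_to_event_or_window_end=float(days if days is not None else rng.integers(1, 366)),
        )
        for i in range(n)
    ]


def test_ratio_three_matching_yields_exact_group_sizes():
    rng = np.random.default_rng(0)
    cases = candidates(10, "c", rng)
    controls = candidates(100, "k", rng, days=365)
    ds = propensity_match(cases, controls, MatchConfig(control_ratio=3))
    labels = ds.labels
    assert (labels == 1).sum() == 10 and (labels == 0).sum() == 30
    groups = {}
    for cand, lab, g in ds.entries:
        groups.setdefault(g, []).append(lab)
    assert all(sorted(v) == [0, 0, 0, 1] for v in groups.values())
    ids = [c.record_id for c, _, _ in ds.entries]
    assert len(ids) == len(set(ids))  # no record reused


def test_identical_covariates_still_give_exact_ratio():
    rng = np.random.default_rng(1)
    cases = [MatchCandidate(f"c{i}", f"c{i}", 500.0, 100.0) for i in range(5)]
    controls = [MatchCandidate(f"k{i}", f"k{i}", 500.0, 100.0) for i in range(20)]
    ds = propensity_match(cases, controls, MatchConfig(control_ratio=3))
    assert (ds.labels == 0).sum() == 15


def test_greedy_matching_agrees_with_exhaustive_oracle():
    """2 cases, 10 controls, non-degenerate covariates: greedy nearest-logit
    selection must equal a brute-force search over control assignments."""
    rng = np.random.default_rng(2)
    cases = [
        MatchCandidate("c0", "c0", 100.0, 40.0),
        MatchCandidate("c1", "c1", 700.0, 300.0),
    ]
    controls = [
        MatchCandidate(f"k{i}", f"k{i}", float(d), float(dd))
        for i, (d, dd) in enumerate(
            [(90, 80), (120, 50), (800, 280), (650, 330), (400, 180),
             (150, 60), (680, 310), (50, 30), (760, 250), (410, 200)]
        )
    ]
    ds = propensity_match(cases, controls, MatchConfig(control_ratio=3))
    assert not ds.provenance["match_report"]["degenerate_fallback"]

    # independent oracle: refit the same propensity model, then for the
    # greedy case order enumerate all control triples minimising total
    # |logit| distance without replacement
    from sklearn.linear_model import LogisticRegression

    X = np.array([[c.discharge_date, c.days_to_event_or_window_end] for c in cases + controls])
    y = np.array([1, 1] + [0] * 10)
    Xs = (X - X.mean(0)) / X.std(0)
    lr = LogisticRegression(max_iter=1000, random_state=0).fit(Xs, y)
    logit = Xs @ lr.coef_[0] + lr.intercept_[0]
    case_order = sorted([0, 1], key=lambda i: -logit[i])
    remaining = set(range(10))
    expected = {}
    for ci in case_order:
        best = min(
            itertools.combinations(sorted(remaining), 3),
            key=lambda t: sum(abs(logit[2 + j] - logit[ci]) for j in t),
        )
        expected[cases[ci].record_id] = {controls[j].record_id for j in best}
        remaining -= set(best)

    got = {}
    for cand, lab, g in ds.entries:
        got.setdefault(g, {"case": None, "ctl": set()})
        if lab == 1:
            got[g]["case"] = cand.record_id
        else:
            got[g]["ctl"].add(cand.record_id)
    for g, d in got.items():
        assert d["ctl"] == expected[d["case"]]


def test_insufficient_controls_error_names_the_shortfall():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError, match="insufficient controls"):
        propensity_match(candidates(5, "c", rng), candidates(10, "k", rng), MatchConfig())


@pytest.mark.parametrize("seed", range(5))
def test_matching_does_not_worsen_covariate_balance(seed):
    """Post-match SMD on each covariate ≤ pre-match SMD on synthetic cohorts
    whose case and control discharge-time distributions genuinely differ."""
    rng = np.random.default_rng(200 + seed)
    cases = [
        MatchCandidate(f"c{i:03d}", f"c{i:03d}", float(rng.normal(650, 100)),
                       float(rng.integers(1, 366)))
        for i in range(30)
    ]
    controls = [
        MatchCandidate(f"k{i:03d}", f"k{i:03d}", float(rng.normal(480, 160)), 365.0)
        for i in range(250)
    ]
    ds = propensity_match(cases, controls, MatchConfig(control_ratio=3))
    rep = ds.provenance["match_report"]
    for cov in ("discharge_date", "days_to_event_or_window_end"):
        assert rep["smd_after"][cov] <= rep["smd_before"][cov] + 1e-12


def test_matching_is_deterministic(strong_data):
    a = build_cohort(strong_data["timelines"], 365)
    b = build_cohort(strong_data["timelines"], 365)
    assert [(c.record_id, l, g) for c, l, g in a.entries] == [
        (c.record_id, l, g) for c, l, g in b.entries
    ]


# -- cohort-level properties --------------------------------------------
def test_every_record_classified_exactly_once(strong_data, strong_cohort):
    prov = strong_cohort.provenance
    n_input = sum(len(t.admissions) for t in strong_data["timelines"])
    assert prov["n_input_records"] == n_input
    accounted = (
        prov["n_merged_away"]
        + sum(prov["n_excluded"].values())
        + prov["n_cases"]
        + prov["n_controls_eligible"]
    )
    assert accounted == n_input
    assert prov["n_controls_eligible"] == prov["n_controls_matched"] + prov["n_controls_unmatched"]


def test_windows_produce_nested_case_sets(strong_data):
    code_sets = OutcomeCodeSets()
    case_ids = {}
    for w in (30, 180, 365):
        ids = set()
        for tl in strong_data["timelines"]:
            for rec in merge_repeats(tl.admissions):
                if label_window(tl, rec, w, code_sets).status == "case":
                    ids.add(rec.record_id)
        case_ids[w] = ids
    assert case_ids[30] <= case_ids[180] <= case_ids[365]
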
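"""Outlier screening, quantile discretization, hash embedding, assembly."""

from __future__ import annotations

import numpy as np
import pytest

from contrastive_ehr.preprocessing import (
    DEFAULT_STOP_TOKENS,
    FeatureSchema,
    assemble_record,
    detect_outliers,
    embed_static,
    fit_discretizer,
    fit_schema,
)
from contrastive_ehr.synthetic_ehr import SyntheticConfig, generate_timelines, read_timelines, write_timelines


# -- outliers -----------------------------------------------------------
@pytest.mark.parametrize("seed", range(5))
def test_planted_10_sigma_point_is_flagged(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((200, 1))
    x[137] = 10.0
    mask = detect_outliers(x, contamination=0.01, seed=seed)
    assert mask[137]
    assert mask.sum() <= 10  # roughly the contamination fraction


def test_identical_rows_are_never_flagged():
    mask = detect_outliers(np.ones((50, 3)), contamination=0.1, seed=0)
    assert not mask.any()


def test_outlier_mask_is_deterministic():
    x = np.random.default_rng(1).standard_normal((100, 2))
    m1 = detect_outliers(x, 0.05, seed=9)
    m2 = detect_outliers(x, 0.05, seed=9)
    assert np.array_equal(m1, m2)


@pytest.mark.parametrize("bad", [{"contamination": 0.7}, {"contamination": 0.0}])
def test_outlier_contamination_validated(bad):
    with pytest.raises(ValueError):
        detect_outliers(np.zeros((20, 1)), seed=0, **bad)


def test_outlier_screen_requires_enough_rows():
    with pytest.raises(ValueError):
        detect_outliers(np.zeros((10, 1)), 0.1, seed=0)


# -- discretization -----------------------------------------------------
def test_quantile_edges_match_brute_force_and_clamp():
    values = np.arange(1.0, 11.0)
    edges = fit_discretizer(values, n_bins=5)
    expected = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    assert np.allclose(edges, expected)
    schema = FeatureSchema(
        n_bins=5, embed_dim=8, history_max_len=8, feature_order=["v"],
        numeric_edges={"v": list(edges)}, categorical_levels={},
    )
    assert schema.discretize("v", 1.0) == 0
    assert schema.discretize("v", 10.0) == 4
    assert schema.discretize("v", -100.0) == 0  # clamps below
    assert schema.discretize("v", 100.0) == 4  # clamps above


def test_constant_feature_collapses_to_single_bin():
    edges = fit_discretizer(np.full(20, 3.7), n_bins=10)
    assert len(edges) == 0
    schema = FeatureSchema(
        n_bins=10, embed_dim=8, history_max_len=8, feature_order=["c"],
        numeric_edges={"c": []}, categorical_levels={},
    )
    assert schema.discretize("c", 3.7) == 0
    assert schema.discretize("c", -5.0) == 0


def test_missing_value_maps_to_reserved_bin():
    schema = FeatureSchema(
        n_bins=4, embed_dim=8, history_max_len=8, feature_order=["v"],
        numeric_edges={"v": [0.0]}, categorical_levels={},
    )
    assert schema.discretize("v", None) == schema.missing_bin == 4
    assert schema.discretize("v", float("nan")) == 4


def test_unknown_feature_error_names_the_feature():
    schema = FeatureSchema(
        n_bins=4, embed_dim=8, history_max_len=8, feature_order=["v"],
        numeric_edges={"v": [0.0]}, categorical_levels={},
    )
    with pytest.raises(KeyError, match="nope"):
        schema.discretize("nope", 1.0)


def test_fit_discretizer_rejects_single_bin():
    with pytest.raises(ValueError):
        fit_discretizer(np.arange(10.0), n_bins=1)


# -- static embedding ---------------------------------------------------
def test_hash_embedding_deterministic_and_unit_norm():
    a = embed_static(["HbA1c"], 64)
    b = embed_static(["HbA1c"], 64)
    assert np.array_equal(a, b)
    assert abs(np.linalg.norm(a[0]) - 1.0) < 1e-6


def test_distinct_tokens_are_nearly_orthogonal_at_dim_64():
    rng = np.random.default_rng(0)
    tokens = [f"tok{i}" for i in range(2000)]
    E = embed_static(tokens, 64)
    pairs = rng.integers(0, 2000, size=(1000, 2))
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    cos = np.abs(np.einsum("ij,ij->i", E[pairs[:, 0]], E[pairs[:, 1]]))
    assert np.quantile(cos, 0.99) < 0.5


def test_empty_input_gives_empty_sequence():
    assert embed_static([], 16).shape == (0, 16)


def test_embedding_dim_validated():
    with pytest.raises(ValueError):
        embed_static(["x"], 0)


# -- schema fitting and assembly ----------------------------------------
def test_assembled_structured_sequence_has_one_slot_per_feature(small_data, small_schema):
    rec = small_data["records"][0]
    enc = assemble_record(rec, small_schema)
    n_labs = len(rec.labs)
    assert enc.e_bins.shape == (n_labs + 3,)  # + age, sex, marital_status
    assert enc.e_names.shape == (n_labs + 3, small_schema.embed_dim)
    assert enc.d_tokens == sorted(rec.diagnosis_codes)


def test_stop_tokens_filtered_and_empty_history_flagged(small_data, small_schema):
    rec = small_data["records"][0]
    rec2 = type(rec)(**{**rec.__dict__, "record_id": "x", "history_tokens": ["unknown", "unclear"]})
    enc = assemble_record(rec2, small_schema)
    assert enc.history_empty
    assert enc.n_embed.shape == (0, small_schema.embed_dim)


def test_record_with_unknown_lab_is_rejected(small_data, small_schema):
    rec = small_data["records"][0]
    bad = type(rec)(**{**rec.__dict__, "labs": rec.labs + [("mystery", 1.0)]})
    with pytest.raises(KeyError, match="mystery"):
        assemble_record(bad, small_schema)


def test_jsonl_round_trip_preserves_encoding(tmp_path, small_data, small_schema):
    write_timelines(small_data["timelines"][:20], tmp_path / "t.jsonl")
    back = [r for t in read_timelines(tmp_path / "t.jsonl") for r in t.admissions]
    orig = [r for t in small_data["timelines"][:20] for r in t.admissions]
    for a, b in zip(orig, back):
        assert assemble_record(a, small_schema) == assemble_record(b, small_schema)


def test_assembly_is_idempotent(small_data, small_schema):
    rec = small_data["records"][3]
    assert assemble_record(rec, small_schema) == assemble_record(rec, small_schema)


def test_schema_edges_depend_on_training_split_only(small_data):
    """Different training splits move the edges; held-out records never do."""
    records = small_data["records"]
    half = len(records) // 2
    s_a = fit_schema(records[:half], n_bins=10, embed_dim=16)
    s_b = fit_schema(records[half:], n_bins=10, embed_dim=16)
    s_a2 = fit_schema(records[:half], n_bins=10, embed_dim=16)
    name = small_data["config"].lab_names()[0]
    assert s_a.numeric_edges[name] != s_b.numeric_edges[name]
    assert s_a.numeric_edges[name] == s_a2.numeric_edges[name]  # refit identical


def test_schema_json_round_trip(tmp_path, small_schema):
    p = tmp_path / "schema.json"
    small_schema.to_json(p)
    back = FeatureSchema.from_json(p)
    assert back.feature_order == small_schema.feature_order
    assert back.numeric_edges == {k: list(v) for k, v in small_schema.numeric_edges.items()}
    assert back.stop_tokens == small_schema.stop_tokens
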
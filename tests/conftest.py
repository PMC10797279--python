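"""Shared fixtures.

The expensive artifacts (strong-signal dataset, pre-trained encoder, matched
cohort) are session-scoped so the training-based tests share one pre-training
run instead of repeating it.
"""

from __future__ import annotations

import numpy as np
import pytest

from contrastive_ehr.cohorts import build_cohort
from contrastive_ehr.preprocessing import assemble_record, fit_schema
from contrastive_ehr.pretraining import EncoderConfig, pretrain
from contrastive_ehr.synthetic_ehr import SyntheticConfig, generate_timelines, strong_signal_config

STRONG_SEED = 7


@pytest.fixture(scope="session")
def small_data():
    """Default-signal dataset: timelines, ground truth, records."""
    cfg = SyntheticConfig(n_patients=200, seed=11)
    timelines, truths = generate_timelines(cfg)
    records = [r for t in timelines for r in t.admissions]
    return {"config": cfg, "timelines": timelines, "truths": truths, "records": records}


@pytest.fixture(scope="session")
def small_schema(small_data):
    return fit_schema(small_data["records"], n_bins=10, embed_dim=32)


@pytest.fixture(scope="session")
def small_encoded(small_data, small_schema):
    return [assemble_record(r, small_schema) for r in small_data["records"]]


@pytest.fixture(scope="session")
def strong_data():
    """Strong-signal study condition (~2000 records, Bayes AUC ≈ 0.93)."""
    cfg = strong_signal_config(n_patients=1000, seed=STRONG_SEED)
    timelines, truths = generate_timelines(cfg)
    records = [r for t in timelines for r in t.admissions]
    return {"config": cfg, "timelines": timelines, "truths": truths, "records": records}


@pytest.fixture(scope="session")
def strong_schema(strong_data):
    return fit_schema(strong_data["records"], n_bins=10, embed_dim=32)


@pytest.fixture(scope="session")
def strong_encoded(strong_data, strong_schema):
    return {r.record_id: assemble_record(r, strong_schema) for r in strong_data["records"]}


@pytest.fixture(scope="session")
def encoder_config():
    return EncoderConfig(embed_dim=32, n_layers=2, fusion_layers=2, epochs=10, batch_size=64, seed=0)


@pytest.fixture(scope="session")
def pretrained(strong_encoded, strong_schema, encoder_config):
    """One shared contrastive pre-training run on the strong-signal data."""
    return pretrain(list(strong_encoded.values()), encoder_config, strong_schema)


@pytest.fixture(scope="session")
def strong_cohort(strong_data):
    """365-day matched case-control cohort on the strong-signal data."""
    return build_cohort(strong_data["timelines"], 365)


@pytest.fixture(scope="session")
def cohort_arrays(strong_cohort, strong_encoded):
    records = [strong_encoded[c.record_id] for c, _, _ in strong_cohort.entries]
    labels = strong_cohort.labels
    pids = [c.patient_id for c, _, _ in strong_cohort.entries]
    return records, labels, pids
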
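"""Turn raw discharge records into model-ready encoded inputs.

Pipeline per the two-stage design: numeric lab values are screened with an
isolation forest (flagged cells become missing), discretized into quantile
bins fitted on training data only, and every structured feature is encoded as
(bin index, feature-name embedding).  Text-like fields (history tokens,
diagnosis and medication code names) are statically embedded with a
deterministic hash embedding: each token maps to a fixed pseudo-random
unit-norm vector derived from a SHA-256 hash of the token string, so the
embedding is identical across runs and machines and needs no model weights.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from sklearn.ensemble import IsolationForest

from .synthetic_ehr import DischargeRecord

__all__ = [
    "FeatureSchema",
    "EncodedInputs",
    "detect_outliers",
    "fit_discretizer",
    "embed_static",
    "fit_schema",
    "assemble_record",
    "DEFAULT_STOP_TOKENS",
]

logger = logging.getLogger(__name__)

# non-informative history descriptions dropped before embedding
DEFAULT_STOP_TOKENS = frozenset({"unclear", "unknown", "none", "na"})

DEMOGRAPHIC_NUMERIC = ("age",)
DEMOGRAPHIC_CATEGORICAL = ("sex", "marital_status")


def detect_outliers(values: np.ndarray, contamination: float, seed: int) -> np.ndarray:
    """Flag ~`contamination` fraction of rows as outliers (isolation forest).

    `values` is (n_rows, n_cols); missing entries (NaN) are mean-imputed for
    scoring only.  An all-constant matrix yields no outliers (with a warning):
    no row can be isolated earlier than any other.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    if n < 16:
        raise ValueError(f"need >= 16 rows for outlier screening, got {n}")
    if not 0.0 < contamination < 0.5:
        raise ValueError(f"contamination must be in (0, 0.5), got {contamination}")
    col_mean = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(values), col_mean, values)
    if np.allclose(filled, filled[0]):
        logger.warning("outlier screening skipped: all rows identical")
        return np.zeros(n, dtype=bool)
    forest = IsolationForest(contamination=contamination, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on tiny n
        flags = forest.fit_predict(filled) == -1
    return flags


def fit_discretizer(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin edges for one feature, fitted on training values only.

    Returns the inner edges (deduplicated); a constant feature yields no
    edges, i.e. a single effective bin.  Values at an edge fall in the lower
    bin; values outside the fitted range clamp to the first/last bin.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0 or vals.min() == vals.max():
        return np.array([])  # constant (or absent) feature: one effective bin
    qs = np.arange(1, n_bins) / n_bins
    return np.unique(np.quantile(vals, qs))


@lru_cache(maxsize=65536)
def _hash_vector(token: str, dim: int) -> np.ndarray:
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    seed = int.from_bytes(digest[:8], "big") % (2**32)
    v = np.random.default_rng(seed).standard_normal(dim)
    v /= np.linalg.norm(v)
    v.setflags(write=False)
    return v


def embed_static(tokens: list[str] | str, dim: int) -> np.ndarray:
    """Fixed unit-norm embedding per token, identical across runs/machines."""
    if dim <= 0:
        raise ValueError(f"dim must be positive, got {dim}")
    if isinstance(tokens, str):
        tokens = [tokens]
    if not tokens:
        return np.zeros((0, dim))
    return np.stack([_hash_vector(t, dim) for t in tokens])


@dataclass
class FeatureSchema:
    """Structured-feature layout fitted on a training split.

    `feature_order` lists demographics then labs; numeric features carry
    quantile bin edges, categoricals carry their level list (level index is
    the bin).  Bin `n_bins` is reserved for missing/unknown values.
    """

    n_bins: int
    embed_dim: int
    history_max_len: int
    feature_order: list[str]
    numeric_edges: dict[str, list[float]]
    categorical_levels: dict[str, list[str]]
    stop_tokens: frozenset = DEFAULT_STOP_TOKENS

    @property
    def missing_bin(self) -> int:
        return self.n_bins

    @property
    def n_features(self) -> int:
        return len(self.feature_order)

    def discretize(self, feature: str, value) -> int:
        if feature in self.numeric_edges:
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return self.missing_bin
            edges = self.numeric_edges[feature]
            return int(np.searchsorted(edges, float(value), side="left"))
        if feature in self.categorical_levels:
            levels = self.categorical_levels[feature]
            return levels.index(value) if value in levels else self.missing_bin
        raise KeyError(f"feature {feature!r} not in schema")

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_bins": self.n_bins,
            "embed_dim": self.embed_dim,
            "history_max_len": self.history_max_len,
            "feature_order": self.feature_order,
            "numeric_edges": {k: list(map(float, v)) for k, v in self.numeric_edges.items()},
            "categorical_levels": self.categorical_levels,
            "stop_tokens": sorted(self.stop_tokens),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        d = json.loads(Path(path).read_text())
        d["stop_tokens"] = frozenset(d["stop_tokens"])
        return cls(**d)


def fit_schema(
    records: list[DischargeRecord],
    n_bins: int = 10,
    embed_dim: int = 32,
    history_max_len: int = 64,
    outlier_contamination: float = 0.01,
    seed: int = 0,
    stop_tokens: frozenset = DEFAULT_STOP_TOKENS,
) -> FeatureSchema:
    """Fit bin edges and categorical levels on a training split.

    Outlier screening runs per lab feature; flagged cells are excluded from
    edge fitting (and mapped to the missing bin at assembly time by the same
    screening applied by the caller, if desired).
    """
    if not records:
        raise ValueError("cannot fit a schema on zero records")
    lab_names = [name for name, _ in records[0].labs]
    numeric_edges: dict[str, list[float]] = {}

    ages = np.array([r.age for r in records], dtype=float)
    numeric_edges["age"] = list(fit_discretizer(ages, n_bins))

    for j, name in enumerate(lab_names):
        col = np.array(
            [r.labs[j][1] if r.labs[j][1] is not None else np.nan for r in records], dtype=float
        )
        ok = ~np.isnan(col)
        if ok.sum() >= 16:
            flags = detect_outliers(col[ok][:, None], outlier_contamination, seed)
            keep = col[ok][~flags]
        else:
            keep = col[ok]
        numeric_edges[name] = list(fit_discretizer(keep, n_bins))

    categorical_levels = {
        "sex": sorted({r.sex for r in records}),
        "marital_status": sorted({r.marital_status for r in records}),
    }
    feature_order = list(DEMOGRAPHIC_NUMERIC) + list(DEMOGRAPHIC_CATEGORICAL) + lab_names
    return FeatureSchema(
        n_bins=n_bins,
        embed_dim=embed_dim,
        history_max_len=history_max_len,
        feature_order=feature_order,
        numeric_edges={k: list(map(float, v)) for k, v in numeric_edges.items()},
        categorical_levels=categorical_levels,
        stop_tokens=stop_tokens,
    )


@dataclass
class EncodedInputs:
    """Model-ready encoding of one discharge record.

    E is the structured sequence: one slot per demographic/lab feature, each
    a (bin index, name embedding) pair, in `FeatureSchema.feature_order`.
    N/D/M are static embedding sequences for history tokens, diagnosis code
    names and medication code names (token strings retained for attribution).
    """

    record_id: str
    e_bins: np.ndarray  # (n_features,) int
    e_names: np.ndarray  # (n_features, dim)
    n_tokens: list[str]
    n_embed: np.ndarray  # (len_n, dim)
    d_tokens: list[str]
    d_embed: np.ndarray
    m_tokens: list[str]
    m_embed: np.ndarray
    history_empty: bool = False

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EncodedInputs)
            and self.record_id == other.record_id
            and np.array_equal(self.e_bins, other.e_bins)
            and np.array_equal(self.e_names, other.e_names)
            and self.n_tokens == other.n_tokens
            and np.array_equal(self.n_embed, other.n_embed)
            and self.d_tokens == other.d_tokens
            and np.array_equal(self.d_embed, other.d_embed)
            and self.m_tokens == other.m_tokens
            and np.array_equal(self.m_embed, other.m_embed)
        )


def assemble_record(record: DischargeRecord, schema: FeatureSchema) -> EncodedInputs:
    """Encode one record against a fitted schema.

    Slot order is fixed: demographics (age, sex, marital_status) then labs in
    schema order.  History tokens are stop-filtered then truncated to the
    schema's maximum length.  Diagnosis/medication codes are encoded in
    sorted order (the encoders are order-invariant regardless).
    """
    lab_values = dict(record.labs)
    bins = []
    for feat in schema.feature_order:
        if feat == "age":
            bins.append(schema.discretize("age", record.age))
        elif feat == "sex":
            bins.append(schema.discretize("sex", record.sex))
        elif feat == "marital_status":
            bins.append(schema.discretize("marital_status", record.marital_status))
        else:
            if feat not in lab_values:
                raise KeyError(f"record {record.record_id} missing lab feature {feat!r}")
            bins.append(schema.discretize(feat, lab_values[feat]))
    unknown = set(lab_values) - set(schema.feature_order)
    if unknown:
        raise KeyError(f"record {record.record_id} has labs unknown to schema: {sorted(unknown)}")

    dim = schema.embed_dim
    tokens = [t for t in record.history_tokens if t.lower() not in schema.stop_tokens]
    if len(tokens) > schema.history_max_len:
        logger.warning(
            "record %s: history truncated from %d to %d tokens",
            record.record_id, len(tokens), schema.history_max_len,
        )
        tokens = tokens[: schema.history_max_len]
    d_tokens = sorted(record.diagnosis_codes)
    m_tokens = sorted(record.medication_codes)
    return EncodedInputs(
        record_id=record.record_id,
        e_bins=np.array(bins, dtype=np.intp),
        e_names=embed_static(list(schema.feature_order), dim),
        n_tokens=tokens,
        n_embed=embed_static(tokens, dim),
        d_tokens=d_tokens,
        d_embed=embed_static(d_tokens, dim),
        m_tokens=m_tokens,
        m_embed=embed_static(m_tokens, dim),
        history_empty=len(tokens) == 0,
    )
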
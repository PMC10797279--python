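"""End-to-end orchestration: generate → preprocess → cohorts → pretrain →
finetune → evaluate → interpret, with seed fan-out and a run manifest.

A single global seed is deterministically fanned out to per-stage seeds
(``stage_seed = (global_seed * 1009 + stage_index) mod 2³¹``) so any stage
can be re-run in isolation.  The manifest records the configuration, the
per-stage seeds and a SHA-256 hash of every artifact written, making each
output traceable to config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import evaluation, interpretation
from .cohorts import MatchConfig, build_cohort
from .finetuning import FineTuneConfig, finetune
from .preprocessing import assemble_record, fit_schema
from .pretraining import EncoderConfig, pretrain, save_checkpoint
from .synthetic_ehr import SyntheticConfig, generate_timelines, write_ground_truth, write_timelines

__all__ = ["RunConfig", "run_all", "stage_seed"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "preprocess", "cohorts", "pretrain", "finetune", "evaluate", "interpret")


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1009 + STAGES.index(stage)) % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "run_output"
    seed: int = 0
    window_days: int = 365
    k_folds: int = 5
    top_features: int = 20
    n_attributed: int = 16
    generator: SyntheticConfig = field(default_factory=SyntheticConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    finetune: FineTuneConfig = field(default_factory=FineTuneConfig)
    n_bins: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in ("generator", "encoder", "match", "finetune"):
                sub = {"generator": SyntheticConfig, "encoder": EncoderConfig,
                       "match": MatchConfig, "finetune": FineTuneConfig}[f.name]
                if sub is SyntheticConfig and "outcome_latent_weight" in v:
                    v["outcome_latent_weight"] = tuple(v["outcome_latent_weight"])
                kwargs[f.name] = sub(**v)
            else:
                kwargs[f.name] = v
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def validate(self) -> None:
        self.generator.validate()
        if self.window_days not in (30, 180, 365):
            raise ValueError("window_days must be one of 30, 180, 365")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}, "artifacts": {}}
    t0 = time.time()

    def done(stage: str, **info):
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage),
                                     "elapsed_s": round(time.time() - t0, 2), **info}
        logger.info("stage %s done (%.1fs)", stage, time.time() - t0)

    try:
        # generate ------------------------------------------------------
        gen_cfg = dataclasses.replace(config.generator, seed=stage_seed(config.seed, "generate"))
        timelines, truths = generate_timelines(gen_cfg)
        write_timelines(timelines, out / "timelines.jsonl")
        write_ground_truth(truths, out / "ground_truth.jsonl")
        records = [r for t in timelines for r in t.admissions]
        done("generate", n_patients=len(timelines), n_records=len(records))

        # preprocess ----------------------------------------------------
        schema = fit_schema(records, n_bins=config.n_bins,
                            embed_dim=config.encoder.embed_dim,
                            seed=stage_seed(config.seed, "preprocess"))
        schema.to_json(out / "schema.json")
        encoded = {r.record_id: assemble_record(r, schema) for r in records}
        done("preprocess", n_features=schema.n_features)

        # cohorts -------------------------------------------------------
        match_cfg = dataclasses.replace(config.match, seed=stage_seed(config.seed, "cohorts"))
        cohort = build_cohort(timelines, config.window_days, match_cfg)
        _write_cohort(cohort, out / "cohort.csv")
        (out / "cohort_provenance.json").write_text(json.dumps(cohort.provenance, indent=1, default=str))
        done("cohorts", n_cases=cohort.provenance["n_cases"])

        # pretrain ------------------------------------------------------
        enc_cfg = dataclasses.replace(config.encoder, seed=stage_seed(config.seed, "pretrain"))
        pre = pretrain(list(encoded.values()), enc_cfg, schema)
        save_checkpoint(pre, schema, out / "pretrained.npz")
        done("pretrain", final_loss=pre.loss_trace[-1], retrieval=pre.retrieval_trace[-1])

        # finetune ------------------------------------------------------
        ft_cfg = dataclasses.replace(config.finetune, seed=stage_seed(config.seed, "finetune"))
        cohort_records = [encoded[c.record_id] for c, _, _ in cohort.entries]
        labels = cohort.labels
        ft = finetune(pre.encoder, schema, cohort_records, labels, ft_cfg)
        (out / "finetune_metrics.json").write_text(json.dumps(
            {"train_loss": ft.train_loss}, indent=1))
        done("finetune", final_loss=ft.train_loss[-1])

        # evaluate ------------------------------------------------------
        raw_cohort = cohort.records()
        pids = [r.patient_id for r in raw_cohort]

        def trainer(tr_recs, tr_labels, te_recs):
            enc_tr = [encoded[r.record_id] for r in tr_recs]
            enc_te = [encoded[r.record_id] for r in te_recs]
            res = finetune(pre.encoder, schema, enc_tr, tr_labels, ft_cfg)
            return res.model.predict_proba(enc_te)

        metrics = evaluation.kfold_evaluate(
            raw_cohort, labels, pids, k=config.k_folds,
            seed=stage_seed(config.seed, "evaluate"),
            baselines=("logistic",), contrastive_trainer=trainer)
        dca = evaluation.decision_curve(metrics.fold_labels, metrics.fold_scores["contrastive"])
        dca.to_frame().to_csv(out / "decision_curve.csv", index=False)
        (out / "evaluation.json").write_text(json.dumps(metrics.summary(), indent=1))
        done("evaluate", **{m: round(metrics.mean_roc(m), 4) for m in metrics.roc_auc})

        # interpret -----------------------------------------------------
        attr_records = cohort_records[: config.n_attributed]
        result = interpretation.attribute_records(ft.model, attr_records, k=config.top_features)
        result.table.to_csv(out / "top_features.csv", index=False)
        done("interpret", n_attributed=len(attr_records))
    except Exception as exc:
        manifest["failed_stage"] = next(
            (s for s in STAGES if s not in manifest["stages"]), "unknown")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline halted in stage {manifest['failed_stage']}: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["match"]["caliper"] = config.match.caliper
    return d


def _write_cohort(cohort, path: Path) -> None:
    import csv

    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "patient_id", "label", "match_group", "window"])
        for cand, label, group in cohort.entries:
            w.writerow([cand.record_id, cand.patient_id, label, group, cohort.window_days])
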
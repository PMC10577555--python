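"""End-to-end pipeline driver.

Runs qc -> pseudobulk DEG -> consensus signature -> module scores
(aging up/down plus optional senescence sets) -> age-state classifier,
writing each stage's artifact plus a machine-readable manifest. Stage
seeds are derived from the global seed and the stage name, so re-running
with the same configuration reproduces byte-identical outputs, and a
``resume`` run skips stages whose outputs already exist under an
unchanged configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as lio
from .classifier import (CvSpec, SplitSpec, evaluate, make_features,
                         stratified_split, train_rf, variable_importance)
from .deg import DegConfig, run_deg
from .qc import QcConfig, filter_cells, lognormalize
from .scoring import ScoreConfig, compare_groups, module_score, senescence_scores
from .signature import build_membership, consensus_signature, upset_summary
from .synthetic import SynthConfig, generate_dataset

STAGES = ("simulate", "qc", "deg", "signature", "score", "classify")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    out_dir: str = "lungage_run"
    run_id: str = "run"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    senescence_gmt: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    deg: DegConfig = field(default_factory=DegConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    cv: CvSpec = field(default_factory=CvSpec)
    min_celltypes: int = 2

    def validate(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ValueError("input_dir required when simulate is false")
        self.qc.validate()
        self.deg.validate()
        self.score.validate()
        self.split.validate()
        self.cv.validate()
        if self.simulate:
            self.synth.validate()

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _log(out: Path, record: dict) -> None:
    with open(out / "log.jsonl", "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute every stage, writing artifacts and a manifest under out_dir.

    Returns the run directory. A stage failure aborts with the stage name;
    artifacts of completed stages are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    digest = config.digest()
    manifest = {"run_id": config.run_id, "config": config.to_jsonable(),
                "config_digest": digest, "stages": {}}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_digest") == digest:
            manifest["stages"] = old.get("stages", {})

    def done(stage: str, outputs: list[str]) -> bool:
        rec = manifest["stages"].get(stage)
        return bool(rec) and all((out / f).exists() for f in outputs)

    def mark(stage: str, outputs: list[str], **info) -> None:
        manifest["stages"][stage] = {"outputs": outputs, "seed": stage_seed(config.seed, stage), **info}
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        _log(out, {"stage": stage, **info})

    stage = "load"
    try:
        # --- simulate / load ------------------------------------------------
        sim_dir = out / "data"
        if config.simulate:
            if not (resume and done("simulate", ["data/matrix.mtx"])):
                synth = dataclasses.replace(config.synth, seed=stage_seed(config.seed, "simulate"))
                counts, meta, truth = generate_dataset(synth)
                lio.write_mtx_bundle(sim_dir, counts, meta)
                lio.write_ground_truth(sim_dir / "ground_truth.json", truth)
                mark("simulate", ["data/matrix.mtx"], n_cells=len(counts.cells),
                     n_genes=len(counts.genes))
            counts, meta, _ = lio.read_mtx_bundle(sim_dir)
        else:
            counts, meta, report = lio.read_mtx_bundle(config.input_dir)
            mark("simulate", [], loaded_from=str(config.input_dir),
                 unmatched=len(report["cells_without_metadata"]))

        # --- qc -------------------------------------------------------------
        stage = "qc"
        counts, meta, qc_report = filter_cells(counts, meta, config.qc)
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=1))
        lognorm = lognormalize(counts, config.qc.lognorm_scale)
        mark(stage, ["qc_report.json"], **qc_report)

        # --- deg ------------------------------------------------------------
        stage = "deg"
        if resume and done(stage, ["deg_table.tsv"]):
            degs = lio.read_deg_table(out / "deg_table.tsv")
        else:
            degs = run_deg(counts, meta, config.deg)
            lio.write_deg_table(out / "deg_table.tsv", degs)
            mark(stage, ["deg_table.tsv"],
                 n_significant=int((degs["direction"] != "ns").sum()))

        # --- signature ------------------------------------------------------
        stage = "signature"
        mem_up = build_membership(degs, "up")
        mem_down = build_membership(degs, "down")
        sig = consensus_signature(mem_up, mem_down, config.min_celltypes,
                                  provenance=config.run_id)
        lio.write_gmt(out / "signature.gmt",
                      {"LungAge_up": sig.up_genes, "LungAge_down": sig.down_genes})
        (out / "upset.json").write_text(json.dumps(
            {"up": upset_summary(mem_up), "down": upset_summary(mem_down),
             "conflicts": sig.conflicts}, indent=1))
        mark(stage, ["signature.gmt", "upset.json"],
             n_up=len(sig.up_genes), n_down=len(sig.down_genes))

        # --- score ----------------------------------------------------------
        stage = "score"
        score_cfg = dataclasses.replace(config.score, seed=stage_seed(config.seed, stage))
        parts = []
        for name, genes in (("aging_up", sig.up_genes), ("aging_down", sig.down_genes)):
            if len(genes) >= score_cfg.min_set_genes_present:
                parts.append(module_score(lognorm, genes, score_cfg, set_name=name))
        if config.senescence_gmt:
            sen_sets = lio.read_gmt(config.senescence_gmt)
            parts.append(senescence_scores(lognorm, sen_sets, score_cfg))
        scores = pd.concat(parts, ignore_index=True)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        comp = compare_groups(scores, meta, by_celltype=True)
        comp.to_csv(out / "score_comparisons.tsv", sep="\t", index=False)
        mark(stage, ["scores.tsv", "score_comparisons.tsv"], n_sets=scores["set"].nunique())

        # --- classify -------------------------------------------------------
        stage = "classify"
        split = dataclasses.replace(config.split, seed=stage_seed(config.seed, "split"))
        cv = dataclasses.replace(config.cv, seed=stage_seed(config.seed, "cv"))
        report: dict = {}
        for subset in ("all", "up", "down"):
            genes = sig.genes(subset)
            if len(genes) == 0:
                report[subset] = {"skipped": "empty signature"}
                continue
            X, y = make_features(lognorm, sig, meta, subset)
            train_ids, test_ids = stratified_split(meta.loc[X.index], split)
            model, cvres = train_rf(X.loc[train_ids], y.loc[train_ids], cv)
            ev = evaluate(model, X.loc[test_ids], y.loc[test_ids],
                          cell_types=meta.loc[test_ids, "cell_type"])
            entry = {**cvres, **ev, "n_features": X.shape[1],
                     "n_train": len(train_ids), "n_test": len(test_ids)}
            if subset == "all":
                imp = variable_importance(model, top_k=20, deg_table=degs)
                imp.to_csv(out / "importance.tsv", sep="\t", index=False)
                entry["top_importance"] = imp["gene"].tolist()
            report[subset] = entry
        (out / "classifier_report.json").write_text(json.dumps(report, indent=1, default=str))
        mark(stage, ["classifier_report.json"],
             auroc_all=report.get("all", {}).get("auroc"))
    except Exception as e:
        _log(out, {"stage": "error", "failed_stage": stage, "message": str(e)})
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e
    return out
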
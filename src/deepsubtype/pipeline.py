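"""End-to-end pipeline: cohort -> aberration calls -> feature filters ->
DBN ensemble -> consensus of consensus -> survival and correlates.

The pipeline is a sequence of named stages, each of which writes its
artifacts into the output directory and records them (with SHA-256
checksums) in ``manifest.json``.  A rerun with ``resume=True`` skips any
stage whose artifacts are present and unchanged, and -- because every stage
seeds its own generator from the global seed -- produces artifacts identical
to an uninterrupted run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed, sha256_file
from .aberration import aberration_matrix
from .consensus import (ConsensusMatrix, consensus_cluster,
                        consensus_of_consensus, pac, select_k)
from .dbn import DeepBeliefNetwork, TrainConfig
from .downstream import (SurvivalRecords, cluster_correlates,
                         export_wordcloud_table, km_curves, logrank_test)
from .features import filter_features, write_filter_report
from .synthdata import CohortConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("cohort", "aberration", "filter", "train", "cluster",
          "survival", "correlates")


def default_ensemble(seed: int = 0) -> list[TrainConfig]:
    """Six desk-scale model configurations with varied architectures,
    mirroring the use of several independently trained DBNs as an ensemble."""
    shapes = [(55, 25, 8), (65, 35, 8), (65, 35, 10),
              (65, 35, 10), (70, 50, 12), (65, 35, 10)]
    out = []
    for i, shape in enumerate(shapes):
        out.append(TrainConfig(layer_sizes=shape, lr_pretrain=0.05,
                               lr_finetune=0.3, epochs_pretrain=30,
                               epochs_finetune=150, batch_size=50,
                               seed=derive_seed(seed, 100 + i)))
    return out


@dataclass
class PipelineConfig:
    """Everything one run needs: cohort source, per-stage parameters,
    model ensemble, clustering grid, output directory, global seed."""

    outdir: str = "deepsubtype_run"
    seed: int = 0
    input_dir: str | None = None              # read a cohort instead of simulating
    cohort: CohortConfig | None = None        # synthetic cohort config
    tail: float = 0.001
    low_sd: float = 0.2
    fold: float = 3.0
    filter_p: float = 0.90
    filter_r_max: float = 0.85
    models: list[TrainConfig] = field(default_factory=list)
    k_list: tuple[int, ...] = (2, 3, 4, 5, 6)
    trials: int = 100
    fraction: float = 0.8
    top_k_correlates: int = 10
    # ensemble screening: a model whose final training cross-entropy exceeds
    # this multiple of the ensemble's best is excluded from pooling (a badly
    # converged autoencoder has collapsed representations); at least the two
    # best models are always kept
    model_ce_ratio: float = 2.0

    def __post_init__(self) -> None:
        if not self.models:
            self.models = default_ensemble(self.seed)
        if not self.k_list:
            raise ValueError("k_list must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            c = dict(raw["cohort"])
            for key in ("control_mean_range", "control_sd_range",
                        "subtype_hazard_ratios"):
                if key in c and c[key] is not None:
                    c[key] = tuple(c[key])
            raw["cohort"] = CohortConfig(**c)
        if "models" in raw and raw["models"]:
            raw["models"] = [TrainConfig(**{**m, "layer_sizes":
                                            tuple(m["layer_sizes"])})
                             for m in raw["models"]]
        if "k_list" in raw:
            raw["k_list"] = tuple(raw["k_list"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}, "version": __version__}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_done(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        for fname, digest in entry["files"].items():
            p = self.path.parent / fname
            if not p.exists() or sha256_file(p) != digest:
                return False
        return True

    def record(self, stage: str, files: list[Path]) -> None:
        self.data["stages"][stage] = {
            "files": {p.name: sha256_file(p) for p in files},
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=2))

    def finalize(self, cfg: PipelineConfig) -> None:
        self.data["config"] = cfg.to_jsonable()
        self.data["seed"] = cfg.seed
        self.path.write_text(json.dumps(self.data, indent=2))


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> Path:
    """Run all stages; returns the artifact directory.

    Any stage failure propagates with the stage name; completed stages are
    checkpointed in the manifest, so a rerun with ``resume=True`` picks up
    where the failed run stopped and yields identical final artifacts.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")

    pkg_logger = logging.getLogger("deepsubtype")
    pkg_logger.setLevel(logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    pkg_logger.addHandler(handler)

    def _stage(name):
        def deco(fn):
            def run():
                if resume and manifest.stage_done(name):
                    logger.info("stage %s: checkpoint valid, skipping", name)
                    return
                logger.info("stage %s: start", name)
                try:
                    files = fn()
                except Exception as exc:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline failed at stage "
                                       f"{name!r}: {exc}") from exc
                manifest.record(name, files)
                logger.info("stage %s: done (%d files)", name, len(files))
            return run
        return deco

    @_stage("cohort")
    def stage_cohort():
        if cfg.input_dir is not None:
            cohort = read_cohort(cfg.input_dir)
        else:
            ccfg = cfg.cohort or CohortConfig(seed=derive_seed(cfg.seed, 1))
            cohort = generate_cohort(ccfg)
        return write_cohort(cohort, out / "cohort", overwrite=True)

    @_stage("aberration")
    def stage_aberration():
        cohort = read_cohort(out / "cohort")
        binary, audit = aberration_matrix(cohort, tail=cfg.tail,
                                          low_sd=cfg.low_sd, fold=cfg.fold)
        p1 = out / "aberrations.tsv"
        binary.T.rename_axis("gene_id").to_csv(p1, sep="\t")
        files = [p1]
        if audit is not None:
            p2 = out / "masking_audit.tsv"
            audit.to_csv(p2, sep="\t", index=False)
            files.append(p2)
        return files

    @_stage("filter")
    def stage_filter():
        cohort = read_cohort(out / "cohort")
        binary = pd.read_csv(out / "aberrations.tsv", sep="\t", index_col=0).T
        tissues = cohort.tissue.loc[binary.index]
        filtered, report = filter_features(binary, tissues,
                                           p=cfg.filter_p, r_max=cfg.filter_r_max)
        p1 = out / "filtered.tsv"
        filtered.T.rename_axis("gene_id").to_csv(p1, sep="\t")
        p2 = out / "filter_report.tsv"
        write_filter_report(report, p2)
        return [p1, p2]

    @_stage("train")
    def stage_train():
        filtered = pd.read_csv(out / "filtered.tsv", sep="\t", index_col=0).T
        files = []
        metrics = []
        for i, mcfg in enumerate(cfg.models):
            res = DeepBeliefNetwork(filtered, layer_sizes=mcfg.layer_sizes,
                                    config=mcfg).fit()
            pm = out / f"model_{i}.h5"
            res.save(pm)
            files.append(pm)
            pe = out / f"encodings_{i}.tsv"
            res.encode().rename_axis("sample_id").to_csv(pe, sep="\t")
            files.append(pe)
            (out / f"model_{i}_summary.txt").write_text(res.summary())
            files.append(out / f"model_{i}_summary.txt")
            metrics.append({
                "model": i,
                "layer_sizes": "-".join(map(str, mcfg.layer_sizes)),
                "final_cross_entropy": res.training_log[
                    "finetune_cross_entropy"][-1],
                "final_mse": res.training_log["finetune_mse"][-1],
            })
        pmx = out / "model_metrics.tsv"
        pd.DataFrame(metrics).to_csv(pmx, sep="\t", index=False)
        files.append(pmx)
        return files

    @_stage("cluster")
    def stage_cluster():
        files = []
        # screen the ensemble: drop models whose autoencoder failed to
        # converge (final cross-entropy far above the best model's) -- their
        # top-layer codes collapse distinct groups and would bias the vote
        metrics = pd.read_csv(out / "model_metrics.tsv", sep="\t")
        ce = metrics["final_cross_entropy"]
        keep_mask = ce <= cfg.model_ce_ratio * ce.min()
        kept = list(metrics.loc[keep_mask, "model"])
        if len(kept) < 2:
            kept = list(metrics.nsmallest(2, "final_cross_entropy")["model"])
        dropped = sorted(set(metrics["model"]) - set(kept))
        if dropped:
            logger.info("cluster: excluded models %s (poor convergence)",
                        dropped)
        sel_path = out / "ensemble_selection.tsv"
        metrics.assign(kept=metrics["model"].isin(kept)).to_csv(
            sel_path, sep="\t", index=False)
        files.append(sel_path)

        pooled_by_k: dict[int, ConsensusMatrix] = {}
        for k in cfg.k_list:
            per_model = []
            for i in kept:
                enc = pd.read_csv(out / f"encodings_{i}.tsv", sep="\t",
                                  index_col=0)
                cm, _ = consensus_cluster(
                    enc, k, trials=cfg.trials, fraction=cfg.fraction,
                    seed=derive_seed(cfg.seed, 200 + i, k))
                per_model.append(cm)
            if len(per_model) > 1:
                pooled_by_k[k], _ = consensus_of_consensus(per_model, k)
            else:
                pooled_by_k[k] = per_model[0]
        sel = select_k(pooled_by_k)
        cm = pooled_by_k[sel.k]
        from .consensus import hierarchical_cluster
        final = hierarchical_cluster(1.0 - cm.values, sel.k, precomputed=True)
        final.sample_ids = cm.sample_ids

        p1 = out / "consensus_matrix.tsv"
        cm.frame().rename_axis("sample_id").to_csv(p1, sep="\t")
        p2 = out / "assignments.tsv"
        final.series().rename_axis("sample_id").to_frame().to_csv(p2, sep="\t")
        p3 = out / "pac_by_k.tsv"
        sel.table.to_csv(p3, sep="\t", index=False)
        files += [p1, p2, p3]
        try:
            from .consensus import plot_consensus_heatmap
            p4 = out / "consensus_heatmap.png"
            plot_consensus_heatmap(cm, p4)
            files.append(p4)
        except Exception as exc:  # plotting is best-effort
            logger.warning("heatmap skipped: %s", exc)
        return files

    @_stage("survival")
    def stage_survival():
        clinical = pd.read_csv(out / "cohort" / "clinical.tsv",
                               sep="\t").set_index("sample_id")
        assignment = pd.read_csv(out / "assignments.tsv", sep="\t",
                                 index_col=0)["cluster"]
        rec = SurvivalRecords.from_frames(clinical, assignment)
        p1 = out / "km_curves.tsv"
        km_curves(rec).to_csv(p1, sep="\t", index=False)
        lr = logrank_test(rec)
        p2 = out / "logrank.txt"
        p2.write_text(f"statistic\t{lr.statistic:.6g}\ndf\t{lr.df}\n"
                      f"p_value\t{lr.p_value:.6g}\n")
        files = [p1, p2]
        try:
            from .downstream import plot_km
            p3 = out / "km_plot.png"
            plot_km(rec, p3)
            files.append(p3)
        except Exception as exc:
            logger.warning("KM plot skipped: %s", exc)
        return files

    @_stage("correlates")
    def stage_correlates():
        assignment = pd.read_csv(out / "assignments.tsv", sep="\t",
                                 index_col=0)["cluster"]
        files = []
        sources = {"degs": out / "filtered.tsv",
                   "mutations": out / "cohort" / "mutations.tsv"}
        for name, path in sources.items():
            if not path.exists():
                continue
            feats = pd.read_csv(path, sep="\t", index_col=0).T
            feats = feats.loc[assignment.index]
            table = cluster_correlates(feats, assignment,
                                       top_k=cfg.top_k_correlates)
            ranked = (export_wordcloud_table(table)
                      if not table.top.empty else table.top.assign(weight=[]))
            ranked = ranked.assign(n=table.n)
            p1 = out / f"correlates_{name}.tsv"
            ranked.to_csv(p1, sep="\t", index=False)
            p2 = out / f"correlates_{name}_full.tsv"
            table.full.to_csv(p2, sep="\t", index=False)
            files += [p1, p2]
        return files

    try:
        for runner in (stage_cohort, stage_aberration, stage_filter,
                       stage_train, stage_cluster, stage_survival,
                       stage_correlates):
            runner()
        manifest.finalize(cfg)
    finally:
        pkg_logger.removeHandler(handler)
        handler.close()
    return out
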
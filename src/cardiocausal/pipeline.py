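"""End-to-end orchestration: simulate/ingest -> extract -> aggregate ->
screen -> discover -> fuse -> classify -> report.

Each stage reads the previous stage's on-disk artifacts and writes its own
into the run directory, recording seeds, row counts and content hashes in
``manifest.json``; completed stages are skipped on re-run (resumable,
idempotent) unless forced.  Configuration is a validated YAML file; every
random draw traces back to seeds recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import aggregate as agg
from . import classify as clf
from . import cohort as coh
from . import fusion as fus
from . import waveforms as wf
from .ges import ScoreModel
from .graphs import Cpdag
from .registry import write_registry_json

__all__ = ["PipelineConfig", "Pipeline", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "extract",
    "aggregate",
    "screen",
    "discover",
    "fuse",
    "classify",
    "report",
)


class CohortSettings(BaseModel):
    n_subjects: int = 40
    prevalence: float = 0.5
    segments_per_subject: tuple[int, int] = (6, 6)
    segment_duration_s: tuple[float, float] = (15.0, 15.0)
    sampling_rate_hz: float = 125.0
    heart_rate_bpm: tuple[float, float] = (55.0, 90.0)
    causal_effect: float = 1.0
    confounder_effect: float = 1.2
    noise_sd: float = 0.02

    def to_spec(self, seed: int) -> coh.CohortSpec:
        return coh.CohortSpec(seed=seed, **self.model_dump())


class InputSettings(BaseModel):
    mode: str = "simulate"  # "simulate" | "csv"
    waveforms_csv: str | None = None
    labels_csv: str | None = None

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("simulate", "csv"):
            raise ValueError("input.mode must be 'simulate' or 'csv'")
        return v


class ScreeningSettings(BaseModel):
    test: str = "mannwhitney"
    alpha: float = Field(0.05, gt=0, lt=1)
    cap: int = Field(50, ge=1, le=50)
    fdr: bool = False

    @field_validator("test")
    @classmethod
    def _test(cls, v):
        if v not in ("mannwhitney", "ttest"):
            raise ValueError("screening.test must be 'mannwhitney' or 'ttest'")
        return v


class ScoreSettings(BaseModel):
    kind: str = "bic"
    penalty: float = Field(1.0, gt=0)
    ridge_lambda: float = Field(0.01, gt=0)
    cv_folds: int = Field(10, ge=2)

    def to_model(self, fold_seed: int = 0) -> ScoreModel:
        return ScoreModel(
            kind=self.kind,
            penalty=self.penalty,
            ridge_lambda=self.ridge_lambda,
            cv_folds=self.cv_folds,
            fold_seed=fold_seed,
        )

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("bic", "kernel"):
            raise ValueError("score.kind must be 'bic' or 'kernel'")
        return v


class FusionSettings(BaseModel):
    runs: int = Field(10, ge=1)
    frac: float = Field(0.8, gt=0, le=1)
    threshold: float = Field(0.5, ge=0, lt=1)


class EvaluationSettings(BaseModel):
    folds: int = Field(10, ge=2)
    algorithms: tuple[str, ...] = clf.ALGORITHMS

    @field_validator("algorithms")
    @classmethod
    def _algos(cls, v):
        bad = set(v) - set(clf.ALGORITHMS)
        if bad:
            raise ValueError(
                f"unknown algorithms {sorted(bad)}; valid: {list(clf.ALGORITHMS)}"
            )
        return v


class PipelineConfig(BaseModel):
    output_dir: str = "runs/demo"
    seed: int = 0
    min_beats: int = 10
    input: InputSettings = InputSettings()
    cohort: CohortSettings = CohortSettings()
    screening: ScreeningSettings = ScreeningSettings()
    score: ScoreSettings = ScoreSettings()
    fusion: FusionSettings = FusionSettings()
    evaluation: EvaluationSettings = EvaluationSettings()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner bound to one output directory and config."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest: dict = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )

    # -- bookkeeping ---------------------------------------------------
    def _record(self, stage: str, outputs: list[Path], seed: int | None, t0: float, extra: dict | None = None) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(self.out)): _sha256(p) for p in outputs},
            "seed": seed,
            "runtime_s": round(time.time() - t0, 3),
            **(extra or {}),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def _done(self, stage: str, outputs: list[Path]) -> bool:
        rec = self.manifest["stages"].get(stage)
        return rec is not None and all(p.exists() for p in outputs)

    # -- stages --------------------------------------------------------
    def simulate(self, force: bool = False) -> tuple[Path, Path]:
        wave, labels = self.out / "waveforms.csv", self.out / "labels.csv"
        if self.cfg.input.mode == "csv":
            return Path(self.cfg.input.waveforms_csv), Path(self.cfg.input.labels_csv)
        if self._done("simulate", [wave, labels]) and not force:
            return wave, labels
        t0 = time.time()
        spec = self.cfg.cohort.to_spec(seed=self.cfg.seed)
        records = coh.simulate_waveform_cohort(spec)
        coh.write_cohort_csv(records, self.out)
        self._record("simulate", [wave, labels], self.cfg.seed, t0,
                     {"n_subjects": len(records)})
        return wave, labels

    def extract(self, force: bool = False) -> Path:
        beats = self.out / "beats.csv"
        reg = self.out / "feature_registry.json"
        if self._done("extract", [beats, reg]) and not force:
            return beats
        wave, labels = self.simulate()
        t0 = time.time()
        records = coh.read_cohort_csv(wave, labels, self.cfg.cohort.sampling_rate_hz)
        tables = [wf.extract_record_features(r) for r in records]
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(beats, index=False, float_format="%.6g")
        write_registry_json(reg)
        self._record("extract", [beats, reg], None, t0, {"n_beats": len(table)})
        return beats

    def aggregate(self, force: bool = False) -> Path:
        path = self.out / "summaries.csv"
        if self._done("aggregate", [path]) and not force:
            return path
        beats = self.extract()
        _, labels_path = self.simulate()
        t0 = time.time()
        table = pd.read_csv(beats)
        labels = pd.read_csv(labels_path).set_index("subject_id")["hypertension"]
        summaries = agg.aggregate_cohort(table, labels, min_beats=self.cfg.min_beats)
        summaries.to_csv(path)
        self._record("aggregate", [path], None, t0, {"n_subjects": len(summaries)})
        return path

    def screen(self, force: bool = False) -> Path:
        path = self.out / "screening.tsv"
        if self._done("screen", [path]) and not force:
            return path
        summaries = pd.read_csv(self.aggregate(), index_col="subject_id")
        t0 = time.time()
        labels = summaries["label"]
        s = self.cfg.screening
        frames = []
        for metric in agg.METRICS:
            res = agg.screen_features(
                summaries, labels, metric, alpha=s.alpha, cap=s.cap, test=s.test, fdr=s.fdr
            )
            frames.append(res.frame())
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        self._record("screen", [path], None, t0)
        return path

    def discover(self, force: bool = False) -> Path:
        gdir = self.out / "graphs"
        marker = gdir / "discover_done.json"
        if self._done("discover", [marker]) and not force:
            return gdir
        screen_path = self.screen()
        summaries = pd.read_csv(self.aggregate(), index_col="subject_id")
        t0 = time.time()
        gdir.mkdir(exist_ok=True)
        screening = pd.read_csv(screen_path, sep="\t")
        model = self.cfg.score.to_model(fold_seed=self.cfg.seed)
        info = {}
        for metric in agg.METRICS:
            feats = screening.loc[
                (screening["metric"] == metric) & screening["retained"], "feature"
            ].tolist()
            feats = [f for f in feats if summaries[f].notna().all()]
            df = summaries[feats].copy()
            df["label"] = summaries["label"]
            if not feats or df["label"].nunique() < 2:
                info[metric] = {"n_features": len(feats), "skipped": True}
                continue
            graphs = fus.subsample_iterations(
                df,
                "label",
                model,
                runs=self.cfg.fusion.runs,
                frac=self.cfg.fusion.frac,
                seed=self.cfg.seed * 13 + agg.METRICS.index(metric),
            )
            for it, g in enumerate(graphs):
                pd.DataFrame(list(g.edge_records())).to_csv(
                    gdir / f"{metric}_iter{it:02d}.tsv", sep="\t", index=False
                )
            info[metric] = {"n_features": len(feats), "runs": len(graphs)}
        marker.write_text(json.dumps(info, indent=1))
        self._record("discover", [marker], self.cfg.seed, t0)
        return gdir

    def _load_iteration_graphs(self, metric: str) -> list[Cpdag]:
        gdir = self.out / "graphs"
        out = []
        for p in sorted(gdir.glob(f"{metric}_iter*.tsv")):
            df = pd.read_csv(p, sep="\t")
            g = Cpdag(["label"])
            for _, row in df.iterrows():
                g.add_node(row["source"])
                g.add_node(row["target"])
                if row["kind"] == "directed":
                    g.add_directed(row["source"], row["target"])
                else:
                    g.add_undirected(row["source"], row["target"])
            out.append(g)
        return out

    def fuse(self, force: bool = False) -> Path:
        path = self.out / "final_graph.tsv"
        feat_path = self.out / "causal_features.csv"
        if self._done("fuse", [path, feat_path]) and not force:
            return path
        self.discover()
        t0 = time.time()
        ensembles = {}
        for metric in agg.METRICS:
            graphs = self._load_iteration_graphs(metric)
            if not graphs:
                continue
            pruned = [fus.prune_to_target(g, "label") for g in graphs]
            ens = fus.majority_merge(
                pruned, "label", threshold=self.cfg.fusion.threshold, metric=metric
            )
            ens.edge_counts.to_csv(
                self.out / "graphs" / f"{metric}_consensus_counts.tsv",
                sep="\t",
                index=False,
            )
            pd.DataFrame(list(ens.consensus.edge_records())).to_csv(
                self.out / "graphs" / f"{metric}_consensus.tsv", sep="\t", index=False
            )
            ensembles[metric] = ens
        final = fus.fuse_across_metrics(ensembles, "label")
        final.edges.to_csv(path, sep="\t", index=False)
        final.features_frame().to_csv(feat_path, index=False)
        self._record(
            "fuse",
            [path, feat_path],
            None,
            t0,
            {
                "n_consensus_subgraphs": len(ensembles),
                "n_final_graphs": 1,
                "n_causal_features": len(final.causal_features),
                "n_collapsed_nodes": len(final.collapsed_nodes),
            },
        )
        return path

    def classify(self, force: bool = False) -> Path:
        path = self.out / "classification_report.csv"
        curves = self.out / "curves.json"
        if self._done("classify", [path, curves]) and not force:
            return path
        self.fuse()
        summaries = pd.read_csv(self.aggregate(), index_col="subject_id")
        t0 = time.time()
        features = pd.read_csv(self.out / "causal_features.csv")
        causal_cols = [
            q for q in features.get("qualified", pd.Series(dtype=str))
            if q in summaries.columns and summaries[q].notna().all()
        ]
        labels = summaries["label"]
        rows, curve_store = [], {}
        if causal_cols:
            X = summaries.drop(columns=["label", "n_valid_beats"])
            X = X.loc[:, X.notna().all()]
            corr_cols = clf.select_correlated(X, labels, k=len(causal_cols))
            for name, cols in (("causal", causal_cols), ("correlation", corr_cols)):
                for algo in self.cfg.evaluation.algorithms:
                    rep = clf.crossval_classify(
                        summaries[cols],
                        labels,
                        algo,
                        folds=self.cfg.evaluation.folds,
                        seed=self.cfg.seed,
                        feature_set=name,
                    )
                    rows.append(rep.row())
                    curve_store[f"{name}/{algo}"] = {
                        "roc_fpr": rep.roc_curve[0].tolist(),
                        "roc_tpr": rep.roc_curve[1].tolist(),
                        "pr_recall": rep.pr_curve[0].tolist(),
                        "pr_precision": rep.pr_curve[1].tolist(),
                    }
        pd.DataFrame(
            rows,
            columns=["algorithm", "feature_set", "accuracy", "precision", "recall", "f1", "auc"],
        ).to_csv(path, index=False)
        curves.write_text(json.dumps(curve_store))
        self._record("classify", [path, curves], self.cfg.seed, t0)
        return path

    def report(self, force: bool = False) -> Path:
        path = self.out / "summary.json"
        if self._done("report", [path]) and not force:
            return path
        self.classify()
        t0 = time.time()
        features = pd.read_csv(self.out / "causal_features.csv")
        perf = pd.read_csv(self.out / "classification_report.csv")
        summary = {
            "causal_features": features.to_dict(orient="records"),
            "performance": perf.to_dict(orient="records"),
            "stages": {k: v.get("runtime_s") for k, v in self.manifest["stages"].items()},
        }
        path.write_text(json.dumps(summary, indent=1))
        self._record("report", [path], None, t0)
        return path

    def run_all(self, force: bool = False) -> dict:
        self.simulate(force)
        self.extract(force)
        self.aggregate(force)
        self.screen(force)
        self.discover(force)
        self.fuse(force)
        self.classify(force)
        self.report(force)
        return self.manifest


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run every stage; returns the manifest (stage -> outputs/seeds/hashes)."""
    return Pipeline(config).run_all(force=force)
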
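"""End-to-end orchestration: embed -> reduce -> (tune) -> cluster -> label -> evaluate.

A single JSON-style config drives the whole run; every randomized stage gets
a sub-seed derived deterministically from the master seed and the stage name,
so a config fully determines every artifact.  Ground-truth labels are touched
only by the labeling and evaluation stages (and by the tuning cost for the
fixed-k branch, which scores candidate clusterings through those stages).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import clustering as clus
from . import evaluation as ev
from . import labeling as lab
from . import reduction as red
from . import tuning
from .embedding import EmbeddingMatrix, extract_embeddings
from .synthdata import FrameSet, generate_frame_set


@dataclass
class PipelineConfig:
    """One input source (synthetic | image_folder | embedding_file) plus stage params."""

    seed: int
    out_dir: str
    synthetic: dict | None = None       # {"n_per_class": int, "size": int}
    image_folder: str | None = None
    embedding_file: str | None = None
    backend: str = "pixel-downsample"
    reduction: dict = field(default_factory=lambda: {"method": "umap"})
    clustering: dict = field(default_factory=lambda: {"method": "agglomerative",
                                                      "n_clusters": 4})
    tuning: dict | None = None          # {"dims": ..., "budget": int, "strategy": "bo"}
    evaluate: bool = True

    def __post_init__(self):
        sources = [self.synthetic, self.image_folder, self.embedding_file]
        if sum(s is not None for s in sources) != 1:
            raise ValueError("exactly one input source must be set")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def stage_seed(master: int, stage: str) -> int:
    """Deterministic sub-seed per stage, below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the configured pipeline, writing every intermediate artifact.

    Returns the run report (also written to ``report.json``): config echo,
    per-stage provenance, the label mapping, classification metrics and
    validity indices when ground truth is available.
    """
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": _jsonable(asdict(config)), "stages": {}, "files": {}}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3),
                                  "seed": stage_seed(config.seed, name)}
        return result

    # --- input / embedding ---------------------------------------------
    truth = None
    if config.embedding_file is not None:
        X = _stage("load", lambda: EmbeddingMatrix.load(config.embedding_file))
    else:
        if config.synthetic is not None:
            frames = _stage("synth", lambda: generate_frame_set(
                seed=stage_seed(config.seed, "synth"), **config.synthetic))
        else:
            frames = _stage("load", lambda: FrameSet.load(config.image_folder))
        truth = frames.labels
        X = _stage("embed", lambda: extract_embeddings(
            frames, backend=config.backend, seed=stage_seed(config.seed, "embed")))
        X.save(out / "embeddings.tsv")
        report["files"]["embeddings"] = "embeddings.tsv"
        report["stages"]["embed"]["shape"] = list(X.shape)
        report["stages"]["embed"]["backend_tag"] = X.backend_tag

    # --- reduction ------------------------------------------------------
    rparams = dict(config.reduction)
    rmethod = rparams.pop("method", "umap")
    Y = _stage("reduce", lambda: red.reduce(
        X, method=rmethod, params=rparams, seed=stage_seed(config.seed, "reduce")))
    np.savetxt(out / "projection.tsv", Y.values, delimiter="\t",
               header=f"{rmethod} {json.dumps(_jsonable(Y.params))}")
    report["files"]["projection"] = "projection.tsv"
    report["stages"]["reduce"]["params"] = _jsonable(Y.params)

    # --- optional hyperparameter tuning --------------------------------
    cparams = dict(config.clustering)
    cmethod = cparams.pop("method", "agglomerative")
    if config.tuning is not None:
        tcfg = dict(config.tuning)
        dims = tcfg.pop("dims", None) or clus.default_search_space(cmethod, Y)
        space = tuning.SearchSpace(cmethod, dims, budget=tcfg.get("budget", 200),
                                   seed=stage_seed(config.seed, "tune"))
        strategy = tcfg.get("strategy", "bo")

        def _evaluate_point(point: dict) -> float:
            params = {**cparams, **point}
            result = clus.cluster(Y, cmethod, params, seed=stage_seed(config.seed, "tune-eval"))
            if cmethod == "dbscan":
                n_target = (len(Y.values) + 3) // 4
                try:
                    return tuning.cost_dbscan(result, n_target=n_target)
                except ValueError:  # everything labeled noise
                    return float(len(Y.values)) + tuning.DEFAULT_ALPHA * tuning.DEFAULT_K
            if truth is None:
                raise ValueError("tuning the fixed-k branch requires ground-truth labels")
            table = lab.contingency(result, truth)
            if table.counts.shape[0] != table.counts.shape[1]:
                return 1.0 + tuning.cost_partition(0.0, 0.0)
            mapping = lab.greedy_label_map(table)
            metrics = ev.classification_metrics(mapping.apply(result.labels), truth)
            s_rec = float(np.mean(list(metrics.recall.values())))
            s_pre = float(np.mean(list(metrics.precision.values())))
            return tuning.cost_partition(s_rec, s_pre)

        tres = _stage("tune", lambda: tuning.search(space, _evaluate_point, strategy))
        cparams.update(tres.best_params)
        report["stages"]["tune"]["best_params"] = _jsonable(tres.best_params)
        report["stages"]["tune"]["best_cost"] = tres.best_cost
        report["stages"]["tune"]["trace_length"] = len(tres.trace)
        with open(out / "tuning_trace.json", "w") as fh:
            json.dump(_jsonable([{"params": p, "cost": c} for p, c in tres.trace]), fh)
        report["files"]["tuning_trace"] = "tuning_trace.json"

    # --- clustering -----------------------------------------------------
    result = _stage("cluster", lambda: clus.cluster(
        Y, cmethod, cparams, seed=stage_seed(config.seed, "cluster")))
    with open(out / "labels.csv", "w") as fh:
        for fid, c in zip(Y.frame_ids, result.labels):
            fh.write(f"{fid},{c}\n")
    report["files"]["cluster_labels"] = "labels.csv"
    report["stages"]["cluster"]["k_found"] = result.k_found
    report["stages"]["cluster"]["n_noise"] = result.n_noise
    report["stages"]["cluster"]["params"] = _jsonable(cparams)

    # --- labeling + evaluation -----------------------------------------
    if truth is not None and config.evaluate:
        mapping = _stage("label", lambda: lab.greedy_label_map(lab.contingency(result, truth)))
        with open(out / "mapping.json", "w") as fh:
            json.dump({"map": {str(k): v for k, v in mapping.map.items()},
                       "total_intersection": mapping.total_intersection,
                       "mode": mapping.mode}, fh)
        report["files"]["mapping"] = "mapping.json"
        report["mapping"] = {"map": {str(k): v for k, v in mapping.map.items()},
                             "mode": mapping.mode,
                             "total_intersection": mapping.total_intersection}

        def _evaluate():
            mapped = mapping.apply(result.labels)
            scores = ev.centroid_distance_scores(Y, result.labels, mapping,
                                                 ev._category_order(truth))
            metrics = ev.classification_metrics(mapped, truth, scores=scores)
            validity = {"silhouette": ev.silhouette(Y, result.labels)
                        if result.k_found >= 2 else None}
            chosen_k, ch = ev.determine_cluster_number(
                Y, seed=stage_seed(config.seed, "validity"))
            validity["ch_by_k"] = ch
            validity["chosen_k"] = chosen_k
            return metrics, validity

        metrics, validity = _stage("evaluate", _evaluate)
        report["metrics"] = _jsonable(metrics.as_dict())
        report["validity"] = _jsonable(validity)
        with open(out / "metrics.json", "w") as fh:
            json.dump(report["metrics"], fh, indent=1, sort_keys=True)
        report["files"]["metrics"] = "metrics.json"

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    report["files"]["report"] = "report.json"
    return report
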
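"""End-to-end orchestration: files in, clusters + CV results out.

One :class:`RunConfig` drives the whole chain: read catalog -> rarity
filter -> spectrum windowing/normalization -> descriptor dissimilarity
(embedding cosine or catalog correlation) -> UPGMA -> K-cut -> OR-rule
labels -> cross-validated training/evaluation -> CSV/JSON outputs.  Every
random draw traces back to the config seed.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .catalog import filter_rare_descriptors, read_catalog
from .clustering import build_cluster_labels, cut_to_k, upgma, write_assignment_csv
from .evaluation import PredictorConfig, crossvalidate, make_folds
from .neuralnet import TrainingConfig
from .semantics import (
    correlation_dissimilarity,
    cosine_dissimilarity,
    mds_embed,
    read_word_vectors,
)
from .spectra import build_spectrum_matrix, read_spectra

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    catalog_path: str
    spectra_path: str
    outdir: str
    embeddings_path: str | None = None
    spectra_format: str = "msp"
    mz_lo: int = 51
    mz_hi: int = 262
    min_count: int = 4
    method: str = "word2vec"  # or "correlation"
    k_values: list[int] = field(default_factory=lambda: [20])
    folds: int = 5
    seed: int = 0
    predictor: PredictorConfig = field(default_factory=PredictorConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pred_raw = raw.pop("predictor", {})
        stages = {
            name: TrainingConfig(**pred_raw.pop(name))
            for name in ("autoencoder", "mapper", "finetune")
            if name in pred_raw
        }
        predictor = PredictorConfig(**pred_raw, **stages)
        return cls(**raw, predictor=predictor)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write result files + manifest.

    Outputs in ``cfg.outdir``: clusters_K<k>.csv, dendrogram.nwk, mds.csv,
    results.csv (fold-level and pooled rates per K and method), and
    manifest.json recording every hyperparameter actually used, including
    the derived epoch-0 learning rates.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    cat = _stage("read_catalog")(read_catalog)(cfg.catalog_path)
    cat, removed = _stage("filter")(filter_rare_descriptors)(cat, cfg.min_count)

    raw = _stage("read_spectra")(read_spectra)(cfg.spectra_path, format=cfg.spectra_format)
    raw_by_id = {sp.chemical_id: sp for sp in raw}
    missing = [c for c in cat.chemical_ids if c not in raw_by_id]
    if missing:
        raise PipelineError(f"stage 'align' failed: no spectrum for {missing[:5]}...")
    ordered = [raw_by_id[c] for c in cat.chemical_ids]
    sm = _stage("spectrum_matrix")(build_spectrum_matrix)(ordered, cfg.mz_lo, cfg.mz_hi)

    if cfg.method == "word2vec":
        if cfg.embeddings_path is None:
            raise PipelineError("stage 'dissimilarity' failed: word2vec method needs embeddings_path")
        emb = _stage("embeddings")(read_word_vectors)(cfg.embeddings_path)
        dm = _stage("dissimilarity")(cosine_dissimilarity)(cat.descriptor_names, emb)
    elif cfg.method == "correlation":
        dm = _stage("dissimilarity")(correlation_dissimilarity)(cat)
    else:
        raise PipelineError(f"stage 'dissimilarity' failed: unknown method {cfg.method!r}")

    coords = mds_embed(dm, 2)
    with open(out / "mds.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["descriptor", "x", "y"])
        for label, (x, y) in zip(dm.labels, coords):
            w.writerow([label, f"{x:.6g}", f"{y:.6g}"])

    dend = _stage("upgma")(upgma)(dm)
    (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")

    folds = make_folds(cat.n_chemicals, cfg.folds, cfg.seed)
    rows = []
    for K in cfg.k_values:
        asg = _stage("cut")(cut_to_k)(dend, K)
        write_assignment_csv(asg, out / f"clusters_K{K}.csv")
        labels = _stage("labels")(build_cluster_labels)(cat, asg)
        result = _stage("crossvalidate")(crossvalidate)(
            labels.matrix, sm, cfg.predictor, folds
        )
        for f, (r, th) in enumerate(zip(result.per_fold, result.thresholds)):
            rows.append([f, cfg.method, K, f"{r.tp_rate:.2f}", f"{r.tn_rate:.2f}",
                         f"{th:.2f}", cfg.seed])
        rows.append(["pooled", cfg.method, K,
                     f"{result.pooled.tp_rate:.2f}", f"{result.pooled.tn_rate:.2f}",
                     "", cfg.seed])
        logger.info("K=%d (%s): pooled TP %.1f%% TN %.1f%%", K, cfg.method,
                    result.pooled.tp_rate, result.pooled.tn_rate)

    with open(out / "results.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fold", "method", "K", "tp_rate", "tn_rate", "threshold", "seed"])
        w.writerows(rows)

    manifest = {
        "odorlex_version": __version__,
        "config": _as_jsonable(cfg),
        "removed_rare_descriptors": removed,
        "n_chemicals": cat.n_chemicals,
        "n_descriptors": cat.n_descriptors,
        "spectrum_dimensions": sm.n_dimensions,
        "fold_sizes": folds.sizes().tolist(),
        "epoch0_rates": {
            stage: {"eta": tc.eta0, "alpha": tc.alpha0}
            for stage, tc in (
                ("autoencoder", cfg.predictor.autoencoder),
                ("mapper", cfg.predictor.mapper),
                ("finetune", cfg.predictor.finetune),
            )
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
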
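"""End-to-end pipeline: intersect -> sample-null -> featurize -> train -> evaluate.

A run is described by a flat YAML config (:class:`RunConfig`); every run
writes its artifacts plus a manifest recording the configuration, the root
seed, input checksums and the package version, sufficient to reproduce all
numeric outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .features import assemble_features
from .genome import Genome
from .intervals import IntervalSet, intersect_replicates, read_bed, write_bed
from .models import (
    LabeledDataset,
    assemble_dataset,
    train_forest,
    train_lasso,
)
from .motifs import parse_jaspar
from .nullsampler import MatchingConfig, sample_matched_negatives
from .shape import load_shape_table

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, model choices and sampler tolerances for one pipeline run."""

    genome_fasta: str
    dsb_bed: str
    dsb_bed_replicate2: str | None = None
    track_beds: dict[str, str] = field(default_factory=dict)
    motif_file: str | None = None
    shape_table: str | None = None
    min_rel_score: float = 0.8
    model: str = "forest"  # forest | lasso
    n_trees: int = 500
    n_folds: int = 10
    gc_tolerance: float = 0.02
    repeat_tolerance: float = 0.05
    negative_ratio: float = 1.0
    test_fraction: float = 0.3
    n_boot: int = 2000
    seed: int = 0
    outdir: str = "dsbpred_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the three-step prediction pipeline; returns the run directory.

    Stages: replicate intersection (when a second replicate is given),
    matched-null sampling, featurization of both classes, model training,
    ROC/PR evaluation. Any stage failure propagates with the stage name.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        genome = Genome.from_fasta(cfg.genome_fasta)
        dsb = read_bed(cfg.dsb_bed, genome)
        if cfg.dsb_bed_replicate2:
            stage = "intersect"
            rep2 = read_bed(cfg.dsb_bed_replicate2, genome)
            dsb = intersect_replicates(dsb, rep2)
        tracks = {
            name: read_bed(path, genome) for name, path in cfg.track_beds.items()
        }
        motif_models = parse_jaspar(cfg.motif_file) if cfg.motif_file else None
        shape = load_shape_table(cfg.shape_table) if cfg.shape_table else None

        stage = "sample-null"
        seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31 - 1)
        negatives = sample_matched_negatives(
            dsb,
            genome,
            MatchingConfig(
                gc_tolerance=cfg.gc_tolerance,
                repeat_tolerance=cfg.repeat_tolerance,
                ratio=cfg.negative_ratio,
                seed=int(seeds[0]),
            ),
        )
        write_bed(negatives, out / "negatives.bed")

        stage = "featurize"
        kwargs = dict(
            genome=genome,
            tracks=tracks or None,
            motif_models=motif_models,
            min_rel_score=cfg.min_rel_score,
            shape_table=shape,
        )
        pos_feats = assemble_features(dsb, **kwargs)
        neg_feats = assemble_features(negatives, **kwargs)
        pos_feats.to_csv(out / "features_pos.tsv", sep="\t")
        neg_feats.to_csv(out / "features_neg.tsv", sep="\t")

        stage = "train"
        data = assemble_dataset(
            pos_feats, neg_feats, test_fraction=cfg.test_fraction, seed=int(seeds[1])
        )
        if cfg.model == "forest":
            results = train_forest(data, seed=int(seeds[2]), n_trees=cfg.n_trees)
        elif cfg.model == "lasso":
            results = train_lasso(data, n_folds=cfg.n_folds, seed=int(seeds[2]))
        else:
            raise ValueError(f"unknown model family {cfg.model!r}")
        results.params_table().to_csv(out / "model_params.tsv", sep="\t")
        import pickle

        with open(out / "model.pkl", "wb") as fh:
            pickle.dump(results, fh)

        stage = "evaluate"
        ev = results.evaluate(data, n_boot=cfg.n_boot, seed=int(seeds[3]))
        ev.roc_points.to_csv(out / "roc.tsv", sep="\t", index=False)
        ev.pr_points.to_csv(out / "pr.tsv", sep="\t", index=False)
        (out / "eval.json").write_text(
            json.dumps(
                {
                    "auroc": ev.auroc,
                    "aupr": ev.aupr,
                    "auroc_ci": list(ev.auroc_ci),
                    "n_boot": ev.n_boot,
                },
                indent=2,
            )
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    inputs = [cfg.genome_fasta, cfg.dsb_bed] + list(cfg.track_beds.values())
    if cfg.dsb_bed_replicate2:
        inputs.append(cfg.dsb_bed_replicate2)
    if cfg.motif_file:
        inputs.append(cfg.motif_file)
    if cfg.shape_table:
        inputs.append(cfg.shape_table)
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "stage_seeds": [int(s) for s in seeds],
        "input_checksums": {p: _checksum(p) for p in inputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
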
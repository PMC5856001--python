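"""Genome-wide prediction in fixed-width bins and transfer prediction.

The whole genome is tiled into 250-base bins (default), every bin is
featurized with exactly the training-time encoders, and the fitted model
scores each bin. High-scoring bins are called predicted DSBs, low-scoring
bins predicted controls, and independent signals can be profiled across
score quantiles to validate the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import assemble_features
from .genome import Genome
from .intervals import GenomicInterval, IntervalSet, bin_genome
from .models import DSBResults
from .motifs import MotifModel
from .shape import ShapeTable

__all__ = [
    "BinScoreTrack",
    "score_genome",
    "call_high_low",
    "signal_by_score",
    "transfer_predict",
]


@dataclass
class BinScoreTrack:
    """Scores of fixed-width genome bins from one model."""

    bins: IntervalSet
    scores: np.ndarray
    model_id: str = "model"
    thresholds: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.bins):
            raise ValueError("one score per bin required")
        low, high = self.thresholds
        if not (0 <= low < high <= 1):
            raise ValueError("thresholds must satisfy 0 <= low < high <= 1")

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for iv, s in zip(self.bins, self.scores):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s:.6g}\n")


def score_genome(
    results: DSBResults,
    genome: Genome,
    tracks: dict[str, IntervalSet] | None = None,
    motif_models: list[MotifModel] | None = None,
    shape_table: ShapeTable | None = None,
    min_rel_score: float = 0.8,
    width: int = 250,
    thresholds: tuple[float, float] = (0.25, 0.75),
) -> BinScoreTrack:
    """Featurize and score every ``width``-base bin of the genome.

    Bins are encoded with the same featurizers as training (occupancy
    fraction, motif counts, shape summaries). Every feature the model was
    trained on must be computable from the supplied inputs; a missing track
    raises rather than silently zero-filling.
    """
    bins = bin_genome(genome, width)
    needed = set(results.feature_names)
    supplied = set(tracks or {})
    track_like = {n for n in needed if not n.startswith("motif_") and "_q" not in n and not n.endswith("_var")}
    missing_tracks = track_like - supplied
    if missing_tracks:
        raise ValueError(
            f"model requires tracks not supplied: {sorted(missing_tracks)}"
        )
    feats = assemble_features(
        bins,
        genome=genome,
        tracks={n: t for n, t in (tracks or {}).items()},
        motif_models=motif_models,
        min_rel_score=min_rel_score,
        shape_table=shape_table,
    )
    missing = needed - set(feats.columns)
    if missing:
        raise ValueError(f"features unavailable for this genome: {sorted(missing)}")
    scores = results.predict_proba(feats)
    return BinScoreTrack(bins, scores, model_id=results.family, thresholds=thresholds)


def call_high_low(track: BinScoreTrack) -> tuple[IntervalSet, IntervalSet]:
    """Split bins into (predicted DSBs, predicted controls) by score.

    Bins with score >= high threshold are predicted DSBs, score <= low are
    predicted controls; the middle band is left unassigned (mirroring a
    two-class presentation that excludes uncertain bins).
    """
    low, high = track.thresholds
    dsb = [iv for iv, s in zip(track.bins, track.scores) if s >= high]
    ctrl = [iv for iv, s in zip(track.bins, track.scores) if s <= low]
    return IntervalSet(dsb), IntervalSet(ctrl)


def signal_by_score(
    track: BinScoreTrack, signal: IntervalSet, n_quantiles: int = 10
) -> pd.DataFrame:
    """Mean signal coverage per score-quantile group of bins.

    Bins are ranked by score and cut into ``n_quantiles`` groups of (near)
    equal size; for each group the mean per-base coverage of ``signal`` over
    its bins is reported. Supports monotonicity checks: break/repair signals
    should increase with the score, locally depleted marks should decrease.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    order = np.argsort(track.scores, kind="stable")
    groups = np.array_split(order, n_quantiles)
    rows = []
    for q, idx in enumerate(groups):
        cov = 0.0
        bases = 0
        for i in idx:
            iv = track.bins[int(i)]
            cov += signal.covered_bases(iv.chrom, iv.start, iv.end)
            bases += iv.length
        rows.append(
            {
                "quantile": q + 1,
                "mean_score": float(track.scores[idx].mean()) if len(idx) else np.nan,
                "mean_signal": cov / bases if bases else np.nan,
                "n_bins": len(idx),
            }
        )
    return pd.DataFrame(rows)


def transfer_predict(results: DSBResults, features: pd.DataFrame) -> np.ndarray:
    """Score another dataset (e.g. another cell type) with a fitted model.

    The feature frame must contain every training feature (extra columns are
    ignored; order is irrelevant). Missing features raise with their names —
    the feature intersection must be chosen explicitly upstream, never
    imputed here.
    """
    missing = [c for c in results.feature_names if c not in features.columns]
    if missing:
        raise ValueError(
            f"training features unavailable in transfer data: {missing}; "
            "train on the explicit feature intersection instead"
        )
    return results.predict_proba(features[results.feature_names])
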
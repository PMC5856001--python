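"""Feature-matrix assembly.

The in-memory feature matrix is a pandas DataFrame: rows are sites (indexed
by site id), columns are named predictors — epigenomic occupancy fractions
in [0, 1], motif occurrence counts, and DNA-shape summary statistics. All
blocks computed for the same site set can be concatenated column-wise; the
assembled matrix must be free of missing values.
"""

from __future__ import annotations

import pandas as pd

from .genome import Genome
from .intervals import IntervalSet, overlap_fraction
from .motifs import MotifModel, count_occurrences
from .shape import ShapeTable, shape_feature_block

__all__ = ["site_ids", "occupancy_features", "assemble_features"]


def site_ids(sites: IntervalSet) -> list[str]:
    """Stable row identifiers: the interval's name, else ``chrom:start-end``."""
    return [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in sites]


def occupancy_features(
    sites: IntervalSet, tracks: dict[str, IntervalSet]
) -> pd.DataFrame:
    """Occupancy fraction x in [0, 1] of each track's peaks over each site.

    One column per track, named after the mark (e.g. ``DNase``, ``CTCF``);
    entry = fraction of the site's bases covered by the union of that mark's
    peaks.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    data = {
        name: [overlap_fraction(iv, track) for iv in sites]
        for name, track in tracks.items()
    }
    return pd.DataFrame(data, index=site_ids(sites))


def assemble_features(
    sites: IntervalSet,
    genome: Genome | None = None,
    tracks: dict[str, IntervalSet] | None = None,
    motif_models: list[MotifModel] | None = None,
    min_rel_score: float = 0.8,
    shape_table: ShapeTable | None = None,
) -> pd.DataFrame:
    """Concatenate the requested feature blocks for one site set.

    Any combination of occupancy, motif-count and shape blocks may be
    requested; sequence-based blocks require a sequence-bearing genome.
    Raises if the assembled matrix contains missing values or duplicate
    feature names.
    """
    blocks: list[pd.DataFrame] = []
    if tracks:
        blocks.append(occupancy_features(sites, tracks))
    if motif_models:
        if genome is None or not genome.has_sequence:
            raise ValueError("motif features require a sequence-bearing genome")
        blocks.append(count_occurrences(sites, genome, motif_models, min_rel_score))
    if shape_table is not None:
        if genome is None or not genome.has_sequence:
            raise ValueError("shape features require a sequence-bearing genome")
        blocks.append(shape_feature_block(sites, genome, shape_table))
    if not blocks:
        raise ValueError("no feature blocks requested")
    out = pd.concat(blocks, axis=1)
    if out.columns.duplicated().any():
        dups = out.columns[out.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dups}")
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values in assembled features: {bad}")
    return out
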
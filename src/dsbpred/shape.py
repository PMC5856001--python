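"""Sequence-derived DNA shape features via a pentamer lookup table.

Four structural features are assigned to each position of a sequence from
the pentamer centered on it: minor groove width (MGW, Å) and propeller twist
(ProT, degrees) at base-pair resolution, and roll (Roll) and helix twist
(HelT, degrees) at base-pair-step resolution. Step features are flattened to
one value per position by averaging the two central steps of the pentamer,
giving all four profiles uniform length L - 4.

Each site is then summarised by 12 statistics per feature — the 11 quantiles
at 0, 10, ..., 100% plus the variance — for 48 named predictors in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import IntervalSet
from .motifs import revcomp

__all__ = [
    "SHAPE_FEATURES",
    "ShapeTable",
    "ShapeProfile",
    "load_shape_table",
    "predict_shape",
    "summarize_shape",
    "shape_feature_names",
    "shape_feature_block",
]

SHAPE_FEATURES = ("MGW", "ProT", "Roll", "HelT")
_QUANTILES = tuple(range(0, 101, 10))
_SYMMETRY_TOL = 1e-6


class ShapeTable:
    """Pentamer -> (MGW, ProT, Roll, HelT) lookup.

    The table must cover all 4^5 = 1024 pentamers, either directly or after
    reverse-complement completion: a missing pentamer inherits the values of
    its reverse complement. Strand symmetry requires value(p) == value(rc(p))
    for MGW and ProT; tables violating it beyond 1e-6 are rejected.
    """

    def __init__(self, entries: dict[str, np.ndarray]):
        completed: dict[str, np.ndarray] = {
            k.upper(): np.asarray(v, dtype=float) for k, v in entries.items()
        }
        for pent in list(completed):
            rc = revcomp(pent)
            if rc not in completed:
                completed[rc] = completed[pent].copy()
        missing = [
            "".join(p)
            for p in itertools.product("ACGT", repeat=5)
            if "".join(p) not in completed
        ]
        if missing:
            raise ValueError(
                f"shape table incomplete after reverse-complement completion; "
                f"{len(missing)} pentamers missing (first: {missing[:5]})"
            )
        for pent, vals in completed.items():
            rc_vals = completed[revcomp(pent)]
            for fi in (0, 1):  # MGW, ProT are base-pair features
                if abs(vals[fi] - rc_vals[fi]) > _SYMMETRY_TOL:
                    raise ValueError(
                        f"shape table violates strand symmetry at {pent} "
                        f"({SHAPE_FEATURES[fi]}: {vals[fi]} vs {rc_vals[fi]})"
                    )
        self.entries = completed

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, pentamer: str) -> np.ndarray:
        return self.entries[pentamer.upper()]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pentamer\t" + "\t".join(SHAPE_FEATURES) + "\n")
            for pent in sorted(self.entries):
                vals = "\t".join(f"{v:.4f}" for v in self.entries[pent])
                fh.write(f"{pent}\t{vals}\n")


def load_shape_table(path: str | Path) -> ShapeTable:
    """Load a pentamer shape table from TSV (pentamer + 4 numeric columns)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if len(cols) < 5:
        raise ValueError(f"{path}: expected pentamer + 4 value columns, got {cols}")
    entries = {}
    for row in df.itertuples(index=False):
        pent = str(row[0]).upper()
        if len(pent) != 5 or set(pent) - set("ACGT"):
            raise ValueError(f"{path}: invalid pentamer {pent!r}")
        entries[pent] = np.asarray(row[1:5], dtype=float)
    return ShapeTable(entries)


@dataclass
class ShapeProfile:
    """Per-position shape values of one sequence; NaN marks N-containing pentamers."""

    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray
    site_id: str = "."

    def feature(self, name: str) -> np.ndarray:
        return {"MGW": self.mgw, "ProT": self.prot, "Roll": self.roll, "HelT": self.helt}[name]


def predict_shape(seq: str, table: ShapeTable, site_id: str = ".") -> ShapeProfile:
    """Shape profile of ``seq``: position i (2 <= i <= L-3) reads seq[i-2 .. i+2].

    Pentamers containing N (or other ambiguity codes) yield NaN at that
    position. Requires L >= 5.
    """
    L = len(seq)
    if L < 5:
        raise ValueError(f"sequence too short for pentamer lookup (L={L} < 5)")
    up = seq.upper()
    n = L - 4
    vals = np.full((n, 4), np.nan)
    for i in range(n):
        pent = up[i : i + 5]
        if not set(pent) - set("ACGT"):
            vals[i] = table.lookup(pent)
    return ShapeProfile(vals[:, 0], vals[:, 1], vals[:, 2], vals[:, 3], site_id)


def shape_feature_names() -> list[str]:
    """The 48 predictor names: <feature>_q<p> for 11 quantiles plus <feature>_var."""
    names = []
    for feat in SHAPE_FEATURES:
        names.extend(f"{feat}_q{q}" for q in _QUANTILES)
        names.append(f"{feat}_var")
    return names


def summarize_shape(profile: ShapeProfile) -> pd.Series:
    """48 summary statistics of a shape profile.

    Per feature: quantiles at 0, 10, ..., 100% (linear interpolation between
    order statistics) and the population (divide-by-n) variance, computed
    over non-missing positions.
    """
    out: dict[str, float] = {}
    for feat in SHAPE_FEATURES:
        v = profile.feature(feat)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(
                f"no non-missing {feat} values for site {profile.site_id}"
            )
        qs = np.quantile(v, np.asarray(_QUANTILES) / 100.0)  # linear interpolation
        for q, val in zip(_QUANTILES, qs):
            out[f"{feat}_q{q}"] = float(val)
        out[f"{feat}_var"] = float(np.var(v))  # population variance
    return pd.Series(out, index=shape_feature_names())


def shape_feature_block(
    sites: IntervalSet, genome: Genome, table: ShapeTable
) -> pd.DataFrame:
    """48-column shape summary matrix, rows aligned with ``sites``."""
    rows = []
    index = []
    for iv in sites:
        sid = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        seq = genome.fetch(iv.chrom, iv.start, iv.end)
        rows.append(summarize_shape(predict_shape(seq, table, site_id=sid)))
        index.append(sid)
    return pd.DataFrame(rows, index=index)
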
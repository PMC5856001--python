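"""JASPAR motif models and PWM scanning at a relative-score threshold.

A motif's position frequency matrix (PFM) is converted to a log-odds weight
matrix with a pseudocount, and every window on both strands whose score is at
least ``min_rel_score`` of the attainable range is a hit:

    rel_score = (score - min_score) / (max_score - min_score)

so the consensus scores exactly 1 and the anti-consensus exactly 0. An "80%
matching score" is rel_score >= 0.8 — the Biostrings/TFBS convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .genome import Genome
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "MotifModel",
    "MotifHit",
    "parse_jaspar",
    "scan_motif",
    "count_occurrences",
    "revcomp",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, case preserved, N-safe."""
    return seq.translate(_COMP)[::-1]


@dataclass
class MotifModel:
    """A position frequency matrix with its log-odds transform.

    ``counts`` is a 4 x W non-negative matrix over rows A, C, G, T. The
    pseudocount (default 0.8) is distributed by the background frequencies
    before the log-odds transform, guaranteeing finite weights.
    """

    motif_id: str
    name: str
    counts: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x W")
        if self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: motif width must be >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if abs(self.background.sum() - 1) > 1e-6:
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def pwm(self) -> np.ndarray:
        """Column-normalized probability matrix (pseudocount applied)."""
        adj = self.counts + self.pseudocount * self.background[:, None]
        return adj / adj.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """4 x W log2-odds weight matrix vs the background."""
        return np.log2(self.pwm / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmax(axis=0))

    @property
    def anticonsensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmin(axis=0))

    def rel_score(self, score: float) -> float:
        span = self.max_score - self.min_score
        if span == 0:
            return 1.0
        return (score - self.min_score) / span

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(
            self.motif_id,
            self.name,
            self.counts[::-1, ::-1].copy(),
            self.pseudocount,
            self.background[::-1].copy(),
        )


@dataclass(frozen=True)
class MotifHit:
    """One PWM match: forward-strand coordinates, strand, raw and relative score."""

    interval: GenomicInterval
    strand: str
    score: float
    rel_score: float


def parse_jaspar(path: str | Path) -> list[MotifModel]:
    """Parse a JASPAR-format PFM text file (">ID NAME" + 4 bracketed rows)."""
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            models = []
            for rec in records:
                counts = np.array(
                    [rec.counts[b] for b in _BASES], dtype=float
                )
                models.append(
                    MotifModel(
                        motif_id=rec.matrix_id or rec.name or "motif",
                        name=rec.name or rec.matrix_id or "motif",
                        counts=counts,
                    )
                )
    # Bio.motifs raises on rows of unequal width / missing base rows; the
    # record id (when recoverable) is included in the re-raised message.
        except Exception as exc:
            raise ValueError(f"failed to parse JASPAR file {path}: {exc}") from exc
    if not models:
        raise ValueError(f"no motif records found in {path}")
    return models


def _encode(seq: str) -> np.ndarray:
    """Map ACGT (case-insensitive) to 0..3 and anything else to 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows; windows containing non-ACGT are flagged invalid."""
    w = lo.shape[1]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    # pad weight matrix with a zero row for ambiguous bases, track validity
    lo_pad = np.vstack([lo, np.zeros(w)])
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for k in range(w):
        col = codes[k : k + n]
        scores += lo_pad[col, k]
        valid &= col < 4
    return scores, valid


def scan_motif(
    seq: str,
    motif: MotifModel,
    min_rel_score: float = 0.8,
    offset: int = 0,
    chrom: str = ".",
) -> list[MotifHit]:
    """Scan both strands of ``seq`` for windows with rel_score >= threshold.

    Hit coordinates are forward-strand, 0-based half-open, shifted by
    ``offset`` (the genomic start of ``seq``). Windows containing N are
    skipped. A minus-strand hit at [s, s+W) means the reverse complement of
    that window matches the motif.
    """
    if not (0 < min_rel_score <= 1):
        raise ValueError("min_rel_score must lie in (0, 1]")
    w = motif.width
    if len(seq) < w:
        return []
    codes = _encode(seq)
    hits: list[MotifHit] = []
    for strand, model in (("+", motif), ("-", motif.reverse_complement())):
        scores, valid = _window_scores(codes, model.log_odds)
        # min/max attainable are strand-invariant; use the forward motif's
        rels = np.array([motif.rel_score(s) for s in scores])
        take = np.where(valid & (rels >= min_rel_score - 1e-12))[0]
        for i in take:
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, offset + int(i), offset + int(i) + w),
                    strand,
                    float(scores[i]),
                    float(min(rels[i], 1.0)),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def count_occurrences(
    sites: IntervalSet,
    genome: Genome,
    motif_models: list[MotifModel],
    min_rel_score: float = 0.8,
) -> pd.DataFrame:
    """Per-site motif occurrence counts (hits on either strand, fully inside).

    Rows follow ``sites`` order; columns are named ``motif_<name>``. Feeding
    the classifiers these raw counts mirrors the "number of motif occurrences
    within DSB and non-DSB sites" encoding.
    """
    names = [f"motif_{m.name}" for m in motif_models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names")
    out = np.zeros((len(sites), len(motif_models)), dtype=int)
    for i, iv in enumerate(sites):
        seq = genome.fetch(iv.chrom, iv.start, iv.end)
        for j, m in enumerate(motif_models):
            out[i, j] = len(scan_motif(seq, m, min_rel_score))
    index = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in sites]
    return pd.DataFrame(out, index=index, columns=names)
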
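"""Matched negative-site sampling.

Non-DSB control sites are drawn at random from the genome so that each
control matches one positive site exactly in length and lies within a stated
tolerance of that positive's GC fraction and repeat (soft-masked, lowercase)
fraction. Per-site matching is stricter than distribution-level matching and
implies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._placement import NonOverlapTracker
from .genome import Genome
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "SequenceComposition",
    "MatchingConfig",
    "composition",
    "sample_matched_negatives",
    "composition_report",
]

_VALID = set("ACGTNacgtn")


@dataclass(frozen=True)
class SequenceComposition:
    """GC fraction, soft-masked repeat fraction and length of a sequence.

    ``gc`` is computed case-insensitively over unambiguous (non-N) bases;
    ``gc_defined`` is False for all-N sequences, in which case ``gc`` is NaN.
    ``repeat`` is the lowercase fraction of all bases.
    """

    gc: float
    repeat: float
    length: int
    gc_defined: bool = True


def composition(seq: str) -> SequenceComposition:
    """Compute :class:`SequenceComposition` of a case-preserving DNA string."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    n = len(seq)
    counts = {ch: seq.count(ch) for ch in "ACGTNacgtn"}
    lower = sum(counts[ch] for ch in "acgtn")
    n_count = counts["N"] + counts["n"]
    informative = n - n_count
    if informative == 0:
        return SequenceComposition(float("nan"), lower / n, n, gc_defined=False)
    gc = (counts["G"] + counts["C"] + counts["g"] + counts["c"]) / informative
    return SequenceComposition(gc, lower / n, n)


@dataclass
class MatchingConfig:
    """Free parameters of the matched-null sampler.

    gc_tolerance / repeat_tolerance are absolute fractions; ``ratio`` is the
    number of negatives drawn per positive; candidates with > ``max_n_fraction``
    ambiguous bases are rejected outright.
    """

    gc_tolerance: float = 0.02
    repeat_tolerance: float = 0.05
    ratio: float = 1.0
    max_attempts_per_site: int = 10_000
    exclude: IntervalSet | None = None
    seed: int = 0
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.gc_tolerance < 1) or not (0 < self.repeat_tolerance < 1):
            raise ValueError("tolerances must lie in (0, 1)")
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")


class MatchingError(RuntimeError):
    pass


def sample_matched_negatives(
    positives: IntervalSet, genome: Genome, cfg: MatchingConfig
) -> IntervalSet:
    """Draw ``ceil(ratio * n_pos)`` control sites matched per-site to positives.

    Each emitted negative carries a name ``neg<k>|<j>`` recording the index
    ``j`` of the positive it is matched to, so QC can recompute per-pair
    deviations. Negatives overlap neither ``cfg.exclude`` (plus the positives
    themselves) nor each other. Fully reproducible under a fixed seed.

    Raises :class:`MatchingError` if more than 5% of requested sites cannot be
    matched within ``max_attempts_per_site``.
    """
    if len(positives) == 0:
        raise ValueError("no positive sites")
    if not genome.has_sequence:
        raise ValueError("genome must carry sequence for composition matching")

    rng = np.random.default_rng(cfg.seed)
    n_pos = len(positives)
    n_target = int(np.ceil(cfg.ratio * n_pos))

    # target positives: each negative k is matched to positive k % n_pos
    pos_comp = [
        composition(genome.fetch(iv.chrom, iv.start, iv.end)) for iv in positives
    ]

    exclude = IntervalSet(
        list(positives) + (list(cfg.exclude) if cfg.exclude is not None else [])
    )
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_p = sizes / sizes.sum()

    accepted: list[GenomicInterval] = []
    taken = NonOverlapTracker()
    unmatched: list[int] = []

    for k in range(n_target):
        j = k % n_pos
        target = pos_comp[j]
        length = target.length
        placed = False
        for _ in range(cfg.max_attempts_per_site):
            ci = int(rng.choice(len(chroms), p=chrom_p))
            chrom = chroms[ci]
            limit = genome.chrom_sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            if exclude.overlaps_any(chrom, start, end):
                continue
            if taken.overlaps(chrom, start, end):
                continue
            seq = genome.fetch(chrom, start, end)
            comp = composition(seq)
            n_frac = seq.upper().count("N") / length
            if n_frac > cfg.max_n_fraction:
                continue
            if target.gc_defined:
                if not comp.gc_defined or abs(comp.gc - target.gc) > cfg.gc_tolerance:
                    continue
            if abs(comp.repeat - target.repeat) > cfg.repeat_tolerance:
                continue
            accepted.append(GenomicInterval(chrom, start, end, name=f"neg{k}|{j}"))
            taken.add(chrom, start, end)
            placed = True
            break
        if not placed:
            unmatched.append(j)

    if unmatched:
        frac = len(unmatched) / n_target
        if frac > 0.05:
            raise MatchingError(
                f"{len(unmatched)}/{n_target} sites unmatched after "
                f"{cfg.max_attempts_per_site} attempts each; consider looser "
                "tolerances or a larger genome"
            )
    out = IntervalSet(accepted)
    out.unmatched_positive_indices = list(unmatched)  # type: ignore[attr-defined]
    return out


def matched_pairs(neg: IntervalSet) -> list[tuple[int, int]]:
    """Recover (negative index, matched positive index) pairs from names."""
    pairs = []
    for i, iv in enumerate(neg):
        if iv.name and "|" in iv.name:
            pairs.append((i, int(iv.name.rsplit("|", 1)[1])))
    return pairs


def composition_report(
    pos: IntervalSet, neg: IntervalSet, genome: Genome
) -> pd.DataFrame:
    """QC summary of the matching: per-set composition stats + max pair deviations.

    Returns a table with rows ``positives`` / ``negatives`` (mean and quartiles
    of length, GC, repeat) and a row ``max_pair_deviation`` holding the maximum
    per-matched-pair |Δlength|, |ΔGC| and |Δrepeat|.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both interval sets must be non-empty")

    def comps(ivs: IntervalSet) -> pd.DataFrame:
        rows = [composition(genome.fetch(i.chrom, i.start, i.end)) for i in ivs]
        return pd.DataFrame(
            {"length": [c.length for c in rows],
             "gc": [c.gc for c in rows],
             "repeat": [c.repeat for c in rows]}
        )

    cp, cn = comps(pos), comps(neg)

    def summary(df: pd.DataFrame, label: str) -> dict:
        out = {"set": label}
        for col in ("length", "gc", "repeat"):
            out[f"{col}_mean"] = df[col].mean()
            out[f"{col}_q25"] = df[col].quantile(0.25)
            out[f"{col}_median"] = df[col].median()
            out[f"{col}_q75"] = df[col].quantile(0.75)
        return out

    rows = [summary(cp, "positives"), summary(cn, "negatives")]
    report = pd.DataFrame(rows).set_index("set")

    pairs = matched_pairs(neg)
    if pairs:
        report.attrs["max_length_deviation"] = float(
            max(abs(cn.length[i] - cp.length[j]) for i, j in pairs)
        )
        gc_devs = [
            abs(cn.gc[i] - cp.gc[j])
            for i, j in pairs
            if np.isfinite(cn.gc[i]) and np.isfinite(cp.gc[j])
        ]
        report.attrs["max_gc_deviation"] = float(max(gc_devs)) if gc_devs else float("nan")
        report.attrs["max_repeat_deviation"] = float(
            max(abs(cn["repeat"][i] - cp["repeat"][j]) for i, j in pairs)
        )
    return report
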
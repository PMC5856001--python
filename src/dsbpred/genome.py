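"""Genome model: chromosome sizes plus an optional sequence accessor.

Sequences preserve case — lowercase bases are soft-masked repeat annotation
(the RepeatMasker convention) and carry the repeat-content information the
matched-null sampler relies on.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

__all__ = ["Genome"]


class Genome:
    """A reference genome: chromosome sizes and (optionally) sequence.

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bases. All sizes must be
        positive.
    sequences
        Optional mapping of chromosome name to its full sequence (a string
        over ``ACGTN`` and lowercase variants, case preserved). When given,
        each sequence length must equal the declared size.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        sequences: Mapping[str, str] | None = None,
    ) -> None:
        if not chrom_sizes:
            raise ValueError("genome must have at least one chromosome")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self._sequences = dict(sequences) if sequences is not None else None
        if self._sequences is not None:
            for chrom, size in self.chrom_sizes.items():
                seq = self._sequences.get(chrom)
                if seq is None:
                    raise ValueError(f"no sequence provided for chromosome {chrom!r}")
                if len(seq) != size:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared size {size} for {chrom!r}"
                    )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "Genome":
        """Build an in-memory genome from ``{chrom: sequence}``."""
        return cls({c: len(s) for c, s in sequences.items()}, sequences)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        """Load a (soft-masked) FASTA into memory, preserving case."""
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=False)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return cls.from_dict(seqs)

    # -- accessors ---------------------------------------------------------

    @property
    def has_sequence(self) -> bool:
        return self._sequences is not None

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end)`` on ``chrom``, case preserved."""
        if self._sequences is None:
            raise ValueError("genome carries no sequence data")
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= size):
            raise ValueError(
                f"region {chrom}:{start}-{end} outside chromosome bounds [0, {size})"
            )
        return self._sequences[chrom][start:end]

    def replace(self, chrom: str, start: int, replacement: str) -> None:
        """Overwrite bases starting at ``start`` (used by the motif planter)."""
        if self._sequences is None:
            raise ValueError("genome carries no sequence data")
        size = self.chrom_sizes[chrom]
        if start < 0 or start + len(replacement) > size:
            raise ValueError("replacement exceeds chromosome bounds")
        seq = self._sequences[chrom]
        self._sequences[chrom] = seq[:start] + replacement + seq[start + len(replacement):]

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        """Write sequences to FASTA, preserving soft-mask case."""
        if self._sequences is None:
            raise ValueError("genome carries no sequence data")
        with open(path, "w") as fh:
            for chrom in self.chrom_sizes:
                fh.write(f">{chrom}\n")
                seq = self._sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __repr__(self) -> str:  # pragma: no cover
        seq = "with" if self.has_sequence else "without"
        return f"Genome({len(self.chrom_sizes)} chroms, {self.total_size} bp, {seq} sequence)"
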
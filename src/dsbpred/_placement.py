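"""Internal helpers for random interval placement."""

from __future__ import annotations

import bisect

import numpy as np


class NonOverlapTracker:
    """Maintains disjoint intervals per chromosome with O(log n) overlap checks."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        ends = self._ends[chrom]
        i = bisect.bisect_left(starts, end)
        return i > 0 and ends[i - 1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def truncated_lognormal_sizes(
    rng: np.random.Generator,
    n: int,
    median: float,
    sigma_log: float,
    lo: int,
    hi: int,
) -> np.ndarray:
    """Sizes ~ lognormal(ln median, sigma_log) truncated to [lo, hi] by resampling."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.lognormal(np.log(median), sigma_log, size=2 * (n - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = np.round(ok[:take]).astype(np.int64)
        filled += take
    return out
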
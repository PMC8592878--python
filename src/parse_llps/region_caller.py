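"""Contiguous region calls from a P/D/F label track.

A region is called for label L wherever a contiguous interval of length
>= 20 carries >= 90 % L.  Qualifying intervals are made *maximal* (not
contained in any longer qualifying interval for the same label — purity is
non-monotone under extension, so maximality is computed globally rather
than greedily), and overlaps between adjacent regions of different labels
(possible because up to 10 % label mixing is allowed) are split evenly,
the odd residue going to the upstream region.  Post-split regions are not
re-filtered; their purity is recomputed for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .scales import DEFAULT_CONSTANTS, ModelConstants
from .window_classifier import WindowTrack

__all__ = [
    "LabeledRegion",
    "call_regions",
    "longest_pure_region",
    "regions_to_bed",
    "regions_to_tsv",
]

LABELS = ("P", "D", "F")


@dataclass(frozen=True)
class LabeledRegion:
    """A contiguous residue interval with its dominant label.

    ``start`` and ``end`` are 1-based inclusive residue coordinates;
    ``purity`` is the fraction of positions inside the interval that carry
    ``label`` (recomputed after overlap splitting, so values slightly
    below the calling threshold can occur in reported regions).
    """

    id: str
    start: int
    end: int
    label: str
    purity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def _labels_of(track: WindowTrack | str) -> tuple[str, str]:
    if isinstance(track, WindowTrack):
        return track.id, track.labels
    return "seq", str(track)


def _purity(prefix: np.ndarray, s: int, e: int) -> float:
    """Fraction of label positions in the 0-based inclusive interval [s, e]."""
    return (prefix[e + 1] - prefix[s]) / (e - s + 1)


def _threshold_ratio(threshold: float) -> tuple[int, int]:
    """Exact small-fraction form p/q of the purity threshold.

    Purity comparisons are done on integer counts (q*count >= p*length) so
    that boundary purities — exactly 90 % — are decided without float
    round-off.
    """
    fr = Fraction(threshold).limit_denominator(10_000)
    return fr.numerator, fr.denominator


def _maximal_intervals(
    mask: np.ndarray, min_len: int, threshold: float
) -> list[tuple[int, int]]:
    """Maximal qualifying intervals (0-based inclusive) for one label.

    Qualifying: length >= min_len and mean(mask) >= threshold.  For each
    start the longest qualifying end dominates every shorter one with the
    same start; a subsequent left-to-right scan removes intervals contained
    in a longer qualifying interval with an earlier start.
    """
    n = mask.size
    if n < min_len:
        return []
    p, q = _threshold_ratio(threshold)
    prefix = np.concatenate(([0], np.cumsum(mask, dtype=np.int64)))
    lengths_all = np.arange(1, n + 1, dtype=np.int64)
    candidates: list[tuple[int, int]] = []
    for s in range(n):
        lengths = lengths_all[: n - s]
        counts = prefix[s + 1 : n + 1] - prefix[s]
        ok = (lengths >= min_len) & (q * counts >= p * lengths)
        hits = np.nonzero(ok)[0]
        if hits.size:
            candidates.append((s, s + int(hits[-1])))
    # Containment filter: an interval is dominated iff an earlier (or equal)
    # start reaches at least as far (it is then strictly longer).
    maximal: list[tuple[int, int]] = []
    best_end = -1
    for s, e in candidates:
        if e > best_end:
            maximal.append((s, e))
            best_end = e
    return maximal


def _merge_same_label(
    intervals: list[tuple[int, int]], mask: np.ndarray, min_len: int, threshold: float
) -> list[tuple[int, int]]:
    """Merge overlapping same-label intervals whose union still qualifies,
    else keep the longer (upstream wins ties).

    After global maximality filtering a qualifying union is provably
    impossible (it would have contained both inputs), so this is a
    defensive branch kept for parity with the stated rule.
    """
    if not intervals:
        return []
    p, q = _threshold_ratio(threshold)
    prefix = np.concatenate(([0], np.cumsum(mask, dtype=np.int64)))
    out = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = out[-1]
        if s > pe:
            out.append((s, e))
            continue
        us, ue = ps, max(pe, e)
        count = int(prefix[ue + 1] - prefix[us])
        if ue - us + 1 >= min_len and q * count >= p * (ue - us + 1):
            out[-1] = (us, ue)
        elif (e - s) > (pe - ps):
            out[-1] = (s, e)
        # else: keep the previous (longer or equal, upstream) interval
    return out


def call_regions(
    track: WindowTrack | str,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> list[LabeledRegion]:
    """Call P/D/F regions from a label track.

    Accepts a :class:`WindowTrack` or a bare label string.  Returns
    regions sorted by start, non-overlapping after the even-split
    resolution of different-label overlaps (odd residue to the upstream
    region).  The empty list is a valid result.
    """
    seq_id, labels = _labels_of(track)
    arr = np.frombuffer(labels.encode(), dtype="S1")
    min_len = constants.min_region_length
    threshold = constants.purity_threshold

    raw: list[tuple[int, int, str]] = []
    masks = {}
    for label in LABELS:
        mask = (arr == label.encode()).astype(np.int64)
        masks[label] = mask
        intervals = _maximal_intervals(mask, min_len, threshold)
        intervals = _merge_same_label(intervals, mask, min_len, threshold)
        raw.extend((s, e, label) for s, e in intervals)
    raw.sort()

    # Resolve different-label overlaps pairwise left-to-right.
    resolved: list[list] = []
    for s, e, label in raw:
        if resolved and s <= resolved[-1][1]:
            ps, pe, plabel = resolved[-1]
            overlap = pe - s + 1
            left_share = (overlap + 1) // 2  # odd residue to upstream region
            new_pe = s + left_share - 1
            new_s = new_pe + 1
            resolved[-1][1] = new_pe
            if new_s <= e:
                resolved.append([new_s, e, label])
            # fully swallowed intervals are dropped
        else:
            resolved.append([s, e, label])

    regions = []
    prefixes = {
        label: np.concatenate(([0], np.cumsum(masks[label], dtype=np.int64)))
        for label in LABELS
    }
    for s, e, label in resolved:
        regions.append(
            LabeledRegion(
                id=seq_id,
                start=s + 1,
                end=e + 1,
                label=label,
                purity=float(_purity(prefixes[label], s, e)),
            )
        )
    return regions


def longest_pure_region(track: WindowTrack | str, label: str = "P") -> int:
    """Length of the longest interval with >= 90 % of positions == label.

    Implemented by the prefix-sum transform: an interval has mean
    indicator >= t iff the transformed sequence (indicator - t) has a
    nonnegative-sum subarray there, so the answer is the longest subarray
    with nonnegative sum — found in O(N log N) with a suffix-max over
    prefix sums.  Intervals of any length count (a single matching residue
    gives 1); returns 0 when the label never appears.
    """
    _, labels = _labels_of(track)
    threshold = DEFAULT_CONSTANTS.purity_threshold
    p, q = _threshold_ratio(threshold)
    arr = np.frombuffer(labels.encode(), dtype="S1")
    # integer transform: q*indicator - p has nonnegative subarray sum
    # exactly where the interval purity is >= p/q
    x = q * (arr == label.encode()).astype(np.int64) - p
    n = x.size
    if n == 0:
        return 0
    prefix = np.concatenate(([0], np.cumsum(x)))
    # longest j - i with prefix[j] >= prefix[i], i < j
    order = np.argsort(prefix, kind="stable")  # ties: earlier index first
    best = 0
    min_idx = n + 1
    for idx in order:
        if idx < min_idx:
            min_idx = idx
        elif idx - min_idx > best:
            best = idx - min_idx
    return int(best)


def regions_to_bed(
    regions: Sequence[LabeledRegion], path: str | Path | None = None
) -> str:
    """Render regions as BED6 (0-based half-open), one line per region.

    chrom = sequence id, name = label, score = round(1000 * purity),
    strand = '.'.  Writes to ``path`` when given; returns the text either
    way.  An empty region list yields only the header comment.
    """
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    for r in regions:
        lines.append(
            f"{r.id}\t{r.start - 1}\t{r.end}\t{r.label}\t{round(1000 * r.purity)}\t."
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def regions_to_tsv(
    regions: Sequence[LabeledRegion], path: str | Path | None = None
) -> str:
    """Region table: id, start_1based, end_1based, label, length, purity."""
    lines = ["id\tstart_1based\tend_1based\tlabel\tlength\tpurity"]
    for r in regions:
        lines.append(
            f"{r.id}\t{r.start}\t{r.end}\t{r.label}\t{r.length}\t{r.purity:.4f}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
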
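"""Cohort summaries, two-sample tests, and proteome-wide region scans.

The cohort machinery reproduces the set-level analysis used to place the
sector boundaries: per-set descriptor means with sample SDs, pairwise
one-tail z-tests on the set variances, and the nonparametric Mann–Whitney
U test.  The proteome scan measures, per protein, the longest interval
that is >= 90 % P-labeled and summarises a set of proteins as a cumulative
curve (percent of proteins whose longest such region reaches each length
threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import describe_batch, f_ppii, net_charge, predict_rh, turn_levitt, v_model
from .region_caller import longest_pure_region
from .scales import DEFAULT_CONSTANTS, ModelConstants
from .window_classifier import SectorGeometry, NearestCentroidGeometry, label_sequence

__all__ = [
    "CohortSummary",
    "CumulativeCurve",
    "summarize",
    "z_test_one_tail",
    "mann_whitney_u",
    "classify_whole_sequences",
    "proteome_scan",
    "cohort_report",
]


def summarize(values: Sequence[float] | pd.Series) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n - 1 denominator) of a descriptor.

    Requires n >= 2 — the sample SD is undefined for a single value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need n >= 2 values for mean/SD, got {arr.size}")
    return float(arr.mean()), float(arr.std(ddof=1))


def z_test_one_tail(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """One-tail two-sample z-test p-value using the set variances.

    ``z = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)``; the returned p-value is
    the upper-tail standard-normal probability of |z|, so identical
    summaries give exactly 0.5 and the result is symmetric in the two
    samples.  p always lies in (0, 0.5].
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("z-test needs n >= 2 in both sets")
    se = math.sqrt(s1**2 / n1 + s2**2 / n2)
    if se == 0.0:
        raise ValueError("degenerate z-test: both set SDs are zero")
    z = (m1 - m2) / se
    return float(stats.norm.sf(abs(z)))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann–Whitney U statistic (for ``x``) and p-value.

    Midranks handle ties.  The null distribution is evaluated exactly when
    both samples have n <= 20 and there are no ties, and by the normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann–Whitney U needs nonempty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CohortSummary:
    """Per-set descriptor summaries plus pairwise test results."""

    name: str
    n: int
    means: Mapping[str, float]
    sds: Mapping[str, float]
    z_pvalues: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    u_pvalues: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


def cohort_report(
    sets: Mapping[str, pd.DataFrame],
    fields: Sequence[str] = ("v_model", "turn_levitt", "v_int", "r_model"),
) -> dict[str, CohortSummary]:
    """Summaries and pairwise tests for named descriptor tables.

    ``sets`` maps a cohort name to its descriptor DataFrame (as returned
    by :func:`parse_llps.descriptors.describe_batch`).  For every field,
    each cohort is compared with every cohort (including itself — the
    self-comparison z-test p is 0.5 by construction) by the one-tail
    z-test and the Mann–Whitney U test.
    """
    summaries: dict[str, CohortSummary] = {}
    stats_cache = {
        name: {f: summarize(df[f]) for f in fields} for name, df in sets.items()
    }
    for name, df in sets.items():
        z_p: dict[str, dict[str, float]] = {}
        u_p: dict[str, dict[str, float]] = {}
        for f in fields:
            m1, s1 = stats_cache[name][f]
            z_p[f] = {}
            u_p[f] = {}
            for other, odf in sets.items():
                m2, s2 = stats_cache[other][f]
                z_p[f][other] = z_test_one_tail(m1, s1, len(df), m2, s2, len(odf))
                u_p[f][other] = mann_whitney_u(df[f], odf[f])[1]
        summaries[name] = CohortSummary(
            name=name,
            n=len(df),
            means={f: stats_cache[name][f][0] for f in fields},
            sds={f: stats_cache[name][f][1] for f in fields},
            z_pvalues=z_p,
            u_pvalues=u_p,
        )
    return summaries


@dataclass(frozen=True)
class CumulativeCurve:
    """Percent of proteins whose longest >= 90 %-P region reaches a length.

    ``thresholds`` are region lengths in residues (1..max observed);
    ``percent`` is non-increasing and bounded in [0, 100].
    """

    thresholds: np.ndarray
    percent: np.ndarray

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.percent):
            raise ValueError("thresholds and percent must align")

    def percent_at(self, threshold: int) -> float:
        """Percent of proteins with a region at least ``threshold`` long."""
        if len(self.thresholds) == 0 or threshold > self.thresholds[-1]:
            return 0.0
        i = np.searchsorted(self.thresholds, threshold)
        return float(self.percent[i])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"threshold": self.thresholds, "percent": self.percent}
        ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def classify_whole_sequences(
    records: Iterable,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    geometry: SectorGeometry | None = None,
) -> pd.DataFrame:
    """Whole-sequence (v_model, turn) points with their sector.

    One row per record: id, N, v_model, turn_levitt, sector.  This is the
    whole-domain view used to estimate how often folded domains land in
    the Folded sector.
    """
    geometry = geometry or NearestCentroidGeometry(
        centroids=dict(constants.sector_centroids), sigmas=constants.sector_sigmas
    )
    rows = []
    for rec in records:
        seq_id, seq = (rec.id, str(rec.seq)) if hasattr(rec, "seq") else rec
        n = len(seq)
        rh = predict_rh(n, f_ppii(seq), net_charge(seq), constants)
        v = v_model(rh, n, constants)
        t = turn_levitt(seq)
        rows.append(
            {
                "id": seq_id,
                "N": n,
                "v_model": v,
                "turn_levitt": t,
                "sector": geometry.classify(v, t),
            }
        )
    return pd.DataFrame(rows, columns=["id", "N", "v_model", "turn_levitt", "sector"])


def proteome_scan(
    records: Iterable,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    geometry: SectorGeometry | None = None,
    label: str = "P",
    turn_scale: str = "levitt_turn",
) -> tuple[pd.DataFrame, CumulativeCurve, int]:
    """Longest >= 90 %-pure ``label`` region per protein + cumulative curve.

    Records too short for windowed labeling (N <= window size) or with
    invalid residues are counted and skipped, never aborting the batch.
    Returns (per-protein table, curve, n_skipped).  The curve spans
    thresholds 1..max observed length; with no proteins or no labeled
    regions it is empty/all-zero respectively.
    """
    kwargs = {"constants": constants, "turn_scale": turn_scale}
    if geometry is not None:
        kwargs["geometry"] = geometry
    rows = []
    skipped = 0
    for rec in records:
        seq_id, seq = (rec.id, str(rec.seq)) if hasattr(rec, "seq") else rec
        try:
            track = label_sequence(seq, seq_id=seq_id, **kwargs)
        except ValueError:
            skipped += 1
            continue
        rows.append(
            {
                "id": seq_id,
                "N": len(track.sequence),
                "longest_P": longest_pure_region(track, label=label),
            }
        )
    table = pd.DataFrame(rows, columns=["id", "N", "longest_P"])
    if len(table) == 0:
        curve = CumulativeCurve(np.array([], dtype=int), np.array([]))
        return table, curve, skipped
    longest = table["longest_P"].to_numpy()
    max_len = int(longest.max()) if longest.size else 0
    thresholds = np.arange(1, max(max_len, 1) + 1)
    percent = np.array(
        [100.0 * np.mean(longest >= t) for t in thresholds]
    )
    return table, CumulativeCurve(thresholds, percent), skipped
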
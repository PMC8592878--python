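"""Sliding-window classification of residues into P / D / F labels.

A 25-residue window slides along the sequence in 1-residue steps.  For
each window the polymer scaling exponent v_model is computed after
expanding the window composition 4-fold (so the exponent is evaluated at
an effective length of 100 residues, where it is length-stable while
remaining composition-sensitive), together with the Levitt beta-turn
propensity of the window.  The (v, turn) point places the window in the
PS, ID, or Folded sector of the turn-vs-v plane, and the window's central
residue inherits the sector label P, D, or F.  Terminal residues outside
any central window position copy the first / last window's label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol

import numpy as np

from .descriptors import predict_rh
from .scales import DEFAULT_CONSTANTS, ModelConstants, load_scale, validate_sequence

__all__ = [
    "SECTOR_TO_LABEL",
    "LABEL_TO_SECTOR",
    "SectorGeometry",
    "NearestCentroidGeometry",
    "WindowTrack",
    "window_v_model",
    "window_turn",
    "classify_point",
    "label_sequence",
]

_PPII = load_scale("ppii")
_LEVITT = load_scale("levitt_turn")
_CHARGE = load_scale("charge")

#: sector name -> residue label
SECTOR_TO_LABEL: Mapping[str, str] = {"PS": "P", "ID": "D", "Folded": "F"}
LABEL_TO_SECTOR: Mapping[str, str] = {v: k for k, v in SECTOR_TO_LABEL.items()}


class SectorGeometry(Protocol):
    """Strategy mapping a (v_model, turn) point to a sector name."""

    def classify(self, v: float, t: float) -> str: ...


@dataclass(frozen=True)
class NearestCentroidGeometry:
    """SD-normalised nearest-centroid sector assignment.

    Distance to a sector centroid (v_c, t_c) is
    ``((v - v_c)/sigma_v)**2 + ((t - t_c)/sigma_t)**2`` with the null
    cohort's SDs as (sigma_v, sigma_t).  Ties (a measure-zero event) are
    broken by the fixed priority PS > ID > Folded for determinism.
    """

    centroids: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONSTANTS.sector_centroids)
    )
    sigmas: tuple[float, float] = DEFAULT_CONSTANTS.sector_sigmas
    priority: tuple[str, ...] = ("PS", "ID", "Folded")

    def classify(self, v: float, t: float) -> str:
        if not (math.isfinite(v) and math.isfinite(t)):
            raise ValueError(f"non-finite point (v={v}, t={t})")
        sv, st = self.sigmas
        best, best_d = None, math.inf
        for sector in self.priority:
            vc, tc = self.centroids[sector]
            d = ((v - vc) / sv) ** 2 + ((t - tc) / st) ** 2
            if d < best_d:  # strict: earlier priority wins ties
                best, best_d = sector, d
        return best


_DEFAULT_GEOMETRY = NearestCentroidGeometry()


def classify_point(
    v: float, t: float, geometry: SectorGeometry = _DEFAULT_GEOMETRY
) -> str:
    """Sector ('PS', 'ID', or 'Folded') of a (v_model, turn) point."""
    return geometry.classify(v, t)


def window_v_model(
    window_seq: str,
    multiplier: int | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """v_model of a window after k-fold composition expansion.

    The count of each residue type is multiplied by k (default 4) giving an
    effective length N' = k * len(window); the PPII fraction is unchanged
    while the net charge scales to k * Q_net.  v is then obtained from the
    predicted R_h at N'.  At the default 25-residue window and k = 4 the
    exponent is evaluated at N' = 100, where it has become
    length-independent for natural compositions.
    """
    window_seq = validate_sequence(window_seq)
    if len(window_seq) != constants.window_size:
        raise ValueError(
            f"window length {len(window_seq)} != configured window_size "
            f"{constants.window_size}"
        )
    k = constants.expansion_multiplier if multiplier is None else multiplier
    if k < 1:
        raise ValueError(f"multiplier must be >= 1, got {k}")
    n_eff = k * len(window_seq)
    f = sum(_PPII[aa] for aa in window_seq) / len(window_seq)
    q_eff = k * sum(_CHARGE[aa] for aa in window_seq)
    rh = predict_rh(n_eff, f, q_eff, constants)
    return math.log(rh / constants.R0) / math.log(n_eff)


def window_turn(
    window_seq: str,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    turn_scale: str = "levitt_turn",
) -> float:
    """Beta-turn propensity of a window (no expansion needed — the
    composition mean does not depend on length).  The Levitt scale is the
    classifier default; a drop-in composition scale of identical shape
    may be named instead."""
    window_seq = validate_sequence(window_seq)
    if len(window_seq) != constants.window_size:
        raise ValueError(
            f"window length {len(window_seq)} != configured window_size "
            f"{constants.window_size}"
        )
    table = _LEVITT if turn_scale == "levitt_turn" else load_scale(turn_scale)
    return sum(table[aa] for aa in window_seq) / len(window_seq)


@dataclass(frozen=True)
class WindowTrack:
    """Per-residue window values and P/D/F labels for one sequence.

    All arrays have length N.  For interior residues (window centers) the
    values derive from the window centered at that residue; terminal
    residues carry the first / last window's values and label.
    """

    id: str
    sequence: str
    window_v_model: np.ndarray
    window_turn: np.ndarray
    labels: str

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (len(self.labels) == len(self.window_v_model) == len(self.window_turn) == n):
            raise ValueError("track arrays must all have the sequence length")
        if set(self.labels) - set("PDF"):
            raise ValueError(f"labels must be P/D/F, got {set(self.labels)}")

    @property
    def n(self) -> int:
        return len(self.sequence)

    def residue_r_model(self) -> np.ndarray:
        """Per-residue ratio window_turn / window_v_model."""
        return self.window_turn / self.window_v_model

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": np.arange(1, self.n + 1),
                "residue": list(self.sequence),
                "window_v_model": self.window_v_model,
                "window_turn": self.window_turn,
                "label": list(self.labels),
                "residue_r_model": self.residue_r_model(),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _window_center_offset(size: int) -> int:
    # 25-mer starting at 1-based s centers at s + 12; even sizes center at
    # s + size/2 - 1 by convention.
    return (size - 1) // 2 if size % 2 == 1 else size // 2 - 1


def label_sequence(
    seq: str,
    seq_id: str = "seq",
    constants: ModelConstants = DEFAULT_CONSTANTS,
    geometry: SectorGeometry = _DEFAULT_GEOMETRY,
    turn_scale: str = "levitt_turn",
) -> WindowTrack:
    """Label every residue of ``seq`` as P, D, or F.

    Requires N > window_size.  Window w (1-based start s) assigns its
    sector label to the central residue s + 12 (for the default 25-mer);
    residues before the first center copy window 1, residues after the
    last center copy the final window.
    """
    seq = validate_sequence(seq)
    n = len(seq)
    size = constants.window_size
    if n <= size:
        raise ValueError(
            f"windowed labeling needs N > {size}, got N={n}; "
            "whole-sequence descriptors remain available for short sequences"
        )
    n_windows = n - size + 1
    offset = _window_center_offset(size)

    turn_table = _LEVITT if turn_scale == "levitt_turn" else load_scale(turn_scale)
    # Rolling composition update: O(N) scale lookups instead of O(N*size).
    ppii_sum = sum(_PPII[aa] for aa in seq[:size])
    turn_sum = sum(turn_table[aa] for aa in seq[:size])
    q_sum = sum(_CHARGE[aa] for aa in seq[:size])
    k = constants.expansion_multiplier
    n_eff = k * size
    log_n_eff = math.log(n_eff)
    c0, c1, c2, c3, c4 = constants.rh_coeffs
    sqrt_n_eff = math.sqrt(n_eff)

    win_v = np.empty(n_windows)
    win_t = np.empty(n_windows)
    for w in range(n_windows):
        if w > 0:
            out, inc = seq[w - 1], seq[w + size - 1]
            ppii_sum += _PPII[inc] - _PPII[out]
            turn_sum += turn_table[inc] - turn_table[out]
            q_sum += _CHARGE[inc] - _CHARGE[out]
        f = ppii_sum / size
        if f >= 1.0:
            raise ValueError(
                f"window starting at position {w + 1} is pure proline "
                "(f_PPII = 1); the R_h model is undefined there"
            )
        rh = c0 * n_eff ** (c1 - c2 * math.log(1.0 - f)) + c3 * abs(k * q_sum) - c4 * sqrt_n_eff
        win_v[w] = math.log(rh / constants.R0) / log_n_eff
        win_t[w] = turn_sum / size

    win_labels = [
        SECTOR_TO_LABEL[geometry.classify(win_v[w], win_t[w])] for w in range(n_windows)
    ]

    # Spread window values/labels onto residues via the center convention.
    res_v = np.empty(n)
    res_t = np.empty(n)
    res_labels = []
    first_center = offset  # 0-based index of window 1's central residue
    last_center = (n_windows - 1) + offset
    for i in range(n):
        w = min(max(i - offset, 0), n_windows - 1)
        res_v[i] = win_v[w]
        res_t[i] = win_t[w]
        res_labels.append(win_labels[w])
    assert first_center <= last_center  # N > size guarantees >= 1 window

    return WindowTrack(
        id=seq_id,
        sequence=seq,
        window_v_model=res_v,
        window_turn=res_t,
        labels="".join(res_labels),
    )
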
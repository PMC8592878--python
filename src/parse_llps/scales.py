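"""Amino-acid scale tables and model constants.

Every downstream computation (hydrodynamic radius prediction, turn
propensity, hydropathy/charge patterning, window classification) reads its
per-residue numbers from the validated tables housed here.  Tables are
embedded constants — nothing is fetched at runtime — so results are
bit-exact reproducible across machines.

Provenance of each table is recorded in a comment next to its values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "AMINO_ACIDS",
    "ScaleTable",
    "ModelConstants",
    "DEFAULT_CONSTANTS",
    "SCALE_NAMES",
    "load_scale",
    "validate_sequence",
    "export_scales_tsv",
    "InvalidResidueError",
    "EmptySequenceError",
    "UnknownScaleError",
]

#: The 20 standard one-letter residue codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")


class UnknownScaleError(KeyError):
    """Requested scale name is not shipped with the package."""


class InvalidResidueError(ValueError):
    """Sequence contains a character outside the 20 standard residue codes."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"invalid residue {char!r} at position {position}; "
            "only the 20 standard one-letter codes are accepted"
        )


class EmptySequenceError(ValueError):
    """Empty input where a protein sequence was required."""


@dataclass(frozen=True)
class ScaleTable:
    """A named per-residue numeric scale.

    ``values`` maps each of the 20 standard one-letter codes to a real
    number.  For positional scales (the four-position turn potentials)
    ``positional`` holds per-residue 4-tuples for turn positions
    i, i+1, i+2, i+3, and ``values`` holds the position-averaged number.
    """

    name: str
    values: Mapping[str, float]
    positional: Mapping[str, tuple[float, float, float, float]] | None = None

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r}: residue codes mismatch "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        if self.positional is not None:
            if set(self.positional) != set(AMINO_ACIDS):
                raise ValueError(f"scale {self.name!r}: positional table incomplete")
            for aa, pos in self.positional.items():
                if len(pos) != 4:
                    raise ValueError(
                        f"scale {self.name!r}: residue {aa} needs 4 positional values"
                    )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def mean(self) -> float:
        return sum(self.values.values()) / len(self.values)


# ---------------------------------------------------------------------------
# Embedded tables
# ---------------------------------------------------------------------------

# Experimental polyproline II propensities of the 20 amino acids in unfolded
# peptides (Hilser lab host–guest measurements; Elam et al. 2013).  Proline,
# the reference residue, carries propensity 1.00 exactly; all others < 1.
_PPII = {
    "A": 0.37, "C": 0.25, "D": 0.30, "E": 0.42, "F": 0.17,
    "G": 0.13, "H": 0.20, "I": 0.39, "K": 0.56, "L": 0.24,
    "M": 0.36, "N": 0.27, "P": 1.00, "Q": 0.53, "R": 0.38,
    "S": 0.24, "T": 0.32, "V": 0.39, "W": 0.25, "Y": 0.25,
}

# Normalized beta-turn frequencies from the structural survey of Levitt
# (Biochemistry 1978).  Values near 1 are average; P, G, S, N, D are
# turn-preferring, branched hydrophobics I, L, V are turn-avoiding.
_LEVITT_TURN = {
    "A": 0.77, "C": 0.81, "D": 1.41, "E": 0.99, "F": 0.59,
    "G": 1.64, "H": 0.68, "I": 0.51, "K": 0.96, "L": 0.58,
    "M": 0.41, "N": 1.28, "P": 1.91, "Q": 0.98, "R": 0.88,
    "S": 1.32, "T": 1.04, "V": 0.47, "W": 0.76, "Y": 1.05,
}

# Beta-turn conformational parameters Pt of Chou & Fasman
# (Adv. Enzymol. 1978).
_CHOU_FASMAN_TURN = {
    "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60,
    "G": 1.56, "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59,
    "M": 0.60, "N": 1.56, "P": 1.52, "Q": 0.98, "R": 0.95,
    "S": 1.43, "T": 0.96, "V": 0.50, "W": 0.96, "Y": 1.14,
}

# Position-specific beta-turn potentials for the four turn positions
# (i, i+1, i+2, i+3), from the revised turn survey of Hutchinson & Thornton
# (Protein Sci. 1994), all turn types combined.  Transcribed from the
# published table; only the position-resolved turn calculator reads these —
# the P/D/F classifier itself uses the Levitt single-position scale.
_HT_TURN_POSITIONAL = {
    "A": (0.96, 1.25, 0.67, 0.81),
    "C": (1.08, 0.56, 0.93, 1.15),
    "D": (1.48, 1.43, 1.12, 0.86),
    "E": (0.82, 1.36, 0.69, 0.76),
    "F": (0.74, 0.64, 0.65, 1.06),
    "G": (1.25, 0.56, 1.47, 1.64),
    "H": (1.06, 0.74, 1.52, 1.11),
    "I": (0.78, 0.61, 0.42, 0.57),
    "K": (1.00, 1.01, 1.06, 1.14),
    "L": (0.66, 0.62, 0.50, 0.91),
    "M": (0.56, 0.68, 0.53, 0.95),
    "N": (1.74, 0.79, 1.51, 1.35),
    "P": (1.46, 2.96, 0.05, 0.48),
    "Q": (0.79, 1.11, 0.86, 0.95),
    "R": (0.88, 1.10, 0.86, 0.86),
    "S": (1.35, 1.12, 1.26, 1.13),
    "T": (1.21, 1.02, 0.84, 1.06),
    "V": (0.80, 0.66, 0.42, 0.63),
    "W": (0.81, 0.97, 0.64, 1.05),
    "Y": (1.05, 0.66, 0.87, 1.41),
}

# Atom-level octanol–water hydropathy of Kapcha & Rossky (J. Mol. Biol.
# 2014) rescaled to [0, 1] as adopted by the coarse-grained IDP force
# fields and the SHD patterning descriptor (lambda values).
_HYDROPATHY_NORMALIZED = {
    "A": 0.730, "C": 0.595, "D": 0.378, "E": 0.459, "F": 1.000,
    "G": 0.649, "H": 0.514, "I": 0.973, "K": 0.514, "L": 0.973,
    "M": 0.838, "N": 0.432, "P": 1.000, "Q": 0.514, "R": 0.000,
    "S": 0.595, "T": 0.676, "V": 0.892, "W": 0.946, "Y": 0.865,
}

# Formal charge at neutral pH as counted by the net-charge descriptor:
# +1 for K and R, -1 for D and E, 0 for everything else (histidine,
# cysteine, and termini excluded by construction).
_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
_CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})


def _ht_position_mean() -> dict[str, float]:
    return {aa: sum(pos) / 4.0 for aa, pos in _HT_TURN_POSITIONAL.items()}


_TABLES: dict[str, ScaleTable] = {
    "ppii": ScaleTable("ppii", _PPII),
    "levitt_turn": ScaleTable("levitt_turn", _LEVITT_TURN),
    "chou_fasman_turn": ScaleTable("chou_fasman_turn", _CHOU_FASMAN_TURN),
    "ht_turn_positional": ScaleTable(
        "ht_turn_positional", _ht_position_mean(), positional=_HT_TURN_POSITIONAL
    ),
    "hydropathy_normalized": ScaleTable(
        "hydropathy_normalized", _HYDROPATHY_NORMALIZED
    ),
    "charge": ScaleTable("charge", _CHARGE),
}

SCALE_NAMES: tuple[str, ...] = tuple(_TABLES)


def _validate_table_invariants(table: ScaleTable) -> None:
    if table.name == "ppii":
        bad = {aa: v for aa, v in table.values.items() if not (0.0 < v <= 1.0)}
        if bad:
            raise ValueError(f"ppii propensities outside (0, 1]: {bad}")
    elif table.name == "charge":
        bad = {aa: v for aa, v in table.values.items() if v not in (-1.0, 0.0, 1.0)}
        if bad:
            raise ValueError(f"charge values outside {{-1, 0, +1}}: {bad}")
    elif table.name == "hydropathy_normalized":
        bad = {aa: v for aa, v in table.values.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ValueError(f"normalized hydropathy outside [0, 1]: {bad}")


def load_scale(name: str) -> ScaleTable:
    """Return the validated built-in scale table called ``name``.

    Supported names: ``ppii``, ``levitt_turn``, ``chou_fasman_turn``,
    ``ht_turn_positional``, ``hydropathy_normalized``, ``charge``.
    """
    try:
        table = _TABLES[name]
    except KeyError:
        raise UnknownScaleError(
            f"unsupported scale {name!r}; available: {', '.join(SCALE_NAMES)}"
        ) from None
    _validate_table_invariants(table)
    return table


def validate_sequence(seq: str) -> str:
    """Uppercase ``seq`` and verify it uses only the 20 standard codes.

    Raises :class:`EmptySequenceError` for empty input and
    :class:`InvalidResidueError` (carrying the 1-based position) for any
    other character, including the ambiguity codes X/B/Z/U/O — no scale
    value is ever imputed for a nonstandard residue.
    """
    if not isinstance(seq, str):
        raise TypeError(f"sequence must be a string, got {type(seq).__name__}")
    if seq == "":
        raise EmptySequenceError("empty sequence")
    seq = seq.upper()
    allowed = set(AMINO_ACIDS)
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise InvalidResidueError(ch, i)
    return seq


def export_scales_tsv(directory: str | Path) -> list[Path]:
    """Write every built-in scale as an audit TSV under ``directory``.

    Columns are ``residue\\tvalue`` plus ``pos_i..pos_i3`` for positional
    scales.  Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in SCALE_NAMES:
        table = load_scale(name)
        path = directory / f"scale_{name}.tsv"
        with open(path, "w") as fh:
            if table.positional is None:
                fh.write("residue\tvalue\n")
                for aa in AMINO_ACIDS:
                    fh.write(f"{aa}\t{table.values[aa]:g}\n")
            else:
                fh.write("residue\tvalue\tpos_i\tpos_i1\tpos_i2\tpos_i3\n")
                for aa in AMINO_ACIDS:
                    pos = table.positional[aa]
                    fh.write(
                        f"{aa}\t{table.values[aa]:g}\t"
                        + "\t".join(f"{p:g}" for p in pos)
                        + "\n"
                    )
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Model constants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConstants:
    """All tunable constants of the classifier in one place.

    The hydrodynamic-radius predictor is
    ``R_h = 2.16 A * N**(0.503 - 0.11*ln(1 - f_PPII)) + 0.26*|Q_net|
    - 0.29*N**0.5`` and the scaling exponent is
    ``v = log(R_h / R0) / log(N)`` with ``R0 = 2.16 A``.  The internal
    scaling exponent is ``v_int = a*SHD + b*SCD + c``.  Windowed
    classification uses a 25-residue window whose composition is expanded
    ``expansion_multiplier``-fold before evaluating v, and regions are
    called with the >=20-residue, >=90 %-purity rule.  Sector centroids are
    the (v, turn) means of the three calibration cohorts with the null
    cohort's SDs as the normalisation.
    """

    R0: float = 2.16  # Angstrom; prefactor of R_h = R0 * N**v
    rh_coeffs: tuple[float, float, float, float, float] = (
        2.16,   # Angstrom, chain-length prefactor
        0.503,  # baseline scaling exponent at f_PPII = 0
        0.11,   # PPII sensitivity of the exponent
        0.26,   # Angstrom per unit |Q_net|
        0.29,   # Angstrom * N**-0.5 finite-size correction
    )
    vint_coeffs: tuple[float, float, float] = (-0.0423, 0.0074, 0.701)  # a, b, c
    window_size: int = 25
    expansion_multiplier: int = 4
    min_region_length: int = 20
    purity_threshold: float = 0.90
    # (v_model, turn) centroids of the PS / ID / Folded sectors
    sector_centroids: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "PS": (0.542, 1.152),
            "ID": (0.558, 1.062),
            "Folded": (0.536, 0.969),
        }
    )
    # null-cohort SDs used to normalise distances in the (v, turn) plane
    sector_sigmas: tuple[float, float] = (0.019, 0.082)

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.expansion_multiplier < 1:
            raise ValueError("expansion_multiplier must be >= 1")
        if not (0.0 < self.purity_threshold <= 1.0):
            raise ValueError("purity_threshold must be in (0, 1]")
        if self.min_region_length < 1:
            raise ValueError("min_region_length must be >= 1")

    def replace(self, **kwargs) -> "ModelConstants":
        from dataclasses import replace

        return replace(self, **kwargs)


DEFAULT_CONSTANTS = ModelConstants()
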
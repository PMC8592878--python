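"""FASTA ingestion and run manifests.

Reading goes through Biopython's parser; each record's sequence is
validated against the 20 standard residue codes.  Two policies govern
invalid records: ``strict`` (default) raises on the first offending
record, ``skip`` drops whole records and counts them — a scale value is
never imputed for a nonstandard residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import EmptySequenceError, InvalidResidueError, validate_sequence

__all__ = ["SequenceRecord", "read_fasta", "write_fasta", "write_run_manifest"]


@dataclass(frozen=True)
class SequenceRecord:
    """A validated sequence with its FASTA id and description."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        object.__setattr__(self, "seq", validate_sequence(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(
    path: str | Path, policy: str = "strict"
) -> tuple[list[SequenceRecord], int]:
    """Read a multi-record FASTA file.

    Returns ``(records, n_skipped)``.  Wrapped sequence lines are joined
    and whitespace stripped by the parser.  Duplicate ids are always an
    error; invalid residues or empty sequences raise under the ``strict``
    policy and are skipped (and counted) under ``skip``.
    """
    if policy not in ("strict", "skip"):
        raise ValueError(f"policy must be 'strict' or 'skip', got {policy!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    skipped = 0
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} (record {i})")
        seen.add(rec.id)
        try:
            records.append(
                SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
            )
        except (InvalidResidueError, EmptySequenceError) as err:
            if policy == "strict":
                raise ValueError(f"record {i} ({rec.id!r}): {err}") from err
            skipped += 1
    return records, skipped


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records as FASTA with ``wrap``-column sequence lines."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def write_run_manifest(path: str | Path, **params) -> Path:
    """Write an auditable JSON manifest of run parameters.

    Every CLI run records its scales version, window size, multiplier,
    centroids, thresholds and seeds here so outputs can be reproduced.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _jsonable(v):
        if isinstance(v, (str, int, float, bool)) or v is None:
            return v
        if isinstance(v, dict):
            return {k: _jsonable(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_jsonable(x) for x in v]
        return repr(v)

    path.write_text(json.dumps({k: _jsonable(v) for k, v in params.items()}, indent=2))
    return path
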
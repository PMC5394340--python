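"""FASTA and AGP (v2.1) reading and writing.

AGP coordinates are 1-based inclusive on both the object and the component,
per the format definition; all internal pipeline coordinates are 0-based
half-open and converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AGPRow",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "read_agp",
    "write_agp",
    "validate_agp",
    "fasta_from_agp",
]

AGP_HEADER = "##agp-version\t2.1"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class AGPRow:
    """One AGP line: a W (component) or N (gap) row."""

    object: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # 'W' or 'N'
    # W fields
    component_id: str = ""
    component_beg: int = 0
    component_end: int = 0
    orientation: str = "+"
    # N fields
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "map"

    def fields(self) -> list[str]:
        if self.component_type == "W":
            tail = [
                self.component_id,
                str(self.component_beg),
                str(self.component_end),
                self.orientation,
            ]
        else:
            tail = [str(self.gap_length), self.gap_type, self.linkage, self.evidence]
        return [
            self.object,
            str(self.object_beg),
            str(self.object_end),
            str(self.part_number),
            self.component_type,
            *tail,
        ]


def write_agp(path: str | Path, rows: Iterable[AGPRow]) -> None:
    with open(path, "w") as fh:
        fh.write(AGP_HEADER + "\n")
        for row in rows:
            fh.write("\t".join(row.fields()) + "\n")


def read_agp(path: str | Path) -> list[AGPRow]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: AGP rows have 9 columns, got {len(f)}")
            base = dict(
                object=f[0],
                object_beg=int(f[1]),
                object_end=int(f[2]),
                part_number=int(f[3]),
                component_type=f[4],
            )
            if f[4] in ("N", "U"):
                rows.append(
                    AGPRow(
                        **base,
                        gap_length=int(f[5]),
                        gap_type=f[6],
                        linkage=f[7],
                        evidence=f[8],
                    )
                )
            else:
                rows.append(
                    AGPRow(
                        **base,
                        component_id=f[5],
                        component_beg=int(f[6]),
                        component_end=int(f[7]),
                        orientation=f[8],
                    )
                )
    return rows


def validate_agp(rows: Iterable[AGPRow]) -> None:
    """Check that rows tile each object exactly, with sane W spans."""
    expect: dict[str, tuple[int, int]] = {}  # object -> (next_beg, next_part)
    for row in rows:
        beg, part = expect.get(row.object, (1, 1))
        if row.object_beg != beg or row.part_number != part:
            raise ValueError(
                f"AGP rows do not tile {row.object}: part {row.part_number} "
                f"starts at {row.object_beg}, expected {beg}"
            )
        span = row.object_end - row.object_beg + 1
        if span < 1:
            raise ValueError(f"{row.object} part {row.part_number}: empty span")
        if row.component_type == "W":
            if row.orientation not in ("+", "-", "?"):
                raise ValueError(
                    f"{row.object} part {row.part_number}: bad orientation "
                    f"{row.orientation!r}"
                )
            if row.component_end - row.component_beg + 1 != span:
                raise ValueError(
                    f"{row.object} part {row.part_number}: component span != object span"
                )
        else:
            if row.gap_length != span:
                raise ValueError(
                    f"{row.object} part {row.part_number}: gap_length != span"
                )
        expect[row.object] = (row.object_end + 1, part + 1)


def fasta_from_agp(
    rows: Iterable[AGPRow], component_seqs: Mapping[str, str]
) -> dict[str, str]:
    """Rebuild object sequences from AGP rows plus component sequences.

    Unknown orientation '?' is treated as '+' (component used as stored),
    the convention this package also applies when emitting unoriented
    placements.
    """
    rows = list(rows)
    validate_agp(rows)
    out: dict[str, list[str]] = {}
    for row in rows:
        parts = out.setdefault(row.object, [])
        if row.component_type == "W":
            try:
                seq = component_seqs[row.component_id]
            except KeyError:
                raise KeyError(
                    f"no sequence for component {row.component_id!r}"
                ) from None
            piece = seq[row.component_beg - 1 : row.component_end]
            if row.orientation == "-":
                piece = reverse_complement(piece)
            parts.append(piece)
        else:
            parts.append("N" * row.gap_length)
    return {obj: "".join(parts) for obj, parts in out.items()}
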
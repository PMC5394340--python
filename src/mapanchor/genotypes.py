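"""Genotype containers for a biparental RIL mapping population.

Calls are parent-coded: ``A`` for the first founder, ``B`` for the second,
``H`` for heterozygous and ``-`` for missing.  Internally the four states are
stored as small integers so that whole marker-by-line matrices can be handled
as dense :class:`numpy.ndarray` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

# integer codes for genotype calls
P1 = 0  # first founder allele (code "A")
P2 = 1  # second founder allele (code "B")
HET = 2  # heterozygous (code "H")
MISSING = 3  # no call (code "-")

CALL_CHARS = np.array(["A", "B", "H", "-"])
CHAR_TO_CODE = {"A": P1, "B": P2, "H": HET, "-": MISSING}

META_COLUMNS = ("marker_id", "scaffold_id", "pos_bp")


class GenotypeTableError(ValueError):
    """Raised for malformed genotype tables."""


@dataclass
class MarkerTable:
    """SNP-level genotype calls per RIL, keyed by scaffold and position.

    Parameters
    ----------
    meta
        One row per marker with columns ``marker_id``, ``scaffold_id`` and
        ``pos_bp`` (0-based offset on the scaffold).
    calls
        ``(n_markers, n_rils)`` int8 array of genotype codes.
    ril_ids
        Ordered RIL identifiers, one per call column.
    """

    meta: pd.DataFrame
    calls: np.ndarray
    ril_ids: list[str]

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise GenotypeTableError(f"meta lacks columns {missing_cols}")
        if self.calls.shape != (len(self.meta), len(self.ril_ids)):
            raise GenotypeTableError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.meta)} markers x {len(self.ril_ids)} RILs"
            )
        if (self.meta["pos_bp"] < 0).any():
            raise GenotypeTableError("pos_bp must be >= 0")
        dup = self.meta.duplicated(subset=["scaffold_id", "pos_bp"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise GenotypeTableError(
                f"duplicate (scaffold_id, pos_bp) at marker row {row}"
            )
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > 3):
            raise GenotypeTableError("calls contain codes outside {0,1,2,3}")

    @property
    def n_markers(self) -> int:
        return len(self.meta)

    @property
    def n_rils(self) -> int:
        return len(self.ril_ids)

    def scaffold_ids(self) -> list[str]:
        """Scaffold ids in order of first appearance."""
        return list(dict.fromkeys(self.meta["scaffold_id"]))

    def scaffold_rows(self, scaffold_id: str) -> np.ndarray:
        """Row indices of a scaffold's markers, sorted by position."""
        mask = (self.meta["scaffold_id"] == scaffold_id).to_numpy()
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            raise KeyError(f"scaffold {scaffold_id!r} not in table")
        order = np.argsort(self.meta["pos_bp"].to_numpy()[rows], kind="stable")
        return rows[order]

    def subset(self, scaffold_id: str) -> "MarkerTable":
        rows = self.scaffold_rows(scaffold_id)
        return MarkerTable(self.meta.iloc[rows], self.calls[rows], list(self.ril_ids))

    def sorted(self) -> "MarkerTable":
        """Copy sorted by (scaffold_id, pos_bp)."""
        order = np.lexsort(
            (self.meta["pos_bp"].to_numpy(), self.meta["scaffold_id"].to_numpy())
        )
        return MarkerTable(self.meta.iloc[order], self.calls[order], list(self.ril_ids))

    def to_tsv(self, path: str | Path) -> None:
        """Write the table in the genotype TSV dialect (calls as A/B/H/-)."""
        chars = pd.DataFrame(
            CALL_CHARS[self.calls], columns=self.ril_ids, index=self.meta.index
        )
        out = pd.concat([self.meta[list(META_COLUMNS)], chars], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerTable":
        """Read a genotype TSV, validating header, row shape and call codes."""
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[: len(META_COLUMNS)] != list(META_COLUMNS):
                raise GenotypeTableError(
                    f"{path}: header must start with {' '.join(META_COLUMNS)}"
                )
            ril_ids = header[len(META_COLUMNS):]
            if not ril_ids:
                raise GenotypeTableError(f"{path}: no RIL columns in header")
            meta_rows: list[tuple[str, str, int]] = []
            call_rows: list[list[int]] = []
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(header):
                    raise GenotypeTableError(
                        f"{path}:{lineno}: expected {len(header)} fields, "
                        f"got {len(fields)}"
                    )
                try:
                    pos = int(fields[2])
                except ValueError as exc:
                    raise GenotypeTableError(
                        f"{path}:{lineno}: pos_bp {fields[2]!r} is not an integer"
                    ) from exc
                try:
                    codes = [CHAR_TO_CODE[c] for c in fields[3:]]
                except KeyError as exc:
                    raise GenotypeTableError(
                        f"{path}:{lineno}: invalid call code {exc.args[0]!r} "
                        "(expected A, B, H or -)"
                    ) from None
                meta_rows.append((fields[0], fields[1], pos))
                call_rows.append(codes)
        meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
        calls = (
            np.array(call_rows, dtype=np.int8)
            if call_rows
            else np.empty((0, len(ril_ids)), dtype=np.int8)
        )
        return cls(meta, calls, ril_ids)


@dataclass
class HaplotypeMatrix:
    """Per-scaffold consensus haplotypes: one call per RIL per scaffold.

    ``support`` is the fraction of informative marker calls backing the
    consensus; ``n_informative`` the number of non-missing marker calls used.
    """

    scaffold_ids: list[str]
    calls: np.ndarray  # (n_scaffolds, n_rils) int8
    support: np.ndarray  # (n_scaffolds, n_rils) float
    n_informative: np.ndarray  # (n_scaffolds, n_rils) int
    ril_ids: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self._index = {s: i for i, s in enumerate(self.scaffold_ids)}

    def vector(self, scaffold_id: str) -> np.ndarray:
        return self.calls[self._index[scaffold_id]]

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._index

    def subset(self, scaffold_ids: Sequence[str]) -> "HaplotypeMatrix":
        idx = [self._index[s] for s in scaffold_ids]
        return HaplotypeMatrix(
            list(scaffold_ids),
            self.calls[idx],
            self.support[idx],
            self.n_informative[idx],
            list(self.ril_ids),
        )

    def to_tsv(self, path: str | Path) -> None:
        chars = pd.DataFrame(CALL_CHARS[self.calls], columns=self.ril_ids)
        chars.insert(0, "scaffold_id", self.scaffold_ids)
        chars.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        ril_ids = list(df.columns[1:])
        chars = df[ril_ids].to_numpy()
        calls = np.vectorize(CHAR_TO_CODE.__getitem__, otypes=[np.int8])(chars)
        n_inf = (calls != MISSING).astype(int)
        return cls(
            list(df["scaffold_id"]),
            calls,
            (calls != MISSING).astype(float),
            n_inf,
            ril_ids,
        )


def majority_vector(vectors: np.ndarray) -> np.ndarray:
    """Element-wise majority call over a stack of haplotype vectors.

    The mode among non-missing calls is returned per position; ties and
    all-missing positions yield MISSING.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.int8))
    counts = np.stack([(vectors == k).sum(axis=0) for k in (P1, P2, HET)])
    top = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    n_top = (counts == top).sum(axis=0)
    out = np.where((top > 0) & (n_top == 1), winner, MISSING)
    return out.astype(np.int8)
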
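"""Per-scaffold consensus haplotypes and chimeric-scaffold detection.

In an advanced RIL population every line is a near-homozygous mosaic of the
two founder genomes, so all markers of a correctly assembled scaffold (a few
hundred kb, well under a centiMorgan-scale window for most lines) carry the
same parental call in a given line.  A misjoined (chimeric) scaffold glues
together loci that segregate independently: at the misjoin, roughly half of
the population switches parental call in a coordinated way.  This module
assigns consensus haplotypes, profiles call switches along each scaffold,
calls chimeras where the population-wide switch fraction is high, and splits
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genotypes import (
    P1,
    P2,
    HET,
    MISSING,
    HaplotypeMatrix,
    MarkerTable,
)

__all__ = [
    "ScaffoldHaplotypeVector",
    "SwitchProfile",
    "ChimeraCall",
    "ChimeraReport",
    "consensus_haplotype",
    "consensus_matrix",
    "compute_switch_profile",
    "call_chimeras",
    "detect_chimeras",
    "split_scaffold",
    "apply_chimera_splits",
]

DEFAULT_MIN_MARKERS = 2
DEFAULT_MAJORITY_THRESHOLD = 0.7
DEFAULT_BLOCK_SIZE = 5
DEFAULT_TAU = 0.30
DEFAULT_MIN_SUPPORT = 20


def _window_consensus(
    calls: np.ndarray, min_markers: int, majority_threshold: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Consensus over a marker-window: per RIL the dominant call class.

    Returns (consensus codes, support fraction, n informative).  The
    consensus is MISSING when fewer than ``min_markers`` non-missing calls
    are present or no class reaches ``majority_threshold`` of them.
    """
    calls = np.atleast_2d(calls)
    counts = np.stack([(calls == k).sum(axis=0) for k in (P1, P2, HET)])
    n_inf = counts.sum(axis=0)
    top = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(n_inf > 0, top / np.maximum(n_inf, 1), 0.0)
    ok = (n_inf >= min_markers) & (support >= majority_threshold)
    consensus = np.where(ok, winner, MISSING).astype(np.int8)
    return consensus, support, n_inf


@dataclass
class ScaffoldHaplotypeVector:
    """Consensus parental call per RIL for one scaffold."""

    scaffold_id: str
    calls: np.ndarray  # int8 per RIL
    support: np.ndarray
    n_informative: np.ndarray
    ril_ids: list[str]


def consensus_haplotype(
    table: MarkerTable,
    scaffold_id: str,
    min_markers: int = DEFAULT_MIN_MARKERS,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
) -> ScaffoldHaplotypeVector:
    """Consensus haplotype of one scaffold from all its marker calls.

    Per RIL, P1/P2/HET calls are counted over the scaffold's markers; the
    consensus is the class whose fraction among informative (non-missing)
    calls reaches ``majority_threshold``, MISSING otherwise.
    """
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    if not 0.5 < majority_threshold <= 1.0:
        raise ValueError("majority_threshold must be in (0.5, 1]")
    rows = table.scaffold_rows(scaffold_id)  # KeyError for unknown scaffold
    consensus, support, n_inf = _window_consensus(
        table.calls[rows], min_markers, majority_threshold
    )
    return ScaffoldHaplotypeVector(
        scaffold_id, consensus, support, n_inf, list(table.ril_ids)
    )


def consensus_matrix(
    table: MarkerTable,
    min_markers: int = DEFAULT_MIN_MARKERS,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
) -> HaplotypeMatrix:
    """Consensus haplotypes for every scaffold in the table."""
    scaffold_ids = table.scaffold_ids()
    rows_calls, rows_support, rows_ninf = [], [], []
    for sid in scaffold_ids:
        vec = consensus_haplotype(table, sid, min_markers, majority_threshold)
        rows_calls.append(vec.calls)
        rows_support.append(vec.support)
        rows_ninf.append(vec.n_informative)
    return HaplotypeMatrix(
        scaffold_ids,
        np.stack(rows_calls),
        np.stack(rows_support),
        np.stack(rows_ninf),
        list(table.ril_ids),
    )


@dataclass
class Junction:
    """One inter-marker junction of a switch profile."""

    left_bp: int  # position of the last marker before the junction
    right_bp: int  # position of the first marker after it
    n_switching: int
    n_informative: int

    @property
    def switch_fraction(self) -> float:
        return self.n_switching / self.n_informative if self.n_informative else float("nan")


@dataclass
class SwitchProfile:
    """Population-wide genotype-switch fractions along one scaffold."""

    scaffold_id: str
    junctions: list[Junction] = field(default_factory=list)

    @property
    def testable(self) -> bool:
        return any(j.n_informative > 0 for j in self.junctions)


def compute_switch_profile(
    table: MarkerTable,
    scaffold_id: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
) -> SwitchProfile:
    """Switch fractions at every inter-marker junction of a scaffold.

    At junction i the consensus of up to ``block_size`` markers on each side
    is compared per RIL; lines with a homozygous consensus on both sides are
    informative, and switch when the two sides disagree.  Flanking windows
    slide with the junction so a misjoin is detectable wherever it falls
    along the scaffold, while multi-marker consensus damps single-call
    genotyping errors.  Scaffolds with fewer than two markers yield an
    untestable (empty) profile.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rows = table.scaffold_rows(scaffold_id)
    m = len(rows)
    if m < 2:
        return SwitchProfile(scaffold_id)
    calls = table.calls[rows]
    pos = table.meta["pos_bp"].to_numpy()[rows]
    junctions = []
    for i in range(1, m):
        left, _, _ = _window_consensus(
            calls[max(0, i - block_size): i], 1, majority_threshold
        )
        right, _, _ = _window_consensus(
            calls[i: i + block_size], 1, majority_threshold
        )
        informative = (left <= P2) & (right <= P2)  # homozygous both sides
        switching = informative & (left != right)
        junctions.append(
            Junction(
                int(pos[i - 1]),
                int(pos[i]),
                int(switching.sum()),
                int(informative.sum()),
            )
        )
    return SwitchProfile(scaffold_id, junctions)


@dataclass
class ChimeraCall:
    """One called misjoin: a breakpoint interval on a scaffold."""

    scaffold_id: str
    breakpoint_lo: int  # half-open interval [lo, hi) containing the misjoin
    breakpoint_hi: int
    switch_fraction: float
    n_informative: int


@dataclass
class ChimeraReport:
    scaffold_id: str
    verdict: str  # chimeric | clean | untestable
    calls: list[ChimeraCall] = field(default_factory=list)
    max_switch_fraction: float = float("nan")


def call_chimeras(
    profile: SwitchProfile,
    tau: float = DEFAULT_TAU,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> ChimeraReport:
    """Classify a scaffold from its switch profile.

    A junction qualifies when its switch fraction reaches ``tau`` over at
    least ``min_support`` informative lines.  Runs of adjacent qualifying
    junctions (a misjoin elevates neighbouring sliding windows too) are
    merged to the single junction of maximal fraction.  Scaffolds without
    any sufficiently supported junction are untestable rather than clean.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    supported = [
        j for j in profile.junctions if j.n_informative >= min_support
    ]
    if not supported:
        return ChimeraReport(profile.scaffold_id, "untestable")
    max_frac = max(j.switch_fraction for j in supported)
    qual_idx = [
        i
        for i, j in enumerate(profile.junctions)
        if j.n_informative >= min_support and j.switch_fraction >= tau
    ]
    if not qual_idx:
        return ChimeraReport(profile.scaffold_id, "clean", [], max_frac)
    # merge consecutive qualifying junctions into one call each
    runs: list[list[int]] = [[qual_idx[0]]]
    for i in qual_idx[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    calls = []
    for run in runs:
        best = max(run, key=lambda i: (profile.junctions[i].switch_fraction, -i))
        j = profile.junctions[best]
        calls.append(
            ChimeraCall(
                profile.scaffold_id,
                j.left_bp,
                j.right_bp,
                j.switch_fraction,
                j.n_informative,
            )
        )
    return ChimeraReport(profile.scaffold_id, "chimeric", calls, max_frac)


def detect_chimeras(
    table: MarkerTable,
    block_size: int = DEFAULT_BLOCK_SIZE,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
    tau: float = DEFAULT_TAU,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> dict[str, ChimeraReport]:
    """Switch-profile chimera screen over every scaffold in a table."""
    reports = {}
    for sid in table.scaffold_ids():
        profile = compute_switch_profile(table, sid, block_size, majority_threshold)
        reports[sid] = call_chimeras(profile, tau, min_support)
    return reports


def split_scaffold(
    scaffold_id: str,
    length: int,
    calls: list[ChimeraCall],
    markers: pd.DataFrame | None = None,
    sequence: str | None = None,
) -> list[dict]:
    """Partition a scaffold at the midpoints of its breakpoint intervals.

    Returns one record per sub-scaffold with keys ``new_id``, ``start``,
    ``end``, plus remapped ``markers`` (positions shifted to sub-scaffold
    coordinates) and the corresponding ``sequence`` slice when provided.
    With no calls the single original record is returned unchanged (suffix
    ``_p1`` is only applied to genuine splits).
    """
    if not calls:
        rec = {"new_id": scaffold_id, "start": 0, "end": length}
        if markers is not None:
            rec["markers"] = markers.copy()
        if sequence is not None:
            rec["sequence"] = sequence
        return [rec]
    mids = sorted((c.breakpoint_lo + c.breakpoint_hi) // 2 for c in calls)
    if len(set(mids)) != len(mids):
        raise ValueError(f"{scaffold_id}: duplicate breakpoints")
    for c in calls:
        if not (0 <= c.breakpoint_lo < c.breakpoint_hi <= length):
            raise ValueError(
                f"{scaffold_id}: breakpoint interval "
                f"[{c.breakpoint_lo},{c.breakpoint_hi}) outside [0,{length})"
            )
    if mids[0] <= 0 or mids[-1] >= length:
        raise ValueError(f"{scaffold_id}: breakpoint midpoint on scaffold edge")
    edges = [0] + mids + [length]
    records = []
    for k in range(len(edges) - 1):
        start, end = edges[k], edges[k + 1]
        rec = {"new_id": f"{scaffold_id}_p{k + 1}", "start": start, "end": end}
        if markers is not None:
            sub = markers[(markers["pos_bp"] >= start) & (markers["pos_bp"] < end)].copy()
            sub["pos_bp"] = sub["pos_bp"] - start
            sub["scaffold_id"] = rec["new_id"]
            rec["markers"] = sub
        if sequence is not None:
            rec["sequence"] = sequence[start:end]
        records.append(rec)
    return records


def apply_chimera_splits(
    table: MarkerTable,
    reports: Mapping[str, ChimeraReport],
    lengths: Mapping[str, int],
    sequences: dict[str, str] | None = None,
) -> tuple[MarkerTable, pd.DataFrame, dict[str, int], dict[str, str] | None]:
    """Split every chimera-called scaffold across a whole marker table.

    Returns the rewritten table, a split map (old_id, new_id, start, end),
    updated scaffold lengths and (optionally) updated sequences.  Marker
    count and total length are conserved exactly.
    """
    meta_parts = []
    call_parts = []
    map_rows = []
    new_lengths: dict[str, int] = {}
    new_seqs: dict[str, str] | None = {} if sequences is not None else None
    for sid in table.scaffold_ids():
        rows = table.scaffold_rows(sid)
        markers = table.meta.iloc[rows].reset_index(drop=True)
        markers["_row"] = rows
        report = reports.get(sid)
        calls = report.calls if report is not None else []
        records = split_scaffold(
            sid,
            int(lengths[sid]),
            calls,
            markers,
            sequences.get(sid) if sequences is not None else None,
        )
        for rec in records:
            map_rows.append((sid, rec["new_id"], rec["start"], rec["end"]))
            new_lengths[rec["new_id"]] = rec["end"] - rec["start"]
            if new_seqs is not None:
                new_seqs[rec["new_id"]] = rec["sequence"]
            sub = rec["markers"]
            meta_parts.append(sub[["marker_id", "scaffold_id", "pos_bp"]])
            call_parts.append(table.calls[sub["_row"].to_numpy()])
    new_table = MarkerTable(
        pd.concat(meta_parts, ignore_index=True),
        np.concatenate(call_parts, axis=0),
        list(table.ril_ids),
    )
    split_map = pd.DataFrame(map_rows, columns=["old_id", "new_id", "start", "end"])
    return new_table, split_map, new_lengths, new_seqs


def switch_profile_frame(profiles: Iterable[SwitchProfile]) -> pd.DataFrame:
    """Flatten switch profiles to a tidy frame for TSV output."""
    rows = []
    for p in profiles:
        for j in p.junctions:
            rows.append(
                (
                    p.scaffold_id,
                    j.left_bp,
                    j.right_bp,
                    j.n_switching,
                    j.n_informative,
                    round(j.switch_fraction, 6) if j.n_informative else float("nan"),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold_id",
            "left_bp",
            "right_bp",
            "n_switching",
            "n_informative",
            "switch_fraction",
        ],
    )


def chimera_report_frame(reports: Mapping[str, ChimeraReport]) -> pd.DataFrame:
    rows = []
    for sid, rep in reports.items():
        if rep.calls:
            for c in rep.calls:
                rows.append(
                    (
                        sid,
                        rep.verdict,
                        c.breakpoint_lo,
                        c.breakpoint_hi,
                        round(c.switch_fraction, 6),
                        c.n_informative,
                    )
                )
        else:
            rows.append((sid, rep.verdict, -1, -1, float("nan"), 0))
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold_id",
            "verdict",
            "breakpoint_lo",
            "breakpoint_hi",
            "switch_fraction",
            "n_informative",
        ],
    )
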
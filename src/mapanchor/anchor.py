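"""Superscaffold placement, orientation and pseudomolecule construction.

A superscaffold (an ordered, stranded chain of scaffolds from long-range
scaffolding) is placed into the genetic map by the bins of its first and
last mapped component scaffolds; components conflicting in linkage group or
bin monotonicity flag a misassembly; terminal bins that differ orient the
superscaffold (crossovers within it resolve its direction), while
superscaffolds confined to a single bin cannot be oriented.  The per-group
order is refined by minimizing double recombinants (X-Y-X genotype patterns
across consecutive units, which true meiosis makes rare), and chromosomal
pseudomolecules are emitted as FASTA plus AGP with fixed N spacers between
superscaffolds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import P1, P2, MISSING
from .linkmap import BinMap, count_double_recombinants_matrix
from .seqio import AGPRow, reverse_complement
from .simpop import Component, SuperscaffoldLayout

__all__ = [
    "Placement",
    "place_superscaffold",
    "flag_misassembly",
    "orient_superscaffold",
    "count_double_recombinants",
    "refine_order",
    "initial_order",
    "superscaffold_sequence",
    "build_pseudomolecules",
    "find_telomere_arrays",
]

DEFAULT_SPACER_BP = 10_000
DEFAULT_MISASSEMBLY_TOLERANCE = 2
DEFAULT_REFINE_WINDOW = 5


@dataclass
class Placement:
    superscaffold_id: str
    lg: int | None
    first_bin: int | None
    last_bin: int | None
    span_cm: float
    orientation: str  # forward | reverse | unoriented
    status: str  # placed | unplaced | misassembled
    n_mapped: int = 0

    @property
    def midpoint_bin(self) -> float:
        if self.first_bin is None:
            return float("inf")
        return (self.first_bin + self.last_bin) / 2.0


def _mapped_components(
    layout: SuperscaffoldLayout, bin_map: BinMap
) -> list[tuple[Component, int, int]]:
    out = []
    for comp in layout.components:
        hit = bin_map.scaffold_to.get(comp.scaffold_id)
        if hit is not None:
            out.append((comp, hit[0], hit[1]))
    return out


def place_superscaffold(layout: SuperscaffoldLayout, bin_map: BinMap) -> Placement:
    """Genetic placement from the first and last mapped components.

    The linkage group is the majority LG over mapped components; the genetic
    span runs from the bin of the first to the bin of the last component
    mapped to that LG.  Superscaffolds confined to one bin (or with a single
    mapped component) cannot be oriented.
    """
    mapped = _mapped_components(layout, bin_map)
    if not mapped:
        return Placement(
            layout.superscaffold_id, None, None, None, 0.0, "unoriented", "unplaced"
        )
    lg_counts: dict[int, int] = {}
    for _, lg, _ in mapped:
        lg_counts[lg] = lg_counts.get(lg, 0) + 1
    lg = min(lg_counts, key=lambda g: (-lg_counts[g], g))
    in_lg = [(c, b) for c, g, b in mapped if g == lg]
    first_bin = in_lg[0][1]
    last_bin = in_lg[-1][1]
    span = abs(bin_map.bin_cm(lg, last_bin) - bin_map.bin_cm(lg, first_bin))
    placement = Placement(
        layout.superscaffold_id,
        lg,
        first_bin,
        last_bin,
        span,
        "unoriented",
        "placed",
        n_mapped=len(mapped),
    )
    placement.orientation = orient_superscaffold(placement, n_mapped_in_lg=len(in_lg))
    return placement


def orient_superscaffold(placement: Placement, n_mapped_in_lg: int | None = None) -> str:
    """Orientation from terminal bin indices: crossovers within the
    superscaffold separate its ends into different bins and fix its
    direction; equal terminal bins or a single mapped component leave it
    unoriented."""
    if placement.status != "placed" or placement.first_bin is None:
        return "unoriented"
    if n_mapped_in_lg is not None and n_mapped_in_lg < 2:
        return "unoriented"
    if placement.first_bin < placement.last_bin:
        return "forward"
    if placement.first_bin > placement.last_bin:
        return "reverse"
    return "unoriented"


def flag_misassembly(
    layout: SuperscaffoldLayout,
    bin_map: BinMap,
    tolerance: int = DEFAULT_MISASSEMBLY_TOLERANCE,
) -> tuple[bool, int | None]:
    """Misassembly verdict plus a proposed split component index.

    A superscaffold is misassembled when its mapped components span more
    than one linkage group, or when the within-LG bin sequence is
    non-monotonic beyond ``tolerance`` out-of-order components (guarding
    against bin-assignment noise).  The proposed split is the junction
    between the conflicting runs: the returned index k means "split between
    components k-1 and k" (layout component indexing).
    """
    mapped = _mapped_components(layout, bin_map)
    if len(mapped) < 2:
        return False, None
    lgs = [lg for _, lg, _ in mapped]
    if len(set(lgs)) > 1:
        # split at the first LG change, located at the component junction
        for k in range(1, len(mapped)):
            if lgs[k] != lgs[k - 1]:
                split_at = layout.components.index(mapped[k][0])
                return True, split_at
    bins = [b for _, _, b in mapped]
    violations = len(bins) - max(
        _longest_monotone(bins, ascending=True),
        _longest_monotone(bins, ascending=False),
    )
    if violations > tolerance:
        jumps = [abs(bins[k] - bins[k - 1]) for k in range(1, len(bins))]
        k = int(np.argmax(jumps)) + 1
        split_at = layout.components.index(mapped[k][0])
        return True, split_at
    return False, None


def _longest_monotone(seq: Sequence[int], ascending: bool) -> int:
    """Longest non-decreasing (or non-increasing) subsequence, O(n^2)."""
    n = len(seq)
    if n == 0:
        return 0
    vals = seq if ascending else [-x for x in seq]
    best = [1] * n
    for i in range(n):
        for j in range(i):
            if vals[j] <= vals[i]:
                best[i] = max(best[i], best[j] + 1)
    return max(best)


def count_double_recombinants(
    order: Sequence[str], vectors: Mapping[str, np.ndarray]
) -> int:
    """Double recombinants (X-Y-X patterns) over an ordered list of units.

    Per RIL, the unit calls are condensed to their homozygous (P1/P2)
    entries in order -- HET and MISSING are skipped, so each triple is
    defined on the nearest informative neighbours -- and every internal
    element differing from both neighbours counts once.
    """
    if len(order) < 3:
        return 0
    calls = np.stack([np.asarray(vectors[u]) for u in order])  # (U, R)
    return count_double_recombinants_matrix(calls)


def initial_order(placements: Sequence[Placement]) -> list[str]:
    """Initial within-LG superscaffold order from genetic placement.

    Sorted by midpoint bin, ties by first bin, then descending mapped
    component count, then id -- a reproducible refinement of "order by the
    genetic position of the first and last scaffolds".
    """
    placed = [p for p in placements if p.status == "placed"]
    placed.sort(
        key=lambda p: (
            p.midpoint_bin,
            p.first_bin,
            -p.n_mapped,
            p.superscaffold_id,
        )
    )
    return [p.superscaffold_id for p in placed]


def refine_order(
    order: Sequence[str],
    vectors: Mapping[str, np.ndarray],
    window: int = DEFAULT_REFINE_WINDOW,
) -> list[str]:
    """Hill-climb on the double-recombinant count.

    Adjacent transpositions and single-unit reinsertions within a sliding
    window are tried in a deterministic scan; only strictly improving moves
    are accepted; terminates at a local optimum, so the objective never
    increases.
    """
    cur = list(order)
    if len(cur) < 3:
        return cur
    best = count_double_recombinants(cur, vectors)
    improved = True
    while improved:
        improved = False
        for i in range(len(cur) - 1):
            cand = cur.copy()
            cand[i], cand[i + 1] = cand[i + 1], cand[i]
            c = count_double_recombinants(cand, vectors)
            if c < best:
                cur, best = cand, c
                improved = True
        for i in range(len(cur)):
            for j in range(max(0, i - window), min(len(cur), i + window + 1)):
                if j == i:
                    continue
                cand = cur.copy()
                unit = cand.pop(i)
                cand.insert(j, unit)
                c = count_double_recombinants(cand, vectors)
                if c < best:
                    cur, best = cand, c
                    improved = True
    return cur


def superscaffold_sequence(
    layout: SuperscaffoldLayout, scaffold_seqs: Mapping[str, str]
) -> str:
    """Assemble a superscaffold's sequence from its components and gaps."""
    parts = []
    for comp in layout.components:
        try:
            seq = scaffold_seqs[comp.scaffold_id]
        except KeyError:
            raise KeyError(
                f"no sequence for component scaffold {comp.scaffold_id!r} "
                f"of {layout.superscaffold_id}"
            ) from None
        if len(seq) != comp.end - comp.start:
            raise ValueError(
                f"{comp.scaffold_id}: sequence length {len(seq)} != layout span "
                f"{comp.end - comp.start}"
            )
        parts.append(reverse_complement(seq) if comp.strand == "-" else seq)
        if comp.gap_after:
            parts.append("N" * comp.gap_after)
    return "".join(parts)


def _oriented_components(
    layout: SuperscaffoldLayout, reverse: bool
) -> list[tuple[str, int, str, int]]:
    """(scaffold_id, length, strand, gap_after) in emission order."""
    comps = layout.components
    if not reverse:
        return [(c.scaffold_id, c.end - c.start, c.strand, c.gap_after) for c in comps]
    flipped = {"+": "-", "-": "+", "?": "?"}
    out = []
    for k in range(len(comps) - 1, -1, -1):
        c = comps[k]
        gap = comps[k - 1].gap_after if k > 0 else 0
        out.append((c.scaffold_id, c.end - c.start, flipped[c.strand], gap))
    return out


def build_pseudomolecules(
    lg_orders: Mapping[int, Sequence[str]],
    placements: Mapping[str, Placement],
    layouts: Mapping[str, SuperscaffoldLayout],
    scaffold_seqs: Mapping[str, str],
    spacer_bp: int = DEFAULT_SPACER_BP,
    object_prefix: str = "LG",
) -> tuple[dict[str, str], list[AGPRow]]:
    """Concatenate ordered superscaffolds into pseudomolecules.

    Superscaffolds placed in reverse orientation are reverse-complemented;
    unoriented ones are kept as input.  Consecutive superscaffolds are
    separated by ``spacer_bp`` N's, written as AGP gap rows (gap_type
    scaffold, linkage yes, evidence map); every component scaffold gets a W
    row, so AGP plus component sequences reconstruct the FASTA exactly.
    """
    fasta: dict[str, str] = {}
    agp_rows: list[AGPRow] = []
    for lg in sorted(lg_orders):
        obj = f"{object_prefix}{lg}"
        pos = 0  # 0-based running offset
        part = 1
        pieces: list[str] = []
        order = list(lg_orders[lg])
        for idx, ss_id in enumerate(order):
            layout = layouts[ss_id]
            placement = placements[ss_id]
            rev = placement.orientation == "reverse"
            seq = superscaffold_sequence(layout, scaffold_seqs)
            if rev:
                seq = reverse_complement(seq)
            for sid, length, strand, gap in _oriented_components(layout, rev):
                agp_rows.append(
                    AGPRow(
                        obj,
                        pos + 1,
                        pos + length,
                        part,
                        "W",
                        component_id=sid,
                        component_beg=1,
                        component_end=length,
                        orientation=strand,
                    )
                )
                pos += length
                part += 1
                if gap:
                    agp_rows.append(
                        AGPRow(
                            obj,
                            pos + 1,
                            pos + gap,
                            part,
                            "N",
                            gap_length=gap,
                            gap_type="scaffold",
                            linkage="yes",
                            evidence="paired-ends",
                        )
                    )
                    pos += gap
                    part += 1
            pieces.append(seq)
            if idx < len(order) - 1 and spacer_bp:
                agp_rows.append(
                    AGPRow(
                        obj,
                        pos + 1,
                        pos + spacer_bp,
                        part,
                        "N",
                        gap_length=spacer_bp,
                        gap_type="scaffold",
                        linkage="yes",
                        evidence="map",
                    )
                )
                pos += spacer_bp
                part += 1
                pieces.append("N" * spacer_bp)
        if pieces:
            fasta[obj] = "".join(pieces)
    return fasta, agp_rows


@dataclass
class TelomereHit:
    object: str
    end: str  # "5prime" or "3prime"
    motif: str
    copies: int


def find_telomere_arrays(
    seqs: Mapping[str, str],
    motif: str = "TTTAGGG",
    min_copies: int = 10,
    window_bp: int = 10_000,
) -> list[TelomereHit]:
    """Tandem telomere-motif arrays near sequence ends.

    Searches the first and last ``window_bp`` of each sequence for tandem
    runs of the motif or its reverse complement (plant telomeres read
    TTTAGGG on one strand and CCCTAAA on the other) and reports runs of at
    least ``min_copies``; the maximal run per end and motif variant is kept.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    variants = {motif.upper(), reverse_complement(motif.upper())}
    hits = []
    for name, seq in seqs.items():
        seq = seq.upper()
        windows = (("5prime", seq[:window_bp]), ("3prime", seq[-window_bp:]))
        for end, chunk in windows:
            for var in sorted(variants):
                runs = [
                    len(m.group(0)) // len(var)
                    for m in re.finditer(f"(?:{var})+", chunk)
                ]
                best = max(runs, default=0)
                if best >= min_copies:
                    hits.append(TelomereHit(name, end, var, best))
    return hits


def placement_frame(placements: Mapping[str, Placement]) -> pd.DataFrame:
    rows = [
        (
            p.superscaffold_id,
            p.lg if p.lg is not None else 0,
            p.first_bin if p.first_bin is not None else -1,
            p.last_bin if p.last_bin is not None else -1,
            round(p.span_cm, 4),
            p.orientation,
            p.status,
            p.n_mapped,
        )
        for p in placements.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "superscaffold_id",
            "LG",
            "first_bin",
            "last_bin",
            "span_cM",
            "orientation",
            "status",
            "n_mapped",
        ],
    ).sort_values("superscaffold_id").reset_index(drop=True)
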
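"""Two-point linkage analysis, linkage grouping, cosegregation binning.

The observed recombinant fraction R between two loci in a selfed RIL
population overestimates the per-meiosis fraction r because recombinants
accumulate over the selfing generations; at fixation R = 2r/(1+2r)
(Haldane-Waddington), inverted here as r = R/(2(1-R)).  Map distances use
the Haldane function d = -50 ln(1-2r) cM, consistent with the
no-interference crossover model of the simulator.

Scaffolds are clustered into linkage groups by single-linkage transitive
closure over pairs with high LOD and low recombinant fraction, assigned to
cosegregation bins (identical segregation up to missing data), and bins are
ordered by seriation (nearest-neighbour chain refined by 2-opt on the sum of
adjacent corrected recombination fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.special import xlogy
from scipy.stats import spearmanr, rankdata

from .genotypes import P1, P2, MISSING, HaplotypeMatrix, majority_vector

__all__ = [
    "LinkageEstimate",
    "GeneticBin",
    "BinMap",
    "pairwise_recombinant_fraction",
    "ril_correct",
    "haldane_cm",
    "kosambi_cm",
    "lod_two_point",
    "pairwise_matrices",
    "cluster_linkage_groups",
    "phase_normalize",
    "assign_bins",
    "order_bins",
    "build_binmap",
    "compare_orders",
]

DEFAULT_LOD_MIN = 6.0
DEFAULT_R_MAX = 0.35
DEFAULT_MIN_LEN_BP = 1000
DEFAULT_MIN_INFORMATIVE = 20
# cap on the corrected fraction when accumulating cM along a bin order, so a
# noisy ~0.5 estimate between adjacent bins cannot inject an infinite gap
ADJACENT_R_CAP = 0.45


@dataclass
class LinkageEstimate:
    scaffold_a: str
    scaffold_b: str
    r_hat: float  # observed recombinant fraction
    n_informative: int
    r_map: float  # Haldane-Waddington corrected
    lod: float


def _signed(calls: np.ndarray) -> np.ndarray:
    """P1 -> +1, P2 -> -1, HET/MISSING -> 0."""
    return np.where(calls == P1, 1.0, np.where(calls == P2, -1.0, 0.0))


def pairwise_recombinant_fraction(
    vec_a: np.ndarray, vec_b: np.ndarray
) -> tuple[float, int]:
    """Observed recombinant fraction over lines homozygous at both loci.

    Returns (R_hat, n_informative); R_hat is NaN when no line is informative.
    """
    vec_a = np.asarray(vec_a)
    vec_b = np.asarray(vec_b)
    if vec_a.shape != vec_b.shape:
        raise ValueError("haplotype vectors are over different RIL panels")
    both = ((vec_a == P1) | (vec_a == P2)) & ((vec_b == P1) | (vec_b == P2))
    n = int(both.sum())
    if n == 0:
        return float("nan"), 0
    discordant = int((vec_a[both] != vec_b[both]).sum())
    return discordant / n, n


def ril_correct(r_hat: float | np.ndarray) -> float | np.ndarray:
    """Invert the RIL map expansion R = 2r/(1+2r): r = R/(2(1-R)), capped at 0.5."""
    r_hat = np.asarray(r_hat, dtype=float)
    if np.any(r_hat >= 1.0) or np.any(r_hat < 0.0):
        raise ValueError("R_hat must be in [0, 1)")
    r = np.minimum(r_hat / (2.0 * (1.0 - r_hat)), 0.5)
    return float(r) if r.ndim == 0 else r


def haldane_cm(r_map: float | np.ndarray) -> float | np.ndarray:
    """Haldane map distance d = -50 ln(1-2r) cM; infinite at r >= 0.5."""
    r = np.asarray(r_map, dtype=float)
    if np.any(r < 0.0):
        raise ValueError("r_map must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(r < 0.5, -50.0 * np.log1p(-2.0 * np.minimum(r, 0.5 - 1e-15)), np.inf)
    d = np.where(r >= 0.5, np.inf, d)
    return float(d) if d.ndim == 0 else d


def kosambi_cm(r_map: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM (optional alternative)."""
    r = np.asarray(r_map, dtype=float)
    if np.any(r < 0.0):
        raise ValueError("r_map must be >= 0")
    with np.errstate(divide="ignore"):
        d = np.where(r < 0.5, 25.0 * (np.log1p(2 * r) - np.log1p(-2 * np.minimum(r, 0.5 - 1e-15))), np.inf)
    return float(d) if d.ndim == 0 else d


def lod_two_point(r_hat: float | np.ndarray, n_informative: int | np.ndarray):
    """Two-point LOD against free recombination (R = 1/2).

    LOD = n [R log10 R + (1-R) log10(1-R)] + n log10 2, with 0 log 0 := 0.
    Zero at R = 1/2, n log10 2 at complete cosegregation.
    """
    r = np.asarray(r_hat, dtype=float)
    n = np.asarray(n_informative, dtype=float)
    ent = xlogy(r, r) + xlogy(1.0 - r, 1.0 - r)
    lod = n * (ent / np.log(10.0) + np.log10(2.0))
    return float(lod) if lod.ndim == 0 else lod


def pairwise_matrices(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (R_hat, n_informative) for a stack of haplotype vectors.

    R is NaN where no line is informative for a pair.
    """
    v = _signed(calls)
    a = np.abs(v)
    n = a @ a.T
    dot = v @ v.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (n - dot) / (2.0 * n)
    r[n == 0] = np.nan
    return r, n


def estimate_pair(
    hap: HaplotypeMatrix, scaffold_a: str, scaffold_b: str
) -> LinkageEstimate:
    r_hat, n = pairwise_recombinant_fraction(
        hap.vector(scaffold_a), hap.vector(scaffold_b)
    )
    if np.isnan(r_hat):
        return LinkageEstimate(scaffold_a, scaffold_b, r_hat, 0, float("nan"), 0.0)
    folded = min(r_hat, 1.0 - r_hat)
    return LinkageEstimate(
        scaffold_a,
        scaffold_b,
        r_hat,
        n,
        float(ril_correct(folded)),
        float(lod_two_point(folded, n)),
    )


@dataclass
class LinkagePartition:
    """Linkage groups (numbered by descending size) plus unplaced scaffolds."""

    groups: dict[int, list[str]]
    unplaced: list[str]

    def lg_of(self) -> dict[str, int]:
        return {s: lg for lg, members in self.groups.items() for s in members}


def cluster_linkage_groups(
    hap: HaplotypeMatrix,
    lengths: Mapping[str, int] | None = None,
    lod_min: float = DEFAULT_LOD_MIN,
    r_max: float = DEFAULT_R_MAX,
    min_len_bp: int = DEFAULT_MIN_LEN_BP,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> LinkagePartition:
    """Single-linkage transitive closure over significant linkage edges.

    An edge joins two scaffolds when LOD >= ``lod_min``, the phase-folded
    recombinant fraction min(R, 1-R) <= ``r_max`` and at least
    ``min_informative`` lines back the estimate (sparse pairs never
    cluster).  Scaffolds shorter than ``min_len_bp`` are excluded up front;
    connected components of >= 2 members become linkage groups, everything
    else is unplaced.
    """
    keep = list(hap.scaffold_ids)
    excluded: list[str] = []
    if lengths is not None:
        excluded = [s for s in keep if lengths.get(s, 0) < min_len_bp]
        keep = [s for s in keep if lengths.get(s, 0) >= min_len_bp]
    if not keep:
        return LinkagePartition({}, excluded)
    sub = hap.subset(keep)
    r, n = pairwise_matrices(sub.calls)
    folded = np.minimum(r, 1.0 - r)
    with np.errstate(invalid="ignore"):
        lod = lod_two_point(np.where(np.isnan(folded), 0.5, folded), n)
    adj = (
        (lod >= lod_min)
        & (np.nan_to_num(folded, nan=1.0) <= r_max)
        & (n >= min_informative)
    )
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, list[str]] = {}
    for sid, lab in zip(keep, labels):
        comps.setdefault(int(lab), []).append(sid)
    multi = sorted(
        (members for members in comps.values() if len(members) >= 2),
        key=lambda m: (-len(m), min(m)),
    )
    groups = {i + 1: sorted(members) for i, members in enumerate(multi)}
    singletons = [m[0] for m in comps.values() if len(m) == 1]
    return LinkagePartition(groups, sorted(singletons + excluded))


def phase_normalize(hap: HaplotypeMatrix, flip: bool = True) -> tuple[HaplotypeMatrix, dict[str, bool]]:
    """Bring all vectors of one linkage group to a consistent phase.

    Phase is propagated along a minimum spanning tree of the folded
    recombinant-fraction distances, rooted at the lexicographically smallest
    scaffold id: each scaffold is flipped when it is discordant with its
    (already phased) tree parent in more than half of the informative lines.
    MST edges connect tightly linked scaffolds, so each decision is crisp.
    In a parent-coded design the input phase is already consistent and this
    is a no-op safeguard.
    """
    n_sc = len(hap.scaffold_ids)
    flips = {s: False for s in hap.scaffold_ids}
    if n_sc <= 1 or not flip:
        return hap, flips
    r, n = pairwise_matrices(hap.calls)
    folded = np.minimum(r, 1.0 - r)
    w = np.nan_to_num(folded, nan=0.5) + 1e-6  # avoid zero weights in MST
    np.fill_diagonal(w, 0.0)
    mst = minimum_spanning_tree(csr_matrix(w))
    und = mst + mst.T
    root = min(range(n_sc), key=lambda i: hap.scaffold_ids[i])
    order = [root]
    seen = {root}
    parent = {root: None}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(und.getrow(u).indices.tolist()):
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    order.append(v)
                    nxt.append(v)
        frontier = nxt
    calls = hap.calls.copy()
    flipped = np.zeros(n_sc, dtype=bool)
    for v in order[1:]:
        u = parent[v]
        r_uv = r[u, v]
        if np.isnan(r_uv):
            continue
        discordant_frac = 1.0 - r_uv if flipped[u] else r_uv
        if discordant_frac > 0.5:
            flipped[v] = True
    for i in np.flatnonzero(flipped):
        hom = calls[i] <= P2
        calls[i, hom] = 1 - calls[i, hom]
        flips[hap.scaffold_ids[i]] = True
    out = HaplotypeMatrix(
        list(hap.scaffold_ids), calls, hap.support.copy(),
        hap.n_informative.copy(), list(hap.ril_ids),
    )
    return out, flips


@dataclass
class GeneticBin:
    """A set of cosegregating scaffolds with one representative vector."""

    bin_id: int
    members: list[str]
    representative: np.ndarray
    cm: float | None = None


def _discordant(a: np.ndarray, b: np.ndarray) -> int:
    both = (a <= P2) & (b <= P2)
    return int((a[both] != b[both]).sum())


def assign_bins(
    hap: HaplotypeMatrix, max_mismatch: int = 0
) -> list[GeneticBin]:
    """Greedy agglomeration of one LG's (phase-normalized) vectors.

    Scaffolds are scanned in id order; a scaffold joins the first existing
    bin whose representative it matches with <= ``max_mismatch`` discordant
    informative lines (missing data tolerated), else founds a new bin.
    Representatives are element-wise majorities over members.
    """
    bins: list[GeneticBin] = []
    member_calls: list[list[np.ndarray]] = []
    for sid in sorted(hap.scaffold_ids):
        vec = hap.vector(sid)
        placed = False
        for b, stack in zip(bins, member_calls):
            if _discordant(b.representative, vec) <= max_mismatch:
                b.members.append(sid)
                stack.append(vec)
                b.representative = majority_vector(np.stack(stack))
                placed = True
                break
        if not placed:
            bins.append(GeneticBin(len(bins), [sid], vec.copy()))
            member_calls.append([vec])
    return bins


def _adjacent_sum(order: list[int], dist: np.ndarray) -> float:
    return float(sum(dist[order[k], order[k + 1]] for k in range(len(order) - 1)))


def count_double_recombinants_matrix(calls: np.ndarray) -> int:
    """Double recombinants over ordered unit rows of a call matrix.

    Per RIL the unit calls are condensed to their homozygous entries in row
    order (HET/MISSING skipped, so triples use the nearest informative
    neighbours); every internal element differing from both neighbours
    counts once.  True double crossovers between nearby units are rare, so
    the count penalizes wrong unit order.
    """
    total = 0
    for ril in range(calls.shape[1]):
        col = calls[:, ril]
        hom = col[col <= P2]
        if len(hom) < 3:
            continue
        mid = hom[1:-1]
        total += int(((mid != hom[:-2]) & (mid != hom[2:])).sum())
    return total


def refine_order_by_double_recombinants(
    order: list[int], calls: np.ndarray, window: int = 5
) -> list[int]:
    """Hill-climb on the double-recombinant count of an index order.

    Adjacent transpositions and single-unit reinsertions within ``window``
    positions are scanned deterministically; only strictly improving moves
    are accepted, so the objective never increases; terminates at a local
    optimum.
    """
    cur = list(order)
    if len(cur) < 3:
        return cur
    best = count_double_recombinants_matrix(calls[cur])
    improved = True
    while improved:
        improved = False
        for i in range(len(cur) - 1):
            cand = cur.copy()
            cand[i], cand[i + 1] = cand[i + 1], cand[i]
            c = count_double_recombinants_matrix(calls[cand])
            if c < best:
                cur, best = cand, c
                improved = True
        for i in range(len(cur)):
            for j in range(max(0, i - window), min(len(cur), i + window + 1)):
                if j == i:
                    continue
                cand = cur.copy()
                cand.insert(j, cand.pop(i))
                c = count_double_recombinants_matrix(calls[cand])
                if c < best:
                    cur, best = cand, c
                    improved = True
    return cur


TERMINAL_NEIGHBOUR_R = 0.25


def order_bins(bins: list[GeneticBin]) -> list[GeneticBin]:
    """Seriation of bins: nearest-neighbour chain refined by 2-opt.

    Distant pairs all sit near R = 1/2, so global comparisons cannot pick
    the map ends; instead the chain is seeded at a terminal bin, identified
    as the bin with the fewest neighbours at R below
    ``TERMINAL_NEIGHBOUR_R`` (linkage is one-sided at a chromosome end).
    The chain grows greedily by smallest corrected fraction and 2-opt
    segment reversals are applied until the sum of adjacent distances stops
    decreasing (first-improvement, deterministic scan; ties broken by bin
    id).  cM positions are the cumulative Haldane distances over adjacent
    corrected fractions, origin 0 at the first bin.  The returned order is
    flipped, if needed, so that the bin containing the lexicographically
    smallest scaffold id among the two terminal bins comes first.
    """
    if not bins:
        return []
    if len(bins) == 1:
        out = [bins[0]]
        out[0].cm = 0.0
        return out
    reps = np.stack([b.representative for b in bins])
    r, n = pairwise_matrices(reps)
    r_eff = np.where(np.isnan(r), 0.5, np.minimum(r, 0.99))
    # seriation objective: the uncapped transform R/(2(1-R)) stays monotone
    # beyond R = 0.5, so misjoining distant ends costs strictly more than
    # joining near ends and 2-opt cannot plateau with a reversed arm
    dist = r_eff / (2.0 * (1.0 - r_eff))
    np.fill_diagonal(dist, 0.0)
    # seed: a terminal bin, which has the fewest close linkage neighbours
    rr = np.where(np.isnan(r), 0.5, r)
    np.fill_diagonal(rr, 1.0)
    n_close = (rr < TERMINAL_NEIGHBOUR_R).sum(axis=1)
    start = int(np.argmin(n_close))
    order = [start]
    remaining = set(range(len(bins))) - {start}
    while remaining:
        cur = order[-1]
        nxt = min(remaining, key=lambda k: (dist[cur, k], k))
        order.append(nxt)
        remaining.remove(nxt)
    # 2-opt segment reversals plus or-opt single-bin relocations: the greedy
    # chain can strand a few bins at its tail, which reversals alone cannot
    # repair
    improved = True
    while improved:
        improved = False
        best = _adjacent_sum(order, dist)
        for a in range(len(order) - 1):
            for b in range(a + 1, len(order)):
                cand = order[:a] + order[a : b + 1][::-1] + order[b + 1 :]
                s = _adjacent_sum(cand, dist)
                if s < best - 1e-12:
                    order = cand
                    best = s
                    improved = True
        for seg_len in (1, 2, 3):
            for i in range(len(order) - seg_len + 1):
                accepted = False
                seg = order[i : i + seg_len]
                rest = order[:i] + order[i + seg_len :]
                for j in range(len(rest) + 1):
                    for piece in (seg, seg[::-1]) if seg_len > 1 else (seg,):
                        cand = rest[:j] + piece + rest[j:]
                        if cand == order:
                            continue
                        s = _adjacent_sum(cand, dist)
                        if s < best - 1e-12:
                            order = cand
                            best = s
                            improved = True
                            accepted = True
                            break
                    if accepted:
                        break
        # restart scans after any accepted pass
    first_min = min(bins[order[0]].members)
    last_min = min(bins[order[-1]].members)
    if last_min < first_min:
        order = order[::-1]
    out = []
    cm = 0.0
    prev = None
    for rank, k in enumerate(order):
        b = bins[k]
        if prev is not None:
            r_adj = min(float(dist[prev, k]), ADJACENT_R_CAP)
            cm += float(haldane_cm(r_adj))
        b.bin_id = rank
        b.cm = cm
        out.append(b)
        prev = k
    return out


@dataclass
class BinMap:
    """Ordered genetic bins per linkage group plus scaffold assignments."""

    lgs: dict[int, list[GeneticBin]]
    unplaced: list[str] = field(default_factory=list)
    ril_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scaffold_to: dict[str, tuple[int, int]] = {}
        for lg, bins in self.lgs.items():
            for b in bins:
                for sid in b.members:
                    self.scaffold_to[sid] = (lg, b.bin_id)

    def bin_cm(self, lg: int, bin_index: int) -> float:
        return float(self.lgs[lg][bin_index].cm)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lg, bins in sorted(self.lgs.items()):
            for b in bins:
                for sid in sorted(b.members):
                    rows.append((sid, lg, b.bin_id, round(float(b.cm), 4)))
        for sid in sorted(self.unplaced):
            rows.append((sid, 0, -1, float("nan")))
        return pd.DataFrame(rows, columns=["scaffold_id", "LG", "bin_index", "bin_cM"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinMap":
        """Rebuild order/assignment (without representative vectors) from TSV."""
        lgs: dict[int, list[GeneticBin]] = {}
        unplaced = []
        for (lg, bin_index), grp in df[df["LG"] > 0].groupby(["LG", "bin_index"]):
            lgs.setdefault(int(lg), []).append(
                GeneticBin(
                    int(bin_index),
                    sorted(grp["scaffold_id"]),
                    np.empty(0, dtype=np.int8),
                    float(grp["bin_cM"].iloc[0]),
                )
            )
        for bins in lgs.values():
            bins.sort(key=lambda b: b.bin_id)
        unplaced = sorted(df.loc[df["LG"] == 0, "scaffold_id"])
        return cls(lgs, unplaced)


def build_binmap(
    hap: HaplotypeMatrix,
    lengths: Mapping[str, int] | None = None,
    lod_min: float = DEFAULT_LOD_MIN,
    r_max: float = DEFAULT_R_MAX,
    min_len_bp: int = DEFAULT_MIN_LEN_BP,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    max_mismatch: int = 0,
) -> BinMap:
    """Cluster, phase, bin and order: the full map-construction stage."""
    partition = cluster_linkage_groups(
        hap, lengths, lod_min, r_max, min_len_bp, min_informative
    )
    lgs = {}
    for lg, members in partition.groups.items():
        sub, _ = phase_normalize(hap.subset(members))
        lgs[lg] = order_bins(assign_bins(sub, max_mismatch))
    return BinMap(lgs, partition.unplaced, list(hap.ril_ids))


def compare_orders(
    map_a: pd.DataFrame,
    map_b: pd.DataFrame,
    max_rank_deviation: int = 5,
) -> tuple[float, dict[int, float]]:
    """Colinearity of two maps sharing marker/scaffold ids.

    Linkage groups of the two maps are matched by maximal shared-id overlap
    (labels are arbitrary).  A shared id is inconsistent when its LG
    assignment differs under that matching or its within-LG rank deviates by
    more than ``max_rank_deviation`` positions after aligning orientation
    (|rho| is reported, as LG orientation is arbitrary).  Returns
    (inconsistent fraction, per-LG |Spearman rho|).
    """
    a = map_a[map_a["LG"] > 0].set_index("scaffold_id")
    b = map_b[map_b["LG"] > 0].set_index("scaffold_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("maps share no placed ids; not comparable")
    a = a.loc[shared]
    b = b.loc[shared]
    # greedy LG matching by overlap count
    overlap = (
        pd.crosstab(a["LG"], b["LG"]).stack().sort_values(ascending=False)
    )
    match: dict[int, int] = {}
    used_b: set[int] = set()
    for (lg_a, lg_b), cnt in overlap.items():
        if cnt == 0 or lg_a in match or lg_b in used_b:
            continue
        match[int(lg_a)] = int(lg_b)
        used_b.add(int(lg_b))
    inconsistent = 0
    rhos: dict[int, float] = {}
    for lg_a, grp in a.groupby("LG"):
        lg_b = match.get(int(lg_a))
        ids = grp.index
        b_lg = b.loc[ids, "LG"]
        wrong_lg = b_lg != lg_b
        inconsistent += int(wrong_lg.sum())
        ids_ok = ids[~wrong_lg]
        if len(ids_ok) < 2:
            continue
        ra = rankdata(a.loc[ids_ok, "bin_index"], method="average")
        rb = rankdata(b.loc[ids_ok, "bin_index"], method="average")
        rho = spearmanr(ra, rb).statistic
        if np.isnan(rho):
            rho = 1.0  # all in one bin on both maps: trivially colinear
        rhos[int(lg_a)] = abs(float(rho))
        if rho < 0:
            rb = len(rb) + 1 - rb
        inconsistent += int((np.abs(ra - rb) > max_rank_deviation).sum())
    return inconsistent / len(shared), rhos
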
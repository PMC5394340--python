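"""Synthetic RIL population and fragmented-assembly simulator.

Emulates the data behind genetic validation of a draft plant assembly: a
biparental cross selfed to an advanced filial generation (F7 by default),
crossovers drawn under a no-interference (Haldane) model, a genome fragmented
into scaffolds carrying sparse, error-prone SNP genotype calls, a fraction of
scaffolds replaced by chimeric misjoins, and scaffolds chained into
superscaffolds.  Complete ground truth is recorded so every downstream stage
of the validation pipeline can be checked against it.

All randomness flows through a single :class:`numpy.random.Generator` passed
explicitly; identical seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genotypes import P1, P2, HET, MISSING, MarkerTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "PRESETS",
    "expected_residual_het",
    "simulate_meiosis",
    "simulate_ril_population",
    "fragment_into_scaffolds",
    "plant_chimeras",
    "degrade_calls",
    "assemble_superscaffolds",
    "scaffold_sequences",
    "simulate",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cross and assembly.

    ``selfing_generations`` is the filial generation number t of an F_t
    population: t - 1 rounds of meiotic selfing follow the F1.
    """

    n_chromosomes: int = 9
    chrom_genetic_lengths: tuple[float, ...] = (110.0,) * 9  # cM
    chrom_physical_lengths: tuple[int, ...] = (25_000_000,) * 9  # bp
    n_rils: int = 99
    selfing_generations: int = 7
    scaffolds_per_chromosome: int = 40
    markers_per_scaffold: int = 10
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.25
    chimera_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "n_rils": self.n_rils,
            "scaffolds_per_chromosome": self.scaffolds_per_chromosome,
            "markers_per_scaffold": self.markers_per_scaffold,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.selfing_generations < 2:
            raise ValueError("selfing_generations must be >= 2 (F2 or later)")
        rates = {
            "genotype_error_rate": self.genotype_error_rate,
            "missing_rate": self.missing_rate,
            "chimera_fraction": self.chimera_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name, lengths in (
            ("chrom_genetic_lengths", self.chrom_genetic_lengths),
            ("chrom_physical_lengths", self.chrom_physical_lengths),
        ):
            if len(lengths) != self.n_chromosomes:
                raise ValueError(
                    f"{name} has length {len(lengths)}, expected {self.n_chromosomes}"
                )
            if any(v <= 0 for v in lengths):
                raise ValueError(f"{name} entries must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chrom_genetic_lengths"] = list(self.chrom_genetic_lengths)
        d["chrom_physical_lengths"] = list(self.chrom_physical_lengths)
        return d


#: Presets.  "lettuce-like" matches the study design this package emulates:
#: nine chromosomes, 99 F7 RILs, ~1x genotype sparsity, ~1% chimeric
#: scaffolds.  "toy" is a miniature with short chromosomes so that sequence
#: level stages (FASTA/AGP) run instantly.
PRESETS: dict[str, SimConfig] = {
    "lettuce-like": SimConfig(),
    "toy": SimConfig(
        n_chromosomes=3,
        chrom_genetic_lengths=(60.0,) * 3,
        chrom_physical_lengths=(600_000,) * 3,
        n_rils=66,
        scaffolds_per_chromosome=12,
        markers_per_scaffold=8,
        chimera_fraction=0.05,
    ),
}


class Hom(NamedTuple):
    """One homologous chromosome as a founder mosaic.

    Segment i covers [breaks[i], breaks[i+1]) cM and carries founder
    ``labels[i]`` (0 or 1).
    """

    breaks: np.ndarray  # ascending, breaks[0] == 0, breaks[-1] == length
    labels: np.ndarray  # int8, len(breaks) - 1


def _founder_hom(length_cm: float, label: int) -> Hom:
    return Hom(np.array([0.0, length_cm]), np.array([label], dtype=np.int8))


def expected_residual_het(generations: int) -> float:
    """Single-locus heterozygosity expectation for an F_t selfing series.

    Each selfing round halves heterozygosity from the F1's 1.0, giving
    (1/2)**(t-1) at generation t.
    """
    if generations < 2:
        raise ValueError("generations must be >= 2 (F2 or later)")
    return 0.5 ** (generations - 1)


def expected_ril_recombinant_fraction(r: float, generations: int) -> float:
    """Exact two-locus recombinant fraction at generation F_t under selfing.

    Iterates the 16-state Markov chain over ordered gamete pairs (gametes
    AB, Ab, aB, ab) from the F1 coupling heterozygote, with per-meiosis
    recombination fraction ``r``, and returns P(recombinant | both loci
    homozygous).  As t grows this converges to the Haldane-Waddington limit
    2r/(1+2r); at finite t (e.g. F7) it lies slightly below it because
    recombinant classes are still accumulating while heterozygotes fix.
    """
    if generations < 2:
        raise ValueError("generations must be >= 2 (F2 or later)")
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must be in [0, 0.5]")
    # gamete index g = 2a + b with a, b in {0, 1}: 0=AB, 1=Ab, 2=aB, 3=ab
    allele_a = [0, 0, 1, 1]
    allele_b = [0, 1, 0, 1]
    meiosis = np.zeros((16, 4))
    for s in range(16):
        g1, g2 = divmod(s, 4)
        p = np.zeros(4)
        p[g1] += (1 - r) / 2
        p[g2] += (1 - r) / 2
        p[2 * allele_a[g1] + allele_b[g2]] += r / 2
        p[2 * allele_a[g2] + allele_b[g1]] += r / 2
        meiosis[s] = p
    transition = np.stack([np.outer(m, m).ravel() for m in meiosis])
    dist = np.zeros(16)
    dist[0 * 4 + 3] = 1.0  # F1 = AB/ab
    for _ in range(generations - 1):
        dist = dist @ transition
    num = den = 0.0
    for s in range(16):
        g1, g2 = divmod(s, 4)
        if allele_a[g1] == allele_a[g2] and allele_b[g1] == allele_b[g2]:
            den += dist[s]
            if g1 in (1, 2):  # Ab/Ab or aB/aB
                num += dist[s]
    return num / den


def simulate_meiosis(
    h1: Hom, h2: Hom, length_cm: float, rng: np.random.Generator
) -> tuple[Hom, np.ndarray]:
    """One meiosis: crossover count ~ Poisson(length/100), positions uniform.

    The gamete alternates between the two parental homologs at each
    crossover; the starting homolog is equiprobable.  Returns the gamete and
    the crossover positions (cM).
    """
    if length_cm < 0:
        raise ValueError("chromosome length must be >= 0 cM")
    n_co = rng.poisson(length_cm / 100.0)
    cuts = np.sort(rng.uniform(0.0, length_cm, size=n_co))
    phase = int(rng.integers(2))
    bounds = np.concatenate(([0.0], cuts, [length_cm]))
    homs = (h1, h2)
    breaks: list[float] = [0.0]
    labels: list[int] = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        if b <= a:
            continue
        h = homs[(phase + i) % 2]
        j0 = int(np.searchsorted(h.breaks, a, side="right")) - 1
        j0 = min(max(j0, 0), len(h.labels) - 1)
        j1 = int(np.searchsorted(h.breaks, b, side="left"))
        for j in range(j0, min(j1, len(h.labels))):
            s = max(float(h.breaks[j]), a)
            e = min(float(h.breaks[j + 1]), b)
            if e <= s:
                continue
            lab = int(h.labels[j])
            if labels and labels[-1] == lab:
                breaks[-1] = e
            else:
                labels.append(lab)
                breaks.append(e)
    breaks[-1] = length_cm
    return Hom(np.array(breaks), np.array(labels, dtype=np.int8)), cuts


def _calls_at(h1: Hom, h2: Hom, pos_cm: np.ndarray) -> np.ndarray:
    """Diploid genotype codes at positions (cM) on one chromosome."""
    i1 = np.clip(np.searchsorted(h1.breaks, pos_cm, side="right") - 1, 0, len(h1.labels) - 1)
    i2 = np.clip(np.searchsorted(h2.breaks, pos_cm, side="right") - 1, 0, len(h2.labels) - 1)
    a = h1.labels[i1]
    b = h2.labels[i2]
    out = np.where(a == b, np.where(a == 0, P1, P2), HET)
    return out.astype(np.int8)


@dataclass
class RILPopulation:
    """Final diploid mosaics of every RIL plus crossover records."""

    config: SimConfig
    # homologs[ril][chrom] -> (Hom, Hom)
    homologs: list[list[tuple[Hom, Hom]]]
    # crossovers[ril][chrom] -> sorted cM positions over the whole lineage
    crossovers: list[list[np.ndarray]]

    def genotype_at(self, chrom: int, pos_cm: np.ndarray) -> np.ndarray:
        """(n_loci, n_rils) genotype codes at loci on one chromosome."""
        cols = [
            _calls_at(*self.homologs[r][chrom], np.asarray(pos_cm, dtype=float))
            for r in range(self.config.n_rils)
        ]
        return np.stack(cols, axis=1)


def simulate_ril_population(
    config: SimConfig, rng: np.random.Generator
) -> RILPopulation:
    """Selfing-series simulation: F1 heterozygote selfed t-1 times.

    Each round produces the two gametes of the next generation by
    independent meioses of the current diploid, so residual heterozygosity
    arises organically rather than being imposed.
    """
    n_rounds = config.selfing_generations - 1
    homologs: list[list[tuple[Hom, Hom]]] = []
    crossovers: list[list[np.ndarray]] = []
    for _ in range(config.n_rils):
        per_chrom: list[tuple[Hom, Hom]] = []
        per_chrom_xo: list[np.ndarray] = []
        for length in config.chrom_genetic_lengths:
            h1 = _founder_hom(length, 0)
            h2 = _founder_hom(length, 1)
            xo: list[np.ndarray] = []
            for _ in range(n_rounds):
                g1, c1 = simulate_meiosis(h1, h2, length, rng)
                g2, c2 = simulate_meiosis(h1, h2, length, rng)
                h1, h2 = g1, g2
                xo.extend((c1, c2))
            per_chrom.append((h1, h2))
            per_chrom_xo.append(np.sort(np.concatenate(xo)) if xo else np.empty(0))
        homologs.append(per_chrom)
        crossovers.append(per_chrom_xo)
    return RILPopulation(config, homologs, crossovers)


@dataclass
class SimTruth:
    """Ground truth used as the oracle for the validation pipeline."""

    scaffolds: pd.DataFrame  # scaffold_id, chrom, start, end, strand, is_chimeric
    chimeras: pd.DataFrame  # scaffold_id, junction_bp, junction_lo_bp,
    #                         junction_hi_bp, donor_scaffold, donor_chrom
    superscaffolds: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["superscaffold_id", "chrom", "orientation", "is_misjoin"]
        )
    )
    crossovers: list[list[np.ndarray]] | None = None
    founder_labels: tuple[str, str] = ("A", "B")

    def scaffold_lengths(self) -> dict[str, int]:
        df = self.scaffolds
        return dict(
            zip(df["scaffold_id"], (df["end"] - df["start"]).astype(int))
        )


def fragment_into_scaffolds(
    config: SimConfig, population: RILPopulation, rng: np.random.Generator
) -> tuple[MarkerTable, SimTruth]:
    """Partition each chromosome into scaffolds and place markers on them.

    Scaffold widths are jittered around the equal partition; marker loci are
    distinct positions within each scaffold.  Scaffold strand is randomized:
    on a '-' scaffold, ascending scaffold coordinates run against the
    chromosome, so marker order along the scaffold reverses chromosomal
    order.
    """
    s_per_chrom = config.scaffolds_per_chromosome
    m_per_sc = config.markers_per_scaffold
    ril_ids = [f"RIL{r + 1:03d}" for r in range(config.n_rils)]
    truth_rows = []
    meta_rows = []
    call_blocks = []
    sc_index = 0
    for c in range(config.n_chromosomes):
        plen = config.chrom_physical_lengths[c]
        glen = config.chrom_genetic_lengths[c]
        width = plen / s_per_chrom
        if width < 2 * m_per_sc:
            raise ValueError(
                f"chromosome {c}: {s_per_chrom} scaffolds of {m_per_sc} markers "
                f"do not fit in {plen} bp"
            )
        # jittered equal partition keeps every scaffold within [0.5, 1.5]x
        # the mean width and tiles the chromosome exactly
        cuts = np.array(
            [
                int(i * width + rng.uniform(-0.25, 0.25) * width)
                for i in range(1, s_per_chrom)
            ]
        )
        edges = np.concatenate(([0], cuts, [plen]))
        chrom_marker_pos = []  # global bp of every marker on this chromosome
        for j in range(s_per_chrom):
            start, end = int(edges[j]), int(edges[j + 1])
            sc_len = end - start
            sc_id = f"SC{sc_index:05d}"
            sc_index += 1
            strand = "+" if rng.random() < 0.5 else "-"
            local = np.sort(rng.choice(sc_len, size=m_per_sc, replace=False))
            if strand == "+":
                global_bp = start + local
            else:
                global_bp = end - 1 - local  # descending along the chromosome
            truth_rows.append((sc_id, c, start, end, strand, False))
            for k in range(m_per_sc):
                meta_rows.append(
                    (f"{sc_id}_m{k:03d}", sc_id, int(local[k]), int(global_bp[k]))
                )
            chrom_marker_pos.append(global_bp)
        pos_cm = np.concatenate(chrom_marker_pos) / plen * glen
        call_blocks.append(population.genotype_at(c, pos_cm))
    meta = pd.DataFrame(
        meta_rows, columns=["marker_id", "scaffold_id", "pos_bp", "_global_bp"]
    )
    calls = np.concatenate(call_blocks, axis=0)
    table = MarkerTable(meta[["marker_id", "scaffold_id", "pos_bp"]], calls, ril_ids)
    truth = SimTruth(
        scaffolds=pd.DataFrame(
            truth_rows,
            columns=["scaffold_id", "chrom", "start", "end", "strand", "is_chimeric"],
        ),
        chimeras=pd.DataFrame(
            columns=[
                "scaffold_id",
                "junction_bp",
                "junction_lo_bp",
                "junction_hi_bp",
                "donor_scaffold",
                "donor_chrom",
            ]
        ),
        crossovers=population.crossovers,
    )
    return table, truth


def _genetic_midpoint_cm(config: SimConfig, row: pd.Series) -> float:
    plen = config.chrom_physical_lengths[int(row["chrom"])]
    glen = config.chrom_genetic_lengths[int(row["chrom"])]
    return (row["start"] + row["end"]) / 2 / plen * glen


def plant_chimeras(
    table: MarkerTable,
    truth: SimTruth,
    population: RILPopulation,
    config: SimConfig,
    rng: np.random.Generator,
    min_donor_distance_cm: float = 50.0,
) -> tuple[MarkerTable, SimTruth]:
    """Replace a fraction of scaffolds by chimeric misjoins.

    ceil(chimera_fraction * n_scaffolds) scaffolds have their tail markers
    re-sourced from a donor locus on a different chromosome, so the two
    sides of each junction segregate independently and population-wide
    genotype switch fractions at the misjoin approach 0.5.  Only in a
    single-chromosome design are same-chromosome donors at least
    ``min_donor_distance_cm`` away used as a fallback (weaker, but still
    well above within-scaffold recombination).  Marker count, scaffold
    count and physical length are conserved.
    """
    n_sc = len(truth.scaffolds)
    n_chim = math.ceil(config.chimera_fraction * n_sc)
    if n_chim == 0:
        return table, truth
    scaffolds = truth.scaffolds.copy()
    calls = table.calls.copy()
    meta = table.meta.copy()
    chosen = rng.choice(n_sc, size=n_chim, replace=False)
    chim_rows = []
    mid_cm = {
        i: _genetic_midpoint_cm(config, scaffolds.iloc[i]) for i in range(n_sc)
    }
    for i in sorted(int(x) for x in chosen):
        row = scaffolds.iloc[i]
        donors = [
            j for j in range(n_sc) if scaffolds.iloc[j]["chrom"] != row["chrom"]
        ]
        if not donors:  # single-chromosome design: distant same-chrom donors
            donors = [
                j
                for j in range(n_sc)
                if j != i and abs(mid_cm[j] - mid_cm[i]) > min_donor_distance_cm
            ]
        if not donors:
            raise ValueError(
                "no eligible chimera donor: need >= 2 chromosomes or loci "
                f"> {min_donor_distance_cm} cM apart"
            )
        donor = scaffolds.iloc[donors[int(rng.integers(len(donors)))]]
        rows = table.scaffold_rows(str(row["scaffold_id"]))
        m = len(rows)
        if m < 2:
            continue
        j_cut = int(rng.integers(1, m))  # markers j_cut.. take donor calls
        n_tail = m - j_cut
        d_chrom = int(donor["chrom"])
        d_len = int(donor["end"] - donor["start"])
        d_local = np.sort(rng.choice(d_len, size=n_tail, replace=False))
        d_global = int(donor["start"]) + d_local
        plen = config.chrom_physical_lengths[d_chrom]
        glen = config.chrom_genetic_lengths[d_chrom]
        donor_calls = population.genotype_at(d_chrom, d_global / plen * glen)
        calls[rows[j_cut:]] = donor_calls
        pos = meta["pos_bp"].to_numpy()[rows]
        lo, hi = int(pos[j_cut - 1]), int(pos[j_cut])
        scaffolds.loc[scaffolds.index[i], "is_chimeric"] = True
        chim_rows.append(
            (
                str(row["scaffold_id"]),
                (lo + hi) // 2,
                lo,
                hi,
                str(donor["scaffold_id"]),
                d_chrom,
            )
        )
    chimeras = pd.DataFrame(
        chim_rows,
        columns=[
            "scaffold_id",
            "junction_bp",
            "junction_lo_bp",
            "junction_hi_bp",
            "donor_scaffold",
            "donor_chrom",
        ],
    )
    new_truth = SimTruth(
        scaffolds=scaffolds,
        chimeras=chimeras,
        superscaffolds=truth.superscaffolds,
        crossovers=truth.crossovers,
        founder_labels=truth.founder_labels,
    )
    return MarkerTable(meta, calls, list(table.ril_ids)), new_truth


def degrade_calls(
    table: MarkerTable,
    genotype_error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> MarkerTable:
    """Apply missingness then genotyping error, mimicking ~1x sequencing.

    Each call is independently set missing with ``missing_rate``; surviving
    homozygous calls flip to the opposite parent with
    ``genotype_error_rate``.  Heterozygous calls are left unchanged.
    """
    for name, rate in (
        ("genotype_error_rate", genotype_error_rate),
        ("missing_rate", missing_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    calls = table.calls.copy()
    drop = rng.random(calls.shape) < missing_rate
    flip = rng.random(calls.shape) < genotype_error_rate
    calls[drop] = MISSING
    hom = (calls == P1) | (calls == P2)
    sel = hom & flip
    calls[sel] = 1 - calls[sel]  # P1 <-> P2
    return MarkerTable(table.meta.copy(), calls, list(table.ril_ids))


@dataclass
class Component:
    """One scaffold inside a superscaffold layout."""

    scaffold_id: str
    start: int  # 0-based on the superscaffold
    end: int
    strand: str  # '+', '-' or '?'
    gap_after: int = 0  # bp of N after this component (0 for the last)


@dataclass
class SuperscaffoldLayout:
    superscaffold_id: str
    components: list[Component]
    length: int

    @classmethod
    def from_parts(
        cls,
        superscaffold_id: str,
        parts: list[tuple[str, int, str]],  # (scaffold_id, length, strand)
        gap_bp: int = 100,
    ) -> "SuperscaffoldLayout":
        comps = []
        offset = 0
        for k, (sid, length, strand) in enumerate(parts):
            gap = gap_bp if k < len(parts) - 1 else 0
            comps.append(Component(sid, offset, offset + length, strand, gap))
            offset += length + gap
        return cls(superscaffold_id, comps, offset)


def assemble_superscaffolds(
    truth: SimTruth,
    rng: np.random.Generator,
    min_components: int = 2,
    max_components: int = 6,
    gap_bp: int = 100,
    misjoin_fraction: float = 0.0,
) -> tuple[list[SuperscaffoldLayout], SimTruth]:
    """Chain chromosome-consecutive scaffolds into stranded superscaffolds.

    Each superscaffold is randomly presented forward or reversed relative to
    the chromosome; its true orientation is recorded.  When
    ``misjoin_fraction`` > 0, pairs of superscaffolds on different
    chromosomes swap their tail components, planting cross-linkage-group
    misjoins (an even number, two per swap).
    """
    lengths = truth.scaffold_lengths()
    scaffolds = truth.scaffolds
    layouts: list[SuperscaffoldLayout] = []
    ss_rows = []
    # parts per superscaffold in chromosome-forward order first
    groups: list[tuple[int, list[pd.Series]]] = []
    for chrom, chrom_df in scaffolds.groupby("chrom", sort=True):
        chrom_df = chrom_df.sort_values("start")
        rows = [row for _, row in chrom_df.iterrows()]
        i = 0
        while i < len(rows):
            size = int(rng.integers(min_components, max_components + 1))
            groups.append((int(chrom), rows[i : i + size]))
            i += size
    for idx, (chrom, members) in enumerate(groups):
        ss_id = f"SS{idx:04d}"
        flipped = rng.random() < 0.5
        ordered = list(reversed(members)) if flipped else members
        parts = []
        for row in ordered:
            # component strand restores chromosome-forward sequence; a
            # flipped superscaffold flips every component
            fwd = row["strand"] == "+"
            strand = "+" if fwd != flipped else "-"
            parts.append((str(row["scaffold_id"]), lengths[str(row["scaffold_id"])], strand))
        layouts.append(SuperscaffoldLayout.from_parts(ss_id, parts, gap_bp))
        ss_rows.append((ss_id, chrom, "-" if flipped else "+", False))
    ss_truth = pd.DataFrame(
        ss_rows, columns=["superscaffold_id", "chrom", "orientation", "is_misjoin"]
    )
    if misjoin_fraction > 0:
        n_pairs = math.ceil(misjoin_fraction * len(layouts) / 2)
        multi = [
            i for i, lay in enumerate(layouts) if len(lay.components) >= 2
        ]
        rng.shuffle(multi)
        made = 0
        used: set[int] = set()
        for i in multi:
            if made >= n_pairs:
                break
            if i in used:
                continue
            partner = next(
                (
                    j
                    for j in multi
                    if j not in used
                    and j != i
                    and ss_truth.iloc[j]["chrom"] != ss_truth.iloc[i]["chrom"]
                ),
                None,
            )
            if partner is None:
                break
            _swap_tails(layouts, i, partner, rng)
            ss_truth.loc[ss_truth.index[i], "is_misjoin"] = True
            ss_truth.loc[ss_truth.index[partner], "is_misjoin"] = True
            used.update((i, partner))
            made += 1
    new_truth = SimTruth(
        scaffolds=truth.scaffolds,
        chimeras=truth.chimeras,
        superscaffolds=ss_truth,
        crossovers=truth.crossovers,
        founder_labels=truth.founder_labels,
    )
    return layouts, new_truth


def _swap_tails(
    layouts: list[SuperscaffoldLayout],
    i: int,
    j: int,
    rng: np.random.Generator,
) -> None:
    """Swap tail component blocks of two superscaffold layouts in place."""
    a, b = layouts[i], layouts[j]
    cut_a = int(rng.integers(1, len(a.components)))
    cut_b = int(rng.integers(1, len(b.components)))
    parts_a = [(c.scaffold_id, c.end - c.start, c.strand) for c in a.components]
    parts_b = [(c.scaffold_id, c.end - c.start, c.strand) for c in b.components]
    new_a = parts_a[:cut_a] + parts_b[cut_b:]
    new_b = parts_b[:cut_b] + parts_a[cut_a:]
    gap = a.components[0].gap_after or 100
    layouts[i] = SuperscaffoldLayout.from_parts(a.superscaffold_id, new_a, gap)
    layouts[j] = SuperscaffoldLayout.from_parts(b.superscaffold_id, new_b, gap)


def layouts_to_frame(layouts: list[SuperscaffoldLayout]) -> pd.DataFrame:
    rows = [
        (lay.superscaffold_id, c.scaffold_id, c.start, c.end, c.strand, c.gap_after)
        for lay in layouts
        for c in lay.components
    ]
    return pd.DataFrame(
        rows,
        columns=["superscaffold_id", "scaffold_id", "start", "end", "strand", "gap_after"],
    )


def layouts_from_frame(df: pd.DataFrame) -> list[SuperscaffoldLayout]:
    out = []
    for ss_id, grp in df.groupby("superscaffold_id", sort=True):
        grp = grp.sort_values("start")
        comps = [
            Component(
                str(r["scaffold_id"]),
                int(r["start"]),
                int(r["end"]),
                str(r["strand"]),
                int(r["gap_after"]),
            )
            for _, r in grp.iterrows()
        ]
        length = comps[-1].end + comps[-1].gap_after if comps else 0
        out.append(SuperscaffoldLayout(str(ss_id), comps, length))
    return out


def scaffold_sequences(
    truth: SimTruth, rng: np.random.Generator
) -> dict[str, str]:
    """Uniform-random ACGT sequence per scaffold, matching true lengths."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out = {}
    for sid, length in truth.scaffold_lengths().items():
        idx = rng.integers(0, 4, size=length)
        out[sid] = bases[idx].tobytes().decode()
    return out


@dataclass
class SimResult:
    config: SimConfig
    truth: SimTruth
    table: MarkerTable  # observed (degraded) genotype calls
    clean_table: MarkerTable  # pre-degradation calls
    layouts: list[SuperscaffoldLayout]
    population: RILPopulation


def simulate(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    superscaffold_misjoin_fraction: float = 0.0,
) -> SimResult:
    """Full simulation: population, fragmentation, chimeras, degradation."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    population = simulate_ril_population(config, rng)
    table, truth = fragment_into_scaffolds(config, population, rng)
    table, truth = plant_chimeras(table, truth, population, config, rng)
    clean = table
    table = degrade_calls(
        table, config.genotype_error_rate, config.missing_rate, rng
    )
    layouts, truth = assemble_superscaffolds(
        truth, rng, misjoin_fraction=superscaffold_misjoin_fraction
    )
    return SimResult(config, truth, table, clean, layouts, population)


def write_truth(truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    truth.scaffolds.to_csv(outdir / "scaffold_truth.tsv", sep="\t", index=False)
    truth.chimeras.to_csv(outdir / "chimera_truth.tsv", sep="\t", index=False)
    if len(truth.superscaffolds):
        truth.superscaffolds.to_csv(
            outdir / "superscaffold_truth.tsv", sep="\t", index=False
        )


def write_manifest(config: SimConfig, outdir: str | Path) -> None:
    with open(Path(outdir) / "sim_manifest.json", "w") as fh:
        json.dump({"config": config.to_dict()}, fh, indent=2)
        fh.write("\n")
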
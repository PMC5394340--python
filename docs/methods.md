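# Methods

`mapanchor` validates and anchors a fragmented plant genome assembly with a
biparental recombinant-inbred-line (RIL) genetic map. This note documents the
models, the default parameters and why they are set where they are, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The population model

The simulated cross is two inbred founders (calls coded `A` and `B`), an F1
heterozygote, and `t - 1` rounds of selfing to reach generation F_t (default
F7). Each selfing round draws the two gametes of the next generation by
independent meioses of the current diploid, so residual heterozygosity arises
organically rather than being imposed: the single-locus expectation is
(1/2)^(t-1), i.e. 1.5625% at F7 (`expected_residual_het`).

Meiosis follows a no-interference (Haldane) model: the crossover count on a
chromosome of genetic length L cM is Poisson with mean L/100, crossover
positions are uniform, the gamete alternates parental homolog at each
crossover, and the starting homolog is equiprobable. This matches the Haldane
map function used downstream; crossover interference is irrelevant at the
map resolution exercised here.

### Finite-generation recombinant fractions

The familiar RIL map-expansion formula R = 2r/(1+2r) (and its inverse
r = R/(2(1-R)), `ril_correct`) describes the recombinant fraction among
*fully inbred* lines. At F7, fixation is incomplete, and the conditional
recombinant fraction among lines homozygous at both loci is slightly lower:
for loci 10 cM apart, 0.1459 instead of the asymptotic 0.1535.
`expected_ril_recombinant_fraction(r, t)` computes the exact value by
iterating the 16-state two-locus selfing Markov chain (ordered gamete pairs
over {AB, Ab, aB, ab}); it reproduces the F2 closed form
r²/((1-r)² + r²) exactly and converges to 2r/(1+2r) to 1e-9 by t = 60.
Simulator fidelity is tested against this exact expectation; the asymptotic
formula is still used for map-distance correction, where the ≲5% relative
difference is far below the sampling noise of two-point estimates at
99 lines.

## The synthetic assembly

Chromosomes are tiled by scaffolds (jittered equal partition, each scaffold
0.5-1.5x the mean width) with a random strand per scaffold; each scaffold
carries `markers_per_scaffold` markers at distinct positions, whose genotype
columns are evaluated from the RIL mosaics at the marker's true locus.
Chimeric misjoins are planted by re-sourcing the tail markers of
ceil(`chimera_fraction` × n) scaffolds from a donor region on a *different
chromosome*, so the two sides of the junction segregate independently and
the population-wide switch fraction at the misjoin approaches the unlinked
expectation (~0.5 at F7). Same-chromosome donors at ≥ 50 cM are only a
fallback for single-chromosome designs; at smaller separations a misjoin's
switch fraction (e.g. ~0.31 at 30 cM) would sit at the detection threshold
and the planted artifact class would no longer be the one the detector is
specified against. Calls are then degraded: each call is set missing with
`missing_rate`, and surviving homozygous calls flip to the opposite parent
with `genotype_error_rate` (heterozygous calls are left intact). Consecutive
scaffolds are chained into superscaffolds (2-6 components, 100 bp N gaps,
random presentation strand); optionally, pairs of superscaffolds on
different chromosomes swap tail components to plant cross-linkage-group
misjoins.

The default `lettuce-like` preset encodes the study conditions this package
is built around: 9 chromosomes of 110 cM / 25 Mb, 99 F7 RILs, 40
scaffolds/chromosome × 10 markers, 1% genotyping error, 25% missingness, 1%
chimeric scaffolds. The `toy` preset (3 chromosomes of 60 cM / 600 kb, 66
RILs, 12 scaffolds/chromosome) exists so sequence-level stages (FASTA/AGP)
run in well under a second; its 60 cM length keeps the genetic distance
between adjacent scaffold midpoints (5 cM) solidly above the two-point LOD
threshold at 66 lines, comparable to the main preset's density (2.75 cM at
99 lines).

What the generator does **not** emulate: read-level noise (alignment and SNP
calling are upstream of this pipeline), non-uniform recombination along the
chromosome (no pericentromeric suppression), segregation distortion,
paralog-induced genotyping artifacts, and repeat-driven marker density
variation. Passing tests therefore demonstrate correctness of the mapping
and anchoring machinery under clean population-genetic assumptions, not
robustness to every artifact of real resequencing data.

## Consensus haplotypes and chimera detection

Per scaffold and RIL, the consensus call is the class (A/B/H) holding at
least `majority_threshold` (default 0.7) of the non-missing marker calls,
with at least `min_markers` (default 2) informative calls; otherwise
missing. At ~1x coverage equivalents (25% missing, 1% error), a 10-marker
scaffold almost always yields a correct consensus; two or three stray calls
produce a missing consensus, never a confidently wrong one.

Switch profiles compare, at every inter-marker junction, the consensus of up
to `block_size` (default 5) markers on each flank, per RIL; lines homozygous
on both flanks are informative, and switch when the flanks disagree. Sliding
flanking windows (rather than a fixed disjoint blocking) keep full
breakpoint resolution — a misjoin is detectable wherever it falls along the
scaffold — while multi-marker consensus damps single-call errors. A scaffold
is called chimeric when some junction reaches switch fraction `tau` (default
0.30) with at least `min_support` (default 20) informative lines; runs of
adjacent qualifying junctions (a misjoin elevates neighbouring windows too)
merge to the single maximal junction. The margin is wide: within-scaffold
true recombination at ≤ 1 Mb scale gives fractions ≲ 0.05 in an F7 map,
versus ~0.5 at a misjoin of unlinked fragments. Scaffolds with no junction
reaching `min_support` are reported untestable, not clean.

Called scaffolds are split at the midpoint of the flanking-marker interval;
sub-scaffolds are named `<id>_p1..pk`, marker positions are remapped, and
sequence length and marker counts are conserved exactly.

## Linkage grouping, binning, ordering

Two-point estimates use lines homozygous at both scaffolds. The LOD against
free recombination is n·[R̂ log10 R̂ + (1-R̂) log10(1-R̂)] + n·log10 2.
Linkage groups are single-linkage connected components over edges with
LOD ≥ 6, phase-folded min(R̂, 1-R̂) ≤ 0.35, and ≥ 20 informative lines;
scaffolds under 1 kb are excluded up front. At the default preset scale
(~58,000 inter-chromosome pairs of ~96-line vectors) the exact binomial
probability of a spurious edge at LOD ≥ 6 is ~5e-8 per pair — expected
false edges per genome ≪ 1, which is why exact chromosome recovery is a
reasonable guarantee. Pairs with fewer than 20 informative lines never
cluster (sparse evidence floor).

Phase is normalized within each group by propagating along a minimum
spanning tree of folded distances rooted at the lexicographically smallest
scaffold (each MST edge joins tightly linked scaffolds, so every flip
decision is crisp). In this parent-coded design the data are already in
consistent phase and the step is a no-op safeguard; it makes all results
invariant to flipping any single input vector.

Bins agglomerate scaffolds with zero discordant informative lines (missing
tolerated); representatives are element-wise majorities. Bin ordering is
seriation: the chain is seeded at a *terminal* bin — identified as the bin
with the fewest neighbours at R < 0.25, since linkage is one-sided at a
chromosome end, whereas "most distant pair" criteria are decided by noise
(all distant pairs sit near R = 0.5) — grown by nearest neighbour, then
refined by 2-opt segment reversals plus or-opt relocations of segments of
length 1-3 (with optional reversal), first-improvement, deterministic scan.
The relocation moves matter: a greedy chain occasionally strands a few bins
at its tail, which reversals alone cannot repair. The seriation objective is
the sum of adjacent R̂/(2(1-R̂)) values, left uncapped beyond R = 0.5 so
that misjoining distant ends costs strictly more than joining near ends.
cM positions accumulate Haldane distances over adjacent corrected fractions
(capped at r = 0.45 per step so an uninformative ~0.5 estimate cannot inject
an unbounded gap); Kosambi is available behind a flag.

A refinement by double-recombinant minimization is deliberately **not**
applied at bin level: with mostly single-scaffold bins and ~99 lines it
overfits individual genuine double-crossover events and measurably degrades
order recovery. It is applied at superscaffold level (below), where units
are coarser.

**Known limitation — map compression.** The recovered cumulative map length
underestimates the simulated truth by ~30-45% at the default preset density.
Lines recombining *inside* a scaffold often fail the consensus majority and
drop out of the informative set; since exactly those lines are the
recombinant ones for the flanking intervals, adjacent recombinant fractions
are deflated. Bin *order* (the quantity anchoring depends on) is unaffected
— order recovery is Spearman |rho| ≈ 0.998 — but reported cM spans are
compressed and should be read as relative, not absolute, positions.
Similarly, scaffolds that truly cosegregate are guaranteed to land in the
same or an immediately adjacent bin; residual-heterozygosity boundary lines
can occasionally resolve to opposite homozygous consensus on two
cosegregating scaffolds and split a bin.

## Superscaffold anchoring and pseudomolecules

A superscaffold is placed by its mapped components: majority linkage group,
genetic span from first to last mapped component in that group. It is
misassembled if its components span more than one linkage group (split
proposed at the junction between the conflicting runs) or if the within-LG
bin sequence is non-monotone beyond `misassembly_tolerance` = 2 out-of-order
components (longest-monotone-subsequence criterion; the tolerance absorbs
bin-assignment noise). Orientation follows the terminal bins: ascending →
forward, descending → reverse, equal (or a single mapped component) →
unoriented. Orientation is defined *along the linkage group*; group
direction relative to the physical chromosome is arbitrary until fixed
against an external reference. Superscaffolds whose terminal bins differ by
exactly one step inherit the local order's resolution limit; in the packaged
simulations they account for all residual orientation errors
(span ≥ 2 units is error-free), with aggregate accuracy ≈ 99.5%.

The within-group superscaffold order (midpoint bin, ties by first bin, then
descending mapped-component count, then id) is refined by hill-climbing on
the double-recombinant count — X-Y-X patterns per line across consecutive
units, condensed over homozygous calls — using adjacent transpositions and
reinsertion within a 5-unit window, accepting only strict improvements
(monotone objective, deterministic scan).

Pseudomolecules concatenate the ordered superscaffolds with 10 kb N spacers;
reverse-oriented superscaffolds are reverse-complemented, unoriented ones
are kept as input. The AGP (v2.1) lists every component scaffold as a W row
with its *presented* strand and every gap as an N row (`scaffold`/`yes`,
evidence `map` for spacers, `paired-ends` for intra-superscaffold gaps), so
AGP plus component sequences reconstruct the FASTA byte-identically. The
superscaffold-level orientation status lives in the placement report; a `?`
orientation is accepted on input and treated as "use as stored". Telomere
arrays are found by scanning the first and last `window_bp` (default 10 kb)
of each pseudomolecule for tandem runs of the motif (default plant telomere
TTTAGGG) or its reverse complement, reporting runs of ≥ `min_copies`
(default 10); the chance of such a run in random sequence is negligible.

## Reproducibility

All randomness flows through one seeded `numpy.random.Generator` passed
explicitly; identical (config, seed) pairs reproduce byte-identical output
files. The pipeline writes every intermediate as TSV/FASTA/AGP plus a JSON
manifest whose counts are cross-checked against the files on disk.

## Problem sizes used in tests and the acceptance script

Mapping-level guarantees are measured on ten independent `lettuce-like`
genomes (360 scaffolds, 3,600 markers, 99 RILs each). Simulator-fidelity
checks use single-chromosome populations: 60,000 single-locus lines for
heterozygosity (relative SD ~3%) and 4,000 two-locus lines per distance for
recombinant fractions; sequence-level checks (spacers, AGP round trips) use
the `toy` preset. These sizes put every statistical check at ≥ 3 SE
resolution while the whole suite runs in a few minutes on one CPU.
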
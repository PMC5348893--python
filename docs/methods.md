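# Methods

This note documents the models, conventions, and numerical choices
behind `spidrokit`, and what the synthetic-data generator does and does
not emulate.

## Coordinates and sequence handling

All coordinates are 0-based, half-open `[start, end)`. FASTA I/O wraps
at 60 columns; duplicate ids and non-IUPAC characters are hard errors.
ORF search scans the three forward-strand frames by default because
spidroin accessions are deposited in coding orientation; a flag adds
the reverse complement. The minimum ORF length defaults to 300 nt to
skip spurious short frames; the reported interval includes the stop
codon, so ORF length is always a multiple of 3.

## Motif grammar

Classes: `GGX` (length 3, X = any residue, so `GGG` qualifies), `GPG`
(exact word), `POLY_A` (run of A, length ≥ 4), `GA_RUN` (alternating
`(GA)_n`, n ≥ 2, starting on G; a trailing lone G is not included).
Within one class, scanning is greedy, left-to-right, non-overlapping,
and maximally extended — `AAAAA` is one run of 5, `GAGAGA` one run of
6, and overlapping candidates like `GPGPG` count once. Classes are
scanned independently and may overlap each other. Coverage of a class
is covered residues divided by region length; by default the region is
the whole described sequence including termini (a flag restricts to a
region). Species motif values are unweighted means over sequences.
Percentages format by rounding half away from zero to 2 decimals.

Hydropathy uses the Kyte–Doolittle residue scale with a centered
moving average (default window 7, the conventional choice for spotting
hydrophilic spacers); positions with incomplete windows are omitted.

## Spacer detection

Spacers are operationally defined as Gly/Ala-poor stretches outside
the terminal domains. Defaults: N/C margins 150/100 aa (typical
spidroin terminal-domain lengths; in the source data termini were
assigned by homology, so the margins are configurable, not canonical),
window 25 aa, Gly+Ala ceiling 0.25, merge gap 5, minimum length 15 aa.
Flagged windows are merged and clamped to the non-terminal span;
detected boundaries land within roughly half a window of a planted
block's edges. Spacer homogeneity is the mean pairwise
global-alignment identity and is reported as not applicable for fewer
than two spacers.

## Tandem-repeat detection

A bespoke seed-and-extend consensus method:

1. candidate periods are voted by spacings between consecutive
   recurrences of 4-mers (top 40 spacings in 5..600 aa);
2. from each anchor where two adjacent period-length windows agree at
   ≥ the identity floor (default 0.70), every start phase within one
   period is tried and the longest extension kept — anchors can sit a
   few residues before the true array, and the wrong phase fragments
   the block;
3. copies grow against a running majority-rule consensus; the final
   partial copy counts fractionally;
4. harmonic locking (reporting 2× or 4× the true unit) is undone by
   checking the consensus for self-repetition at divisor periods and
   re-extending at the fundamental;
5. overlapping blocks are resolved greedily by the score
   copies × period × identity.

Copy identity is measured against the consensus, not the first copy.
On generator output with per-copy identity ≥ 0.85 and ≥ 3 copies the
detector recovers period and copy number within ±1 (validated over 100
seeds); an i.i.d. random 500-mer yields a block in well under 5% of
seeds. When spacers interleave a repeat array, the ensemble-scale unit
(copies + spacer) can legitimately outscore the short unit; modularity
classification calls a protein `higher_order` if any block has period
> 160 aa with ≥ 2 copies (strict inequality at 160), else `short_unit`
if some block of period ≤ 30 aa has > 10 copies, else `none`.

## Alignment, distances, trees

Global alignment uses affine gap scoring (match 1, mismatch −1, first
gap position −5, each further −1) via a standard dynamic-programming
aligner; the first optimal alignment in its deterministic enumeration
order is returned. Printed divergence percentages on real sequence
pairs are alignment-parameter sensitive at roughly the ±1 percentage
point level. p-distance excludes gap-containing columns (pairwise
deletion). Neighbor joining is the classic Saitou–Nei agglomeration
with the Q criterion; ties break on the lowest index pair; the output
is unrooted (trifurcating seed node, closed-form three-taxon
termination) with optional midpoint rooting; additive matrices are
recovered exactly, topology and branch lengths.

Reconciliation requires rooted binary trees. The LCA map is computed
bottom-up; duplication iff M(g) equals the map of one of its children.
Losses per gene edge (g, c): the species-path edge count from M(g)
down to M(c), minus 1 when g is a speciation — the standard
embedding-based count, which yields zero on congruent trees. The
minimal duplication count matches exhaustive search over consistent
reconciliation maps on small trees.

Independent contrasts follow Felsenstein's pruning exactly (weighted
ancestral values, parent branch lengthened by v_i·v_j/(v_i+v_j));
contrast regressions are forced through the origin. OLS adjusted R² is
1−(1−R²)(n−1)/(n−2) with an intercept and 1−(1−R²)·n/(n−1) through the
origin (uncentered R²); p-values come from the slope t-test.

### The structure–property regression data

The packaged per-species table carries one row per published source.
Two sources report N. clavipes extensibility (0.30 and 0.25) and the
regression uses one value per species; the default takes the
first-listed source, and `regression_species_data(source_rank=...)`
exposes the choice because the fitted adjusted R² moves from 0.53 to
0.49 between them. The divergence-time tree used for the contrasts
regression is synthetic: published topology, plausible round-number
branch lengths (My). The contrasts R² is strongly branch-length
dependent (the published analysis attributes its high value to a short
S. grossa branch), so contrasts output on the packaged tree is a
sensitivity check, not a reproduction.

## Expression ratios

Read assignment is an exhaustive ungapped scan over all references and
offsets, forward orientation by default (reverse complement behind a
flag); the fewest-mismatch placement wins, ties break by reference
input order then leftmost offset, and reads beyond the mismatch
ceiling (default 3) are unassigned. This matches the contract of
"report the one best alignment" without an external aligner: the
references are two known loci and the reads short. The 3'-window count
includes a read if its placement overlaps the 3'-most window (default
500 coding bases) by at least half the read length — the overlap rule
is our choice, as no published rule exists. Ratios are
numerator/denominator counts; a zero denominator yields an undefined
ratio, not an exception. The windowed ratio is the robust one when
library 3' bias meets unequal gene lengths.

## Tensile mechanics

ε = ln(L/L₀) with L = L₀ + extension; σ = F·L/(A₀·L₀),
A₀ = π(d/2)² — with force in µN and diameter in µm this gives MPa
directly. Breakage is the last sample before force drops by more than
50% from its running maximum (falling back to the final sample);
strength and extensibility are read at that sample. The drop fraction
and the modulus window (least-squares slope over ε ≤ 0.02) are
unpublished details of the original workflow; both are configurable
defaults here. Toughness is the trapezoidal integral to breakage, in
MJ/m³, reported as J/cm³ (numerically equal). One-way ANOVA is
computed from explicit sums of squares; Tukey's HSD uses the
studentized range with a common n (harmonic mean of group sizes by
default) and emits a compact letter display. The full multivariate
MANOVA statistic is out of scope; per-property univariate F values are
what this module produces.

## Synthetic-data generator

`generate_spidroin` concatenates an N-terminus, a repeat array, and a
C-terminus. The repeat unit is built to a residue budget per motif
class (default mix 30% GGX, 30% (GA)_n, 20% A_n, GPG configurable;
serine fills the remainder, giving the Gly/Ala/Ser-dominated
composition real spidroins show); spacers (Ser/Thr/Val-rich,
Gly/Ala-free, 30 aa) are planted after chosen copy indices. Per-copy,
per-spacer, and per-terminus substitution rates are independent —
defaults for validation runs use repeat 0.05–0.07 and spacer 0.005,
reproducing the homogenized-spacer signature (spacer identity above
repeat-copy identity). Back-translation draws synonymous codons with a
0.7 probability of an A/T third base, mirroring the observed codon
bias, and logs exact codon counts as truth.

`evolve_family` evolves n loci (duplicated at the root, then diverged
by a burn-in substitution density so paralogs predate speciations)
down a species tree: per-branch Binomial substitutions, Poisson
slippage events that insert or delete one repeat unit of coding
sequence inside the repeat region, and Poisson intergenic
gene-conversion events that overwrite a tract of one paralog with the
other — restricted to the terminal-encoding regions under
`terminal_only`, the regime that homogenizes real spidroin termini
while repeat regions diverge. Every event is logged with locus, branch
and tract.

`generate_reads` draws read start positions with an exponential weight
toward the 3' end (decay 0 = uniform; decay 10 puts > 90% of starts in
the last quarter), the locus of origin proportional to the requested
abundance ratio, and i.i.d. per-base errors. `simulate_tensile` builds
a force–extension trace whose true-curve transform is a bilinear
stiff-then-yielding template (yield strain 0.02 by default) ending at
the requested (extensibility, strength); the strain grid contains the
yield and break points exactly, so noise-free traces recover the
closed-form properties to machine precision; Gaussian force noise and
a post-break collapse are appended. `simulate_bm_traits` is plain
Brownian motion along branches.

What the generator does **not** emulate: realistic substitution
models (no JTT/WAG, no transition/transversion bias), indels other
than unit-sized slippage, read quality scores, aligner-specific
artifacts, fiber diameter variation within a trace, or
supercontraction. Passing recovery tests therefore demonstrates the
pipeline's correctness under the stated statistical structure, not
performance on every artifact real data can contain.

## Problem sizes used in validation

The shipped validation and reproduction runs use: 4 species × 2 loci
families with ~450/300-nt terminal regions, repeat recovery over
50–100 generator seeds, read-ratio recovery at depth 2×10⁴ with 50-nt
reads, 500-replicate Brownian simulations on a 16-tip tree, and
20-trace tensile batches — sizes chosen so the full validation suite
completes in a couple of minutes while keeping Monte-Carlo standard
errors well inside the asserted tolerances.

## Known limitations

- Spacer boundaries are definitional (the original assignments were
  manual); defaults are tuned to the planted-truth generator, and real
  proteins may need ceiling/margin adjustments.
- The repeat detector reports one non-overlapping tiling; biologically
  nested repeat structure (short units inside a higher-order unit) is
  visible only through the harmonic-collapse step, not reported
  simultaneously.
- Reconciliation assumes binary rooted inputs and does not attempt
  rearrangement-based or bootstrap-aware reconciliation.
- Accession-anchored checks (ORF length 6549 nt, the 20.3%
  variant divergence, etc.) require user-downloaded GenBank FASTA
  files; the package does not fetch or redistribute them.
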
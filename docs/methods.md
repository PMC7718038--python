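# Methods

This note documents the models, estimators, numerical conventions and
design choices behind phagekit, and what the synthetic-data tests do and
do not demonstrate about real experiments.

## One-step growth model and estimators

The package targets the classical one-step growth experiment: phage are
mixed with a dense mid-log culture, free phage are titered at fixed
intervals (2 min here), and three quantities are read off the curve.

**Adsorption.** Free phage attach irreversibly to intact cells with a
second-order rate constant k (mL·min⁻¹). The estimator is the two-point
closed form k = −ln(P(t₁)/P(t₀)) / (N(t₁−t₀)) with t₀ = 0, t₁ = 4 min by
default. N is treated as constant over the window, which is accurate
because (a) cells are not consumed by adsorption on this timescale and
(b) the adsorption window ends before the first lysis. Requested times
are matched to the nearest sample within 0.5 min; titers are plate
counts and are never interpolated. An apparent titer *rise* over the
window — possible under plating noise — clamps k to 0 with a flag
rather than erroring.

**Latency.** "Time to significant rise" needs an operational
definition; the one used here is: walking forward through the samples
after the adsorption window, a candidate time t_i is the latency when
its log₁₀ titer exceeds μ + max(3σ, log₁₀ r) — μ, σ taken over the
samples strictly between the window and t_i (at least two) — and every
later sample stays above μ (persistence, so a single noisy plate cannot
fake a burst). The rise factor r defaults to 2.0. On noiseless
simulated data sampled every Δ minutes this returns the true latency
rounded up to the sampling grid. A series that never rises is reported
as "undetected", a flag, not an error.

**Burst size.** B = P(t_burst) / (P(0) − P(t_adsorb)): progeny per
adsorbed phage. The choice of t_burst matters more than it looks. Cells
infected during the adsorption window [0, t_adsorb) finish lysing by
L + t_adsorb; any later sample also contains progeny of cells infected
*after* the window, which are not in the denominator, inflating B by
roughly A(t_burst − L)/A(t_adsorb) (A = cumulative adsorption). The
default is therefore the last sample strictly before
(detected latency + t_adsorb). Two alternatives are provided: an
explicit `t_burst` override (e.g. a conventional fixed read near 26 min)
and a `plateau_mid` strategy (midpoint of the first run of ≥ 2
consecutive post-rise samples with |Δlog₁₀| < 0.1) for a literal
"after the first burst" plateau read; both are biased upward whenever
adsorption is still ongoing at the read time, which is why neither is
the default. A legacy quotient, (P(t_burst) − P(t_adsorb)) / P(0), used
by some older characterizations, is available for comparison as
`estimate_burst_size_legacy`.

Display rounding follows the field's reporting style: MOI to 2
decimals, k to 2 significant figures, B to the nearest integer.
Unrounded values are always carried in the report object.

## Infection simulator

State: free phage P, susceptible S, infected-intact I, lysed cells, in
a well-mixed volume with no bacterial growth over the ≤ 1 h experiment
(S + I + lysed is conserved).

Dynamics: dP/dt = −k(S+I)P; infections accrue at kSP. That is, phage
adsorb to *any intact cell* — receptors on an infected cell still bind
phage — but only first infections are productive (superinfection
contributes nothing). Two consequences are deliberate:

- free phage decay exactly as exp(−kN₀t) before the first lysis, so
  the two-point estimator is exact on noiseless simulated data;
- the burst quotient is a few percent low at moderate MOI because the
  denominator counts adsorbed phage while progeny come from infected
  cells: at MOI 0.14 about 5% of early adsorptions land on
  already-infected cells, giving a recovered B of ~12.4 when the
  simulated per-cell burst is 13. This is a real bias of the
  estimator, not of the simulator, and is left visible.

Each infected cell lyses a latency period after infection, releasing
`burst_size` progeny. With `secondary_infection=False` progeny remain
observable free phage but do not re-adsorb (one-step conditions); with
`True` they join the adsorbing pool and drive subsequent rounds.

**Deterministic mode** (latency_cv = 0) is a cohort recursion on the
sampling grid: within each interval the (P, S, I) ODEs are integrated
by RK4 with 32 substeps, the cells infected in the interval form a
cohort, and the cohort lyses together ceil(L/Δ) intervals after the
interval start. Releases scheduled at a sample time are applied before
the sample is recorded. This grid-synchronized convention is what makes
the detected latency equal the true latency rounded up to the grid and
the default burst read exact. Cell and phage balances hold structurally
(infections are computed as S-before − S-after), to ~1e-15 relative.

**Stochastic mode** simulates integer counts in `volume_ml` of culture
(an explicit field, since concentrations alone do not define counts):
adsorption propensity k(S+I)P/V as an exact event process, per-cell
lysis delays drawn from a gamma distribution parameterized by mean and
CV. CV = 0 degenerates to the fixed delay with the same grid
synchronization as the deterministic mode, so the two agree in mean
trajectory (verified to within 3 Monte-Carlo standard errors over 500
replicates at 10⁵ cells). Above ~10⁶ expected events a tau-leaping
integrator (Poisson adsorption increments on Δ/20 substeps, lysis
aggregated into grid bins) takes over; the threshold is configurable.

**Plating noise.** Observed count ~ Poisson(titer × dilution ×
plate volume); reported titer = count / (dilution × plate volume).
Either a fixed dilution or a per-point automatic 1:10 serial dilution
targeting a minimum expected count (emulating reading the countable
plate of a dilution series) can be used. Replicate experiments are
averaged in log₁₀ space (geometric mean), the natural scale for counts
spanning decades.

## Synthetic genomes

Background bases are i.i.d. with P(G) = P(C) = GC/2, so the realized GC
of an n-base genome has binomial spread √(GC(1−GC)/n) (±0.23
percentage points at n = 46,150). Planted features are written
literally: promoters as TTGACA + 17 random nt + TATAAT; RBS-ORF
cassettes as AGGAGG + 5–9 nt spacer + ATG + non-stop codons + TAA, with
an in-frame TAA placed at the end of the spacer so the planted ATG is
provably the longest-start variant for its stop; restriction sites as
their recognition strings. Rejection resampling redraws any background
(or redrawable in-feature) bases that accidentally form a recognition
site for a *planted* enzyme, so planted-site counts are exact.
Features may not overlap; collisions are an error, not silently moved.

What the generator does **not** emulate: codon bias, operonic
structure, repeated regions, real promoter/RBS degeneracy beyond the
mismatch budgets, sequencing error, or coverage artifacts. Scanner
tests on planted genomes therefore demonstrate coordinate-exact
recovery of consensus motifs and correct digestion arithmetic — not
annotation accuracy on real phage genomes, where weight-matrix tools
and gene finders trained on real data will differ.

## Restriction analysis

Recognition sites are IUPAC patterns matched on the top strand with
overlaps; N in the sequence never matches. The built-in enzymes
(SacI GAGCT^C, ApaI GGGCC^C, XhoI C^TCGAG, EcoRI, BamHI, HindIII) are
palindromic, so top-strand matching counts each physical site once.
Both the recognition-site start and the top-strand cleavage coordinate
(cut falls after the reported base) are exposed, since published
"cutting at position x" statements rarely say which convention they
use; fragment lengths are insensitive to the choice when the enzymes
share a cut offset. Circular sequences are scanned with a wrapped
prefix of pattern-length − 1 and hits de-duplicated modulo the length.
Circular digestion returns one arc per cut; linear digestion returns
cuts + 1 fragments; lengths always sum to the sequence length.

Headful packaging is modeled as: virion i is the linear arc of
`headful_length` bases starting at (pac + i × headful) mod L — the
processive series from a single initiation, which after many rounds
yields molecules of identical length with termini distributed around
the circle. Digesting each virion linearly and pooling fragment
lengths reproduces the diagnostic pattern: internal arcs between cuts
appear as sharp bands while terminal fragments take many lengths (a
smear), and every virion's fragments sum to the headful.

## Feature scanning conventions

Coordinates are 1-based, inclusive, on the forward axis, with a strand
flag. Promoter hits report the forward span plus the strand-oriented
5'-most base of each hexamer; spacer defaults to exactly 17 nt
(configurable range) with ≤ 2 total mismatches over both boxes. The
expected background rate under this rule is the binomial tail
P(Binomial(12, 3/4) ≤ m mismatches) per position and strand — about
3.8e-5 for m = 2, i.e. a handful of hits per 100 kb, and ~6e-8
(essentially none) for exact matches. RBS search accepts contiguous
substrings of AGGAGG of length ≥ 4 whose 3' end lies 5–9 nt upstream of
the start codon, preferring longer then closer matches. ORF calling
reports one ORF per stop codon (earliest in-frame start after the
previous stop), both strands, complete ORFs only, with a default
minimum of 90 nt; with RBS gating on, an ORF is a gene call only when
an RBS is found. The terminator heuristic (perfect inverted repeat,
stem ≥ 5, loop 3–10, ≥ 4 T in an 8-nt window within 3 nt downstream,
score 3·GC + 2·AT + U − loop) is a stated artifact rule: its counts are
not expected to match weight-matrix servers trained on real
terminators.

## Phylogenetics

p-distance = mismatches / compared sites with pairwise deletion (gaps
and ambiguity codes excluded per pair; complete deletion available).
Neighbor joining is the standard Saitou–Nei agglomeration; ties in the
Q criterion are broken by the lexicographically smallest pair of
cluster labels (each cluster keyed by its smallest leaf), which makes
output deterministic and taxon-order invariant. Negative branch
lengths are clamped to zero and flagged. The tree is unrooted,
represented with a trifurcating root. On additive matrices the
reconstruction is exact (path lengths reproduce the input to < 1e-9 up
to 12 taxa in the test suite, and the implementation is cross-checked
against an independent NJ implementation). p-distance is not a metric;
triangle violations are permitted and only affect branch lengths
through clamping.

Bootstrap: columns resampled with replacement, p-distance + NJ per
replicate, support of each internal bipartition of the full-data tree
= percentage of replicates containing it; replicates whose distance
computation fails (a pair with no comparable sites) are skipped with a
warning and removed from the denominator — simpler and more
transparent than resampling until success.

Percent identity uses affine-gap global alignment (match +5, mismatch
−4, gap open 10, gap extend 0.5 — common aligner-style defaults, all
configurable since published identity figures rarely state their
scoring). Identity = identical aligned positions / alignment length.
Above 10 kb the quadratic-memory affine aligner is not viable and a
linear-memory global aligner with unit costs takes over (documented
discontinuity; inputs above 100 kb are refused). Identity percentages
between distantly related genomes should be treated as ordering
information, not precise statistics, as they depend on these choices.

Newick output carries branch lengths at 6 significant figures and
integer bootstrap supports as internal labels, and round-trips through
the bundled reader; output is parseable by standard readers.

## Problem sizes and reproducibility

Defaults and test problem sizes were chosen as the package's own
demonstration scale: 2-min sampling over 60 min; 3×3×3 recovery grids
over k ∈ [4e-10, 1.7e-9] mL·min⁻¹, L ∈ [10, 20] min, B ∈ [5, 40];
stochastic/deterministic agreement at 10⁵ cells × 500 replicates;
bootstrap saturation at 8 taxa × 200 columns × 500 replicates; digestion
conservation over 1,000 random sequences. Every random draw flows from
one integer seed (numpy SeedSequence spawning separates the dynamics,
plating, genome and bootstrap streams), so identical configuration +
seed gives byte-identical outputs; provenance records deliberately omit
timestamps for the same reason.

## Known limitations

- No ODE fitting to whole curves: only the two-point/quotient
  estimators the workflow defines. No media or divalent-ion effects on
  adsorption.
- Burst-size estimates inherit the superinfection bias described above;
  at MOI ≫ 0.1 the quotient increasingly understates the per-cell
  burst (and multi-phage infection effects on burst size are not
  modeled at all).
- The OD proxy counts intact cells only; debris scattering is ignored,
  so simulated OD drops are sharper than turbidimetric reality.
- Consensus scanners are rule-based; they are validated against
  planted ground truth, not against curated annotations.
- Bacterial growth during the experiment is ignored (switchable only by
  regenerating the culture parameters; no growth term is integrated).
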
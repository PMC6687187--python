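# Methods

`latticetumour` simulates the growth of a tumour as a stochastic cellular
automaton on a 2D or 3D lattice, generates multi-region bulk and
single-cell sequencing data from the final tumour, computes the standard
observables of cancer population genetics (VAF spectra, the 1/f² neutral
tail, tree-shape statistics, spatial intermixing), and recovers the
model's evolutionary parameters from such data with ABC-SMC. This note
records the model, the numerical choices, and what the scaled-down test
conditions do and do not establish.

## Growth model

Cells occupy single sites of a square/cubic lattice (default extent 400
per axis in 2D) and divide and die as independent exponential channels:
per cell type (wild type or mutant) the birth channel has rate `b·x` and
the death channel `d·x`, where `x` is the count of that type. Events are
scheduled by the next-reaction Gillespie method — one exponential clock
per channel, the smallest wins, and the global clock advances by it. The
clock unit is raw Gillespie time; dividing by log 2 converts to
population doublings. With `b = 1, d = 0` the expected population grows
as `N(t) = e^{(b−d)t}`.

A division replaces the parent with one daughter in place and must find a
site for the second. If any of the 8 Moore neighbours (26 in 3D) is
empty, one is chosen uniformly. Otherwise the parent may *push*: a
uniformly chosen lattice direction is drawn, the contiguous run of cells
from the parent along that ray shifts one site outward, and the daughter
takes the freed adjacent site; if the ray is occupied all the way to the
grid edge the attempt — and the division — fails (the cell is
"imprisoned"; the event still consumes clock time because channel rates
depend only on cell counts, not on available space). Push permission
implements the boundary parameter `a ∈ [0, 1]`: with the default
deterministic rim rule a parent at Chebyshev radius `r` from the founder
site may push iff `(R − r) ≤ a·R`, where `R` is the current maximal
radius over live cells. `a = 0.2` therefore creates a proliferative rim
of width exactly 20 % of the tumour radius; `a = 1` lets every cell push
(homogeneous growth, exponential); `a → 0` confines proliferation to the
front, giving polynomial growth (`N ∼ t^dims`) and gene-surfing
patterns. A `push_rule="bernoulli"` variant (push permitted with
probability `a`) is provided because the verbal description of the
parameter admits both readings; the rim rule is the default because it
reproduces the 20 %-rim statement exactly.

Each division draws `Pois(u)` brand-new mutation ids — infinite sites, no
back mutation — and assigns them to **both** daughters. Internally the
new ids sit on a shared *division node* of the lineage tree, below which
each daughter starts its own mutation-free genotype node; every id
belongs to exactly one lineage edge, and a cell's genotype is the union
of blocks on its root path. The shared-assignment convention is what
creates truncal mutations (the first division's ids are carried by every
cell even without cell death) and hence the clonal cluster at VAF 0.5 in
diploid sequencing data. The expected number of mutations per cell is
`u × (generations undergone)`, and the subclonal tail follows
`M(v) = u(1/v − 1/v_max)` in VAF units under neutral exponential growth
(u mutations per division at cellular fraction ≈ 2/N when arising at
population size N).

At the first event time at or after `t_driver` one uniformly chosen
wild-type cell becomes the mutant subclone founder. Its advantage `s` is
defined through `1 + s = (b_mut − d_mut)/(b_wt − d_wt)` and realised as
an increased birth rate (default), a decreased death rate, or — in
`push_increase` mode — unchanged rates with unconditional push
permission. Exactly one driver fires per simulation (a fixed driver time
keeps simulations comparable); with no wild-type cell alive at the
trigger the driver is skipped with a warning. `s = 0` turns the driver
into an arbitrary neutral lineage mark. Simulations stop when a cell
reaches the grid boundary, when an optional cell cap is reached, or on
extinction (reported, not retried; `run_with_restarts` reseeds
deterministically for callers that need completed tumours, e.g. ABC).
Treatment (`apply_treatment`) removes a uniform fraction of cells,
always sparing at least one, after which growth may resume.

All randomness of one simulation flows through a single seeded
generator, so a (parameters, seed) pair reproduces a run bit-identically.

## Sampling and sequencing

A bulk sample is a set of adjacent live cells: axis-aligned squares
("punch biopsies"), long thin rectangles ("needle biopsies"), the whole
tumour, or concentric Chebyshev annuli split into N/S/E/W arcs for
centre-to-periphery profiles. The default multi-region design — six
punches at evenly spaced angles at half radius, two orthogonal needles of
thickness 3, plus the whole tumour — is a reproducible stand-in for
designs that are otherwise placed by hand. Per mutation the sample
records the exact cellular fraction (count / sample size) and a clone
annotation: truncal (in every live cell), subclone-founding (present in
the first mutant cell), background (absent from the mutant), subclone
(exclusive to it), or shared.

Sequencing draws per-mutation depth from `Poisson(Z)` (zero depths are
redrawn; an unread site has no record) and variant reads from
`Binomial(depth, n/2)` for cellular fraction `n` — the pure-diploid
heterozygous convention, so clonal mutations cluster at VAF 0.5; the
binomial success probability is configurable (`ploidy="haploid"` uses
`p = n`). Mutations with fewer than `min_alt = 5` variant reads are
discarded, an analytic detection floor of `min_alt/Z = 0.05` at the
default 100×. Single-cell WGS returns exact binary genotypes (an
allele-dropout probability exists but defaults to 0); genotyping
restricts the matrix to the mutations of one reference bulk above a VAF
floor, reproducing the branch-length biases of bulk-guided single-cell
assays.

## Summaries

The cumulative subclonal spectrum `M(f) = #{VAF ≥ f}` (VAFs ≥ 0.35 are
treated as the clonal band) is fitted by least squares to
`M(f) = μ(1/f − 1/f_max)` on the window [0.05, 0.25]; `μ̂` estimates the
mutation rate per effective division (exact when `d = 0`). The AUC
neutrality statistic is the area between the empirical and theoretical
cumulative curves, both normalised to 1 at `f_min` (the theoretical
curve reaches 0 at `f_max`, the empirical need not — this keeps a
subclonal cluster's excess mass visible; a both-endpoint normalisation
absorbs it and was measured to have essentially no power against
selection). The p-value is an upper tail over parametric neutral
resamples at the observed mutation count; each resample reapplies the
binomial read noise at the nominal depth, without which the null is too
tight and neutral simulations are over-rejected. An optional
`block_size` reproduces the burst structure (Pois(u) mutations per
division share one lineage frequency). p < 0.05 rejects neutrality;
cohort-level verdicts, not individual p-values, are the meaningful
output.

The power-law exponent is the negated slope of log binned density vs
log VAF. Its default window [0.10, 0.30] starts two read-noise standard
deviations above the detection floor: sub-floor mutations whose noisy
VAFs leak upward otherwise bias the density slope from 2 to ~2.8. A
single tumour's window holds only ~50–70 mutations, giving the binned
slope a sampling SD of ~0.5, so cohort statements pool tumours (and
sequencing replicates).

Moran's I over occupied sites with Moore-neighbour weights quantifies
clonal intermixing (permutation p-value; undefined and raised as an
error for single-clone tumours; its permutation-null mean −1/(N−1) is
used as an internal calibration check).

## Phylogenies

Under infinite sites without back mutation, maximum parsimony on a
noise-free genotype matrix is the perfect phylogeny, which is built
directly: mutation columns are clustered by identical cell membership,
ordered by support with lexicographic tie-breaks, and nested into a
trie; edge lengths are cluster sizes, and a cluster private to one cell
becomes that cell's terminal edge. Conflicted matrices (possible only
with noise knobs on) reuse the same greedy ordering. The independent
oracle `true_sampled_tree` restricts the simulator's lineage to the
sampled cells, suppressing unary nodes and keeping recorded division
times; on noise-free WGS matrices the two constructions agree at
Robinson–Foulds distance 0. Balance indices follow the standard
definitions (Sackin = sum of leaf depths; Colless on seeded random
binary refinements of multifurcations, mean ± SD over 100 draws; Yule
and PDA normalisations by the usual formulas), plus cophenetic tip
distances, MRCA-depth statistics, branch-length statistics and maximum
node depth. Bulk-tagged trees get an intermixing score: the fraction of
cross-bulk leaf pairs closer than the median same-bulk pair, with a
permutation p-value.

## Inference

θ = (u, t_driver, s, d, a) carries uniform priors u ~ U(0, 100),
t_driver ~ U(0, 15), s, d, a ~ U(0, 1), all overridable and any subset
fixable. Four summary schemes mirror the sampling strategies:
multi-bulk VAF histograms compared by Euclidean distance (100 bins on
[0, 1], per-bulk normalised, concatenated), whole-tumour VAF vectors,
and single-cell tree branch-length or branching-time vectors, the last
three compared by order-1 Wasserstein distance between empirical
distributions with uniform weights (implemented from the quantile-
function definition; cross-checked against an independent implementation
in the tests). Branching times come from recorded division times when
the target is simulator-generated and fall back to mutation-depth
proxies (with a warning) on reconstructed trees.

Rejection ABC draws `N/Q` prior samples and keeps the top quantile `Q`,
so every SMC round carries `N` particles. Later rounds resample from the
previous accepted set by weight, perturb each free parameter with a
uniform kernel of half-range `σ_i = (max_i − min_i)/2` over the previous
round's accepted values (out-of-prior proposals are re-perturbed),
accept at distance < ε, reweight by `π(θ)/Σ_l W_l K(θ|θ_l)` with the
product uniform-kernel density, and shrink ε to the Q-th percentile of
accepted distances. Round-1 weights are all 1; ε is non-increasing by
construction; an effective sample size below 2 aborts with a diagnostic.
Sequential fixing repeatedly runs SMC, declares a parameter converged
when its posterior mode moved < 5 % between the last two rounds *and*
its interquartile range is below 25 % of the prior range, fixes
converged parameters at their posterior modes (KDE argmax over the prior
range), and reruns on the remainder; a preset order can reproduce the
fix-u-first schedule. Posterior modes and per-parameter percent errors
(|true − mode|/|true|·100; absolute error with a flag when the truth is
0) are the reported outputs. Per-particle seeds derive deterministically
from (master seed, round, index), so particle simulations are
order-independent and parallelisable.

`TumourSimulator` optionally runs in common-random-numbers mode
(`fixed_seed`): every simulation reuses one stochastic trajectory, making
θ → summary deterministic. At desk-scale problem sizes (10³–10⁴ cells)
the clone fraction realised for a given (t_driver, s) is dominated by
drift, and without CRN the distance carries almost no information about
the parameters at affordable simulation counts; full-scale analyses with
independent seeds marginalise over drift instead.

## Test conditions and problem sizes

The reference conditions are those of the four representative scenarios
(b = 1, u = 10; neutral/selective × homogeneous/boundary-driven; driver
times 4 and 8, s ∈ {0, 2, 3}, a ∈ {1, 0.025}; nominal sizes 80–100k
cells on a 400² grid). The test suite runs the same scenarios at reduced
cell caps (400–20 000 cells), scaling the driver time where a mid-sweep
subclone is required so that the driver enters at the same population
fraction as at full size. The parameter-recovery check uses three
selective targets (3 000 cells, 100 sampled cells, branching-time
summaries, N = 40 particles, 6 rounds, CRN) constrained a priori to
mid-sweep subclones — the regime in which selection parameters are
identifiable at all; imprisoned or fixed subclones are known to look
neutral. The synthetic test-set generator emits the 34-target inference
benchmark (13 homogeneous no-death, 11 with death, 10 boundary-driven)
with parameters drawn from the priors, truncating death rates to
[0.1, 0.6] and boundary draws to [0.01, 0.2] so every target is
simulable to completion.

What passing tests show: the implementation reproduces the model's
analytic limits (exponential and polynomial growth, channel ratios, the
detection floor, the rim geometry), its statistical signatures (1/f²
tail, clonal cluster at 0.5, mutation-rate recovery, SFS/VAF
equivalence, load–distance gradients, intermixing orderings) and
parameter recoverability under controlled, scaled-down conditions. What
they do not show: performance on real sequencing data (no copy-number
events, no purity below 1, no mapping error, single fixed driver), nor
ABC accuracy at full tumour sizes and simulation budgets with
drift marginalised over independent seeds.

## Known limitations

Diploid genomes without copy-number loss; one driver event per run;
pushing moves a single ray rather than deforming the whole neighbourhood
(no off-lattice mechanics); single-cell data are noise-free unless the
dropout knob is turned; the AUC test's null is calibrated to this
generator's noise model, so its p-values are not exchangeable with those
of other neutrality-test implementations (cohort-level verdicts are).
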
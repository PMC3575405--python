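# Methods

`argsample` implements Bayesian Markov chain Monte Carlo inference of an
ancestral recombination graph (ARG) and evolutionary parameters from an
alignment of phased, recombining nucleotide sequences. This note records
the model, the sampling machinery, the numerical choices, and what the
package's synthetic-data checks do and do not establish.

## Model

The target is the posterior

    Pr{M | D}  ∝  Pr{D | M} · Pr{M}

where `D` is the alignment and the model `M` comprises (i) an ARG — a
rooted directed graph of timed nodes in which tips sit at height 0,
coalescent nodes merge two lineages and recombination nodes split one
lineage at an inter-site breakpoint into two parental lineages — (ii)
the scaled population size θ = 2Nμ and scaled recombination rate
ρ = 2Nr, and (iii) a nucleotide substitution model (F84 or TN93) with
stationary frequencies and one or two transition/transversion
parameters. Time is measured in expected substitutions per site, so θ
also sets the coalescence time scale.

**Coordinates.** Sites are 0-based with half-open intervals internally;
a breakpoint `b ∈ [1, L−1]` routes sites `< b` to parent 0 and sites
`≥ b` to parent 1. User-facing tables are 1-based inclusive.

### Coalescent-with-recombination prior

Backward in time, with `k` extant lineages and population function
θ(t) = θ₀·e^(−g·t):

* total coalescence rate `k(k−1)/θ(t)` (each unordered pair `2/θ(t)`),
* per-lineage recombination rate `(ρ/θ₀) · gᵢ/(L−1)`, where `gᵢ` is the
  number of breakpoint gaps strictly inside the lineage's
  [leftmost, rightmost] ancestral site (Hudson-style eligible span;
  splits outside ancestral material are invisible to data and carry
  zero rate by default).

The density of a specific coalescence is `2/θ(t)` and of a specific
(lineage, gap) recombination `ρ/(θ₀(L−1))`; inter-event survival uses
the integrated total rate (closed form under exponential growth).
An ARG containing events *above* the grand MRCA — above the first time
the lineage count reaches one — has density zero: the backward process
stops there, and the MCMC must be confined to the same support (states
with extra structure stacked above the root are otherwise reachable
through kernel surgery and, being data-invisible, would accumulate
mass without bound). The simulator and the density function share one
implementation of the rate algebra, so they agree realization by
realization; this is load-bearing for all prior-equivalence checks.

Scalar priors default to log-uniform for θ (1e−6…10) and ρ
(1e−3…100) and uniform for κ (0…100); all are configurable.

### Likelihood

The full Felsenstein likelihood of the ARG is computed by pruning on
the graph itself. For a given site, a node's partial vector covers
exactly the tips whose root-ward path for that site passes the node:
recombination nodes propagate their single child vector through P(t),
and coalescent nodes multiply the vectors of the child edges that
arrive for that site. Because the substitution models are stationary
and satisfy Chapman–Kolmogorov, evaluating π·partial at the grand root
equals the sum over marginal-tree intervals of ordinary tree
likelihoods — the identity used for validation against an independent
per-site pruning implementation (agreement ≤ 1e−9 observed, tolerance
1e−6).

Identical alignment columns are collapsed once globally (column
aliasing; a pure relabeling, verified to leave the likelihood
bit-identical). Partials are stored per node per routing-constant site
range; an MCMC proposal marks the touched nodes dirty and recomputation
ascends only through their root-ward closure. Rejected proposals
restore the previous tables by reference exchange, bit-exactly. Gaps,
N and IUPAC ambiguity codes become indicator unions at the tips (fully
missing = all-ones). Partial vectors are renormalized with accumulated
log-scale factors only once ≥ 32 tips sit below a node; above that
depth every node rescales, keeping hundreds of taxa representable.

P(t) comes from a cached spectral decomposition of the symmetrized,
rate-normalized generator (exact for this reversible family; rows sum
to one to ~1e−15 and Chapman–Kolmogorov holds to machine precision).
F84 is the TN93 sub-case α_R = β(1 + κ/π_R), α_Y = β(1 + κ/π_Y).
Base frequencies are empirical alignment frequencies by default
(pseudocount ½) or uniform on request.

### Proposal kernels

Seven ARG kernels plus scalar multiplier moves:

1. **node_height** — reflected uniform window on one non-root internal
   node between its height bounds (symmetric).
2. **root_scale** — multiplier on the root's height above its higher
   child; log HR = log m.
3. **subtree_regraft** — contemporaneous subtree *exchange*: a child
   edge of a coalescent node swaps attachment with an edge crossing
   that node's height. The crossing count is invariant under the swap,
   so the move is exactly symmetric; attachment-height changes come
   from composing with kernel 1. (An SPR-with-new-height variant was
   considered and rejected: its Hastings bookkeeping is strictly harder
   and adds nothing the composition does not already reach.)
4. **add_recombination** — reversible-jump birth: pick an edge
   uniformly, a height uniformly on it, a breakpoint uniformly over the
   edge's eligible gaps, route one side (fair coin) up a new lineage
   that re-coalesces at an Exp(2/θ)-distributed height — on an edge
   drawn uniformly among those crossing it, or above the root. The
   (h_R, h_C) coordinates are proposed directly, so the
   dimension-matching Jacobian is 1; the acceptance ratio multiplies
   the prior ratio by q_death/q_birth with every factor evaluated on
   the state the reverse move sees.
5. **remove_recombination** — death of a (recombination, coalescent)
   pair chosen uniformly among removable pairs; heals both edges and
   reconstructs the reverse-birth density on the healed state. A
   "bubble at the root" (both parents of a recombination being the
   parentless coalescent) cannot be produced by a single birth and is
   auto-rejected.
6. **breakpoint_shift** — uniform integer step in ±window, auto-reject
   outside [1, L−1] (symmetric).
7. **arg_scale** — common multiplier on all internal heights;
   log HR = (number scaled)·log m.

Scalar parameters (θ, ρ, κ or α_R/α_Y) get multiplier moves; a κ/α
change invalidates every cached partial (new P matrices), θ and ρ only
re-price the prior. Window/scale parameters adapt toward ~23%
acceptance during burn-in and freeze afterwards, so detailed balance
holds over the sampled portion. Default mixture: uniform over the
seven ARG kernels with scalar kernels at half weight.

Correctness of the kernel set was established three ways: (a) exact
pairwise reversibility — the acceptance log-ratios of a birth and its
forced inverse death sum to zero to 1e−9, in both directions; (b)
fuzzed structural audits — apply/revert restores the serialized graph
and the likelihood tables bit-exactly, and incremental updates match
from-scratch recomputation to 1e−9; (c) replica stationarity — chains
started at exact simulator draws and run a fixed number of steps retain
the simulator's distributions of breakpoint count, root height and
single-site TMRCA, per kernel and for the full mixture.

### Chain engine

Metropolis–Hastings–Green acceptance
min(1, exp((Δlog-lik + Δlog-prior)/T + log HR)); a NaN in either
density aborts with the kernel name and step number. Metropolis
coupling uses a geometric ladder T_i = (1+λ)^{i−1} (λ = 0.1) with
adjacent-pair swap proposals on a fixed schedule; chains execute
sequentially, only the cold chain is sampled, and a fixed seed gives a
bit-identical trace. Burn-in defaults to the first 50% of steps. The
convergence report (advisory only) compares data-likelihood means and
standard deviations between adjacent quartiles of the post-burn-in
trace. `restart_from_best` re-launches a run from the stored
maximum-posterior ARG, ties resolved to the earliest step.

The chain is initialized at a coalescent tree simulated at ρ = 0 with
θ set from Watterson's estimate when data are attached (a data-informed
but likelihood-free start), or at a user-supplied ARG.

### Collectors

* 2-D breakpoint histogram over (site, node height), default 100 × 50
  bins, overflow heights clamped into the top bin so counts conserve.
* Per-site TMRCA accumulator storing exact samples up to 10⁵ sampled
  ARGs, then reservoir-subsampling (quantiles stay unbiased with
  bounded memory).
* Strict-majority-rule consensus trees (a clade kept iff present in
  more than half the trees; exactly half is dropped), support =
  frequency, heights = means over supporting trees.
* ESS via N/(1 + 2Σγ̂) with Geyer's initial monotone positive sequence
  truncation; constant or <10-point traces are reported as undefined
  rather than guessed.

All collectors merge exactly (merge of two accumulators equals
accumulation of the concatenated stream).

## Synthetic data

`SimulationSpec` defaults (n = 10, L = 10,000, θ = 0.02, ρ = 1.0,
constant population) are the package's reference study conditions for
simulated-data work. The backward simulator tracks ancestral material
per lineage, draws breakpoints uniformly over eligible gaps and stops
at the grand MRCA; `emit_non_ancestral` additionally generates
material-free splits for demonstrations of the undetectable classes.
Sequences evolve down the ARG itself (root states from π, one P(t)
draw per edge per site), so linked sites are correlated exactly as the
graph dictates; a per-marginal-tree independent mode reproduces the
classical one-tree-at-a-time pipeline.

What these data do not emulate: selection, migration or population
structure, gene conversion, variable recombination or mutation maps,
sequencing error, and unphased or missing genotypes beyond literal N/-
columns. Passing the test battery therefore certifies the sampler
against its own generative model — the standard neutral coalescent
with recombination — not against demographic or technical artifacts in
real data.

## Problem sizes used by the test battery

The statistical checks run at desk scale, chosen so the full suite
completes on one CPU in well under half an hour while keeping each
test's discriminating power (the negative controls — a doubled
Hastings ratio, a shifted breakpoint — fail decisively at these sizes):

* likelihood-sum oracle: 50 random ARGs, n ≤ 8, L ≤ 1000;
* prior equivalence: n = 10, θ = 1, ρ = 1, L = 1000, 4×10⁵ steps,
  1000 samples per side (plus a ρ = 0 closed-form mean check);
* single-site TMRCA: n = 10, L = 500, ρ ∈ {0, 1, 5}, 2.5×10⁵ steps;
  KS tests at p > 0.01 with up to three disjoint-seed attempts (a
  correct sampler fails a p > 0.01 gate about 1% of the time);
* incremental-likelihood audit: 1000 fuzzed proposals;
* parameter recovery: 5 datasets at n = 10, L = 4000, θ = 0.02,
  ρ = 1.0 with 1.2×10⁵-step chains; 95% credible intervals must cover
  the generating values in ≥ 4/5 replicates per parameter (the same
  80% fraction as the full-scale 8-of-10 design);
* undetectable recombinations: the constructed three-class ARG (trivial
  bubble, non-ancestral split, detectable breakpoint) plus a 6×10⁴-step
  inference on sequences simulated from it.

## Known limitations

* Single panmictic population; no migration or multiple-population
  models.
* ρ constant across sites and time; no hotspot map.
* No rate heterogeneity across sites (Γ) and no codon/amino-acid
  models.
* Mixing degrades at high ρ (the breakpoint count is heavy-tailed and
  per-site tree space is large); long runs with heavy thinning, or
  Metropolis coupling, are recommended there.
* The marginal-tree extractor and collectors assume a fully phased
  alignment; unphased diploid VCF input is rejected rather than
  phased heuristically.
* VCF `region_fill` mode needs an explicit reference sequence for the
  region to reconstruct monomorphic columns; without one those columns
  are imported as missing, and `variant_only` mode records the
  invariant-column count instead.
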
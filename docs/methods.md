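# Methods

## From contests to interaction strengths

The pipeline's raw input is a species-contact matrix: counts of wins
`W_ij` (species *i* overgrew species *j*), draws `D_ij` (symmetric), and
colony abundances `B_i`. The energy-loss web is the weighted outcome sum
`f_ij = p_W W_ij + p_L L_ij + p_D D_ij` with `L_ij = W_ji`. The default
costs per colony per unit time are `p_W = −0.1`, `p_L = −0.9`,
`p_D = −0.2`: losing (being overgrown) is by far the most expensive
outcome, winning costs little, drawing costs both parties a little. All
three are exposed, and the sensitivity sweep recomputes the whole chain
under alternative allocations, reporting Spearman rank agreement of `s*`
across scenarios — the claim being tested is that *relative* stability is
insensitive to the split. A positive cost is rejected: the loss web is
defined as a matrix of non-positive flow rates, so the draw cost is
negative even though a draw is sometimes loosely described as costing
"0.2".

Intraspecific contests need two conventions. Each recorded overgrowth
event within species *i* is simultaneously one win and one loss for that
species, so it contributes `p_W + p_L`; each intraspecific tie affects two
colonies of the species but is recorded once, so the tie count is doubled.

With unit colony biomass, equating observed loss rates with the
Lotka–Volterra competition terms at steady state eliminates the growth
rates and competition coefficients, leaving `a_ij = f_ij / B_j` — the
per-capita effect (1/time) of species *j* on species *i*. The
Lotka–Volterra symbols never appear at runtime; only the ratio survives.

**Diagonal filling.** Rare species often show no intraspecific contests,
leaving `a_ii = 0`, which would make self-regulation-relative metrics
undefined. Unobserved diagonals are set to `diag_fill_factor` (default
0.1) times the mean Jacobian element and flagged. The mean is taken over
the non-zero entries of the pre-fill matrix: averaging over all S² cells
would make the fill value depend on connectance through structural zeros.
A `fill_mean_includes_zeros` switch implements the other reading, and the
sensitivity sweep accepts a list of fill factors, so the insensitivity of
the qualitative pattern to this choice is checkable rather than assumed.

**Normalisation.** Dividing each row by |a_ii| gives the community matrix
`Ā` with uniform diagonal −1. All matrix manipulations operate on `Ā`, so
they cannot disturb the diagonal structure.

## Critical self-regulation

`s*` is the smallest s ≥ 0 at which the matrix with diagonal scaled by s
has dominant eigenvalue zero. The numeric route expands a bracket
geometrically from s = 1 (doubling upward while unstable, halving
downward while stable; the zero-diagonal matrix has zero trace, so its
dominant real part is ≥ 0 and a downward bracket always exists) and then
bisects `Re(λ_d)` to a tolerance of 1e−8 by default. Bisection assumes
the stability indicator crosses zero once along the bracket; this is not
guaranteed in general, so after convergence the sign is verified at
`s*(1 ± 10·tol)` and a 4001-point grid scan re-brackets the smallest
crossing if verification fails (never observed on competition matrices in
the test ensembles, but cheap insurance). `|Re λ_d| < tol` at s = 1 is
reported as `s* = 1` with a `marginal` flag.

For a normalised matrix the rescaled matrix is `Ā₀ − sI`, so `s*` equals
the dominant eigenvalue of `Ā₀` exactly — no search needed. When a
Jacobian source is supplied the two routes are compared and a relative
gap above 1e−3 triggers a warning; the test suite checks agreement to
1e−6 relative on random matrices of 2–11 species.

## Loop weights

`w^(k)` is the geometric mean of link magnitudes around a simple directed
cycle, scaled by the members' self-regulation terms — equivalently, the
plain geometric-mean cycle magnitude of the normalised matrix, which is
how it is computed (making the spectrum normalisation-invariant by
construction). Per length, the *maximum* over cycles is reported. The
exact search is a dynamic programme over vertex subsets in log-magnitude
space (−∞ for absent links, avoiding underflow on long loops): paths are
anchored at their lowest-index member, so each directed cycle is counted
once per direction; a cycle and its reverse are distinct unless their
weights coincide. Exact up to 20 species (comfortable for the 5–11 range;
cost grows as ~2^S). Larger systems fall back to uniform random cycle
sampling, flagged `sampled` and interpreted as a lower bound. An
independent oracle enumerates all simple cycles via
`networkx.simple_cycles` and must agree with the DP on every length —
this dual route is exercised over hundreds of random matrices in the
tests. Sums of loop weights over disjunct loop combinations
(Levins-style total feedback) are deliberately not computed.

## Hierarchy metrics

*Pairwise asymmetry* averages the stronger/weaker magnitude ratio over
reciprocal pairs; pairs with a one-sided zero are excluded and tallied
(a signed ratio is ill-defined there). *Community asymmetry* maximises
the below/above-diagonal mean-magnitude ratio over species orderings:
exhaustive (vectorised over permutation batches) up to 9 species
(9! ≈ 3.6×10⁵), and a steepest-ascent hill-climb over pairwise
transpositions from 50 restarts — seeded at the dominance-rank order,
i.e. species sorted by inflicted-minus-suffered loss — beyond that,
flagged `heuristic` as a lower bound. On 200 random 5–7 species
instances the heuristic recovers the exact optimum in ≥95% of cases
(test-enforced). The *win index* is the mean dominant win share
`max(W_ij, W_ji) / (W_ij + W_ji)` over pairs with decisive contests;
draw-only pairs are excluded rather than scored 0.5, with the exclusion
count reported. The *intransitivity score* is an operational triad
census on the dominance digraph (`|a_ij| > |a_ji|` ⇒ j dominates i):
1 − 2·(fraction of transitive triads among complete triads), −1 for a
linear hierarchy, +1 for rock–paper–scissors. It is labelled an
operational variant and makes no claim to reproduce any published
intransitivity index.

## Manipulations and random matrices

All manipulations preserve the zero pattern, the diagonal (−1) and the
multiset of non-zero off-diagonal values — checked on every output in the
tests. *Full* randomisation permutes all non-zero values over the
non-zero positions. *Weak* keeps reciprocal value-pairs intact but
reassigns them to random position-pairs with random orientation (2-link
loops preserved; orientation is randomised because the *minimal* mode is
defined as "weak with preserved orientation"). *Minimal* additionally
keeps each pair's above/below-diagonal orientation, which preserves the
below/above value multisets and hence the community asymmetry at the
source ordering. *Restore-pairwise* re-pairs the sorted value multiset
strongest-with-weakest — the pairing that minimises the maximum 2-link
product, verified against brute force over all pairings in the tests —
at random positions and orientations; *restore-community* then flips
every pair's stronger member below the diagonal. Ties in magnitude sorts
are broken by stable order of first appearance.

Random competition matrices draw every link as −|Normal(0, σ)| with
σ = 0.8 by default, diagonal −1, and activate unordered pairs
independently with probability C (expected, not exact, connectance).
`asymmetric` pairing couples the sorted draws strongest-with-weakest,
`symmetric` couples adjacent ranks, `independent` draws the two link
values of a pair separately. The threshold curve reports, per S, the
largest C at which at least a cutoff fraction (default 5%) of a
≥20-matrix ensemble is stable.

## Synthetic assemblages

The generator emulates contest data from disturbance-structured sessile
assemblages: 5–11 species, connectance target 0.9, near-transitive
hierarchies, and weak competitors that dominate numerically. Species get
distinct ranks; the higher-ranked member of a pair wins a decisive
contest with probability `logistic(beta·Δrank)`, so a single knob spans
coin-flip (`beta = 0`) to deterministic (`beta ≳ 4`) hierarchies — the
simplest mechanism generating the observed continuum. Defaults: S = 8,
beta = 1.5, draw probability 0.2, ~20 contests per average pair,
log-abundance slope −0.25 per ability step around a geometric mean of 20
colonies (negative slope ⇒ strong competitors rare), intraspecific
contest rate 0.05 per colony so rare species frequently lack diagonal
estimates. Under the defaults the ensemble win index lands in the
empirically observed 0.63–0.96 envelope in well over 80% of draws
(test-enforced).

What the generator does *not* emulate: spatial structure, colony growth
and size asymmetry, temporal dynamics, observation effort differences
between assemblages, and any taxonomic identity of species. Passing
ensemble tests therefore show that the pipeline's conclusions follow from
rank-structured contest statistics with realistic sampling noise — not
that any particular field system satisfies the model's assumptions.

## Pipeline and problem sizes

`analyze` records per assemblage: S, connectance, `s*` (numeric route),
`Re(λ_d)`, `w²max`, the asymmetry indices on the normalised matrix, the
win index, the intransitivity score, and the number of filled diagonals,
stamping every record with a hash of the configuration; with ≥3
assemblages it fits an OLS regression (with intercept) of `s*` on
`w²max`. `randomization_experiment` uses the normalised-shortcut `s*`
(exact at diagonal −1) for speed, computes loop spectra on at most 50
replicates per kind, and includes the source record in each ensemble
regression. The acceptance script uses 30 assemblages (the study's
count), 300 randomisation replicates per manipulation and 100-matrix
pairing ensembles — sizes at which the reported medians and fractions
are stable across seeds while the full run stays under a minute.

## Known limitations

- Community-asymmetry values above 9 species are heuristic lower bounds.
- The sampled loop-weight fallback (S > 20) is a lower bound without an
  error estimate.
- `s*` assumes diagonal rescaling can stabilise the matrix; a matrix
  violating this raises rather than returning a value.
- The win index operationalisation (dominant share of decisive contests)
  matches the documented range of the published index but was not
  validated against its original definition.
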
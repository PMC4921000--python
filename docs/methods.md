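# Methods

## Model

Single-site evolution is a time-homogeneous, continuous-time Markov chain
on a finite alphabet: the 61 sense codons of the standard genetic code, the
20 amino acids, or an arbitrary toy set. The generator *Q* has non-negative
off-diagonal rates, diagonal `Q_ii = -Σ_{j≠i} Q_ij`, and stationary
distribution π with `πQ = 0`. Every generator the package constructs is
normalized to unit stationary flux, `Σ_i Σ_{j≠i} π_i Q_ij = 1`, so time is
measured in expected substitutions per site throughout.

Mechanistic codon model (M0): for codons differing at exactly one
nucleotide position, `Q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]`;
all other off-diagonal entries are zero. Transitions are A↔G and C↔T;
synonymy follows the standard genetic code. The proportionality constant is
fixed entirely by the flux-1 normalization (no separate rate multiplier is
exposed). The construction satisfies detailed balance, so the supplied
codon frequencies are the stationary distribution by construction.

Empirical models are read from PAML-style files: a lower-triangular
symmetric exchangeability block `s_ij` followed by equilibrium frequencies,
giving the reversible generator `Q_ij = s_ij π_j`. The published WAG
amino-acid matrix is bundled (`src/sitemix/data/wag.dat`, PAML order,
permuted internally to the package's alphabetical amino-acid order).

Among-site rate variability: each site carries a time-constant rate *r*
drawn either from the mean-one gamma density
`ρ(r) = (α^α/Γ(α)) e^{-αr} r^{α-1}` (variance 1/α) or from a finite
(rate, weight) mixture. A site of rate *r* propagates as `e^{rtQ}`; the
population-level observable is the ensemble average
`P̃(t) = E_r[e^{rtQ}]`. The default shape is α = 0.286, a value typical of
estimates across protein families; the worked two-class mixture is
(0.5, 1.5) with equal weights. Rates constant in time (no heterotachy),
sites independent, stationary ancestral states — these are the standard
premises of rate-heterogeneous phylogenetic models, and all results here
inherit them.

## Numerical evaluation of the ensemble average

Two independent routes, used as mutual oracles in the tests:

* **Spectral** (default, reversible generators): with D = diag(π), the
  similarity transform `D^{1/2} Q D^{-1/2}` is symmetric, so `Q` has a real
  non-positive spectrum and an orthogonal eigenbasis. Each eigenvalue λ maps
  through the gamma Laplace transform `E_r[e^{rtλ}] = (1 − tλ/α)^{−α}`,
  which is real and well-defined because tλ ≤ 0. Non-reversible input is
  rejected with a pointer to the quadrature route.
* **Quadrature**: generalized Gauss–Laguerre integration matched to the
  weight `x^{α−1} e^{−x}` (after the substitution x = αr), which absorbs
  the integrable singularity at r = 0 when α < 1. Default 128 nodes with a
  node-doubling convergence check at 1e-8; non-convergence is an error, not
  a silent result.

Matrix exponentials use scipy's scaling-and-squaring Padé implementation;
matrix logarithms and non-integer powers use the principal branch, with a
hard error if the spectrum touches the closed negative real axis or if the
imaginary residue of the logarithm exceeds 1e-9. Propagator rows are
clipped of sub-1e-9 negative round-off and re-closed to sum exactly to 1.

## Diagnostics

* **Expected identity** `I(t) = Σ_i π_i P_ii(t)`; for codon models an
  amino-acid-level variant (counting synonymous changes as identity) is
  also exposed. For reversible models the diagonal of P(t) is completely
  monotone, so I(t) decreases strictly from 1 to Σπ² and the
  identity-to-time inversion is a bracketed Brent search (identity residual
  < 1e-10; bracket grown by doubling, capped at 50 substitutions/site,
  with an error naming the attainable range otherwise).
* **Matched-identity comparison**: Markov and ensemble propagators are
  compared entry by entry at the times where each reaches the same expected
  identity, stratified by the nucleotide-difference class (codons: Hamming
  distance of the triplets; amino acids: minimum over coding-codon pairs).
  Per-class summaries use geometric-mean ratios with structural zeros
  excluded.
* **Chapman–Kolmogorov test**: `P̃(t)` versus `[P̃(t₀)]^{t/t₀}` (principal
  logarithm/power). For a point-mass rate law the deviation is zero to
  numerical tolerance; for any non-trivial mixture it is not. Because
  `log(P̃(t₀))/t₀ → Q` as t₀ → 0, the power mimics a Markov propagator for
  a slightly perturbed generator — the report therefore also gives its
  Frobenius distances to the pure-Markov P(t) (closer) and to P̃(t)
  (farther).
* **Lumpability**: the full chain on (rate class × state) is lumped onto
  states by summing over rate classes. The Kemeny–Snell criterion requires
  equal block-to-block transition sums from every source in a block; since
  one step of duration dt is block-diagonal with blocks `e^{r_c dt Q}`, the
  reported deviation is `max_{i,j} (max_c − min_c) [e^{r_c dt Q}]_ij`. It
  vanishes iff all class rates coincide and decays as O(dt), checked by a
  dt-halving test.

## Naive re-inference and flux fractions

Analyzing ensemble data as Markovian recovers the apparent generator
`Q̃ = log(P̃(t̃))/t`, where by convention `t` is the time at which the
*Markov* dynamics reaches the identity that the ensemble shows at `t̃` —
the time a Markov observer would actually infer. Small negative
off-diagonal entries of Q̃ (an artifact of the logarithm) are retained and
reported; flux fractions use absolute flux,
`f_k = Σ_{class k} π_i |Q̃_ij| / Σ_{j≠i} π_i |Q̃_ij|`, so the partition
f₁+f₂+f₃ = 1 stays well-defined. Generator normalization cancels in the
ratio (asserted by test).

## Simulator

The fixture generator draws ancestral states from π and each descendant
from the exact finite-time row `e^{r_s t Q}[i_s, :]` — for reversible
generators all rows are assembled in one spectral pass, so a million sites
cost one eigendecomposition plus dense matvecs. A per-site Gillespie
(event-by-event) mode provides an independent cross-check on small inputs.
All randomness flows through one seeded numpy Generator; seeds are recorded
in FASTA headers and run manifests. The simulator emulates independent
sites with time-constant rates under a stationary start; it does **not**
emulate indels, heterotachy, codon-usage drift, selection shifts or
correlated sites — agreement of the tests with the propagators validates
the mathematics of the ensemble average, not the realism of those premises
for any particular protein family.

## Parameter files and the codon frequency vector

The amino-acid reference computations use the bundled published WAG matrix
verbatim, and reproduce the reference values at their printed precision
(Markov 80 %-identity time 0.230; double+triple flux share 0.224 ≈ 22 %;
matched-identity Ile→Val 0.104/0.075, Arg→Lys 0.064/0.049, Gly→Ile
0.0006/0.0021).

The codon-level reference computations require a 61-entry codon frequency
vector that is not printed in any bundled source; this package uses the
uniform sense-codon vector as its documented default. The induced
deviations, measured once and reported here, are modest for the
frequency-robust quantities — Markov 80 %-time 0.2313 (reference 0.235),
ensemble identity at t = 0.235 of 85.3 % (85.7 %), ensemble 80 %-time
0.386 (0.4), re-inferred f₂ 0.157 (0.153), f₂+f₃ 0.176 (17 %) — and larger
for frequency-sensitive ones: the triple fraction f₃ comes out 0.019
(reference 0.017, +14 %), and individual codon-pair probabilities such as
GTC→GTT shift substantially with the frequency vector. The acceptance
tests therefore hold the robust codon quantities to 10 % relative
tolerance, the triple fraction to a factor-2 magnitude bracket, and the
per-pair codon probabilities to their qualitative ordering, while the
WAG-driven amino-acid values are held to printed precision.

## Problem sizes and tie-breaks

Monte-Carlo checks run at 10⁵ sites per test and 10⁶ for the headline
pair-frequency check (three-state model), with multinomial goodness-of-fit
at p > 0.001 and moment checks within 3–4 standard errors. Degenerate
inputs are rejected loudly rather than repaired: reducible generators (null
space dimension ≠ 1), zero-flux normalization, unattainable identity
targets, non-positive-spectrum logarithms, and non-converged quadrature all
raise typed errors. Toy-model comparisons use the un-normalized printed
3-state generator (flux 0.8) except where unit time scale matters, in which
case its normalized form is used explicitly.
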
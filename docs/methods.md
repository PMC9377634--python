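# Methods

## Model

All estimators operate on the unfolded site frequency spectrum
`S = (S_1, …, S_{n−1})` of `n` haploid sequences under the neutral Kingman
coalescent with infinitely-many-sites mutation. The genealogy spends
`T_k ~ Exp(k(k−1)/2)` in the level with `k` lineages; mutations fall on
branches at rate θ/2 per unit coalescent time, so `S_i | ℓ_i ~
Poisson(θ·ℓ_i/2)` where `ℓ_i` is the total branch length ancestral to
exactly `i` leaves. First and second moments are `E[S_i] = θ/i` and
`Cov(S) = θD_α + θ²Σ` with `α_i = 1/i`, `D_α = diag(α)` and `Σ` assembled
from the `β_n(i)` terms (`estimators.FuModel`). Recombination is
parameterized by `ρ = 4N_e r L` for a segment of `L` sites; `ρ = 0` means
one shared genealogy, `ρ = ∞` the unlinked limit with independent
`S_k ~ Poisson(θ/k)`.

The harmonic convention is `h_m = Σ_{j=1}^{m−1} 1/j` (so `h_2 = 1` and the
`h_{n+1}` inside `β_n` sums `n` terms). This single convention is used
everywhere and is pinned by the analytic check `σ_11 = 1` at `n = 2`
(`Var(S_1) = θ + θ²` from the Poisson–Exponential mixture) and by the
simulation-covariance test at `n = 10`. The printed case distinctions for
`σ_ii` (`i = n/2`) and `σ_ij` (`i + j = n`) are reconstructed following the
structure of the remaining cases and validated by the same covariance test
rather than taken from any one rendering.

## Estimators

* Watterson: `θ̂_W = ΣS_i / h_n`; variance `θ/h_n + θ²g_n/h_n²` at ρ = 0 and
  `θ/h_n` unlinked.
* Fu BLUE at known θ: `a(θ)ᵀ = αᵀ(D_α+θΣ)⁻¹ / (αᵀ(D_α+θΣ)⁻¹α)`.
* Futschik–Gach minimum-MSE at known θ: `aᵀ = αᵀ(D_α/θ + Σ + ααᵀ)⁻¹`. The
  `D_α/θ` (division) reading is adopted: it is the unique reading that
  reproduces the brute-force MMSE solution `a* = θ/(1+2θ)` at `n = 2` and
  the normal-equations oracle `(Cov+μμᵀ)⁻¹μθ` at every tested `n`.
* Segregating-sites variant: `θ̂ = c·M` with
  `c = θh_n / (h_n + θg_n + θh_n²)`.
* Iterative versions (θ̂_ItV, θ̂_ItMSE): fixed-point iteration
  `θ̂_{k+1} = f_{θ̂_k}(S)` from `θ̂_0 = θ̂_W`, stopping when successive
  values differ by less than `tol = 10⁻³` (three decimal places), capped at
  100 iterations with a `converged` flag. Zero spectra return 0 directly;
  negative intermediate iterates are clamped to 0. The map's contraction
  ratio at `n = 40, θ = 40` is ≈ 0.01–0.02, so the median iteration count is
  3 and the 90th percentile 4; counts rise to ~5 only under tolerances near
  10⁻⁵.

Numerics: `(D_α + θΣ)⁻¹x` is evaluated through a one-time symmetric
eigendecomposition of `D_α^{−1/2} Σ D_α^{−1/2}` (the MMSE rank-one term via
Sherman–Morrison), making per-θ coefficients O(n²) and the iterative
estimators fully vectorized over replicate matrices. The test suite checks
this path against direct bordered-KKT and normal-equation solves to 10⁻⁸
for all `n ≤ 12`.

## Simulation

`simulate_kingman_sfs` samples genealogies by uniform pairwise merging and
accumulates `ℓ_i` exactly; mutation is Poisson-thinned per frequency class,
which is distributionally identical to per-site simulation under infinitely
many sites and needs no external dependency. `simulate_unlinked_sfs` draws
independent Poissons. Intermediate ρ goes through an adapter to msprime in
coalescent units: haploid samples, population size 1, per-site mutation rate
`θ/(2L)` and recombination rate `ρ/(2L)`; the scaling was verified against
the standard diploid parameterization (identical Watterson variance at
ρ = 50) and against `E[S_i] = θ/i`. At ρ = 1000 residual linkage still
inflates `Var(θ̂_W)` about 22% above the `θ/h_n` limit; tests assert the
honest behavior (approach from above), not the limit itself.

Training sets follow the study conditions: `n = 40`, θ uniform on (0, 100),
and a composite set concatenating equal thirds at ρ = 0, high recombination,
and ρ ~ U(0, 50). The high-recombination third is drawn from the unlinked
limit by default (`high_rho_mode="msprime"` simulates ρ = 1000 instead at
~50 ms per spectrum); the distributional difference at ρ = 1000 is the
few-percent residual linkage above. Seeds propagate through
`numpy.random.SeedSequence` spawning: one master seed yields bit-identical
datasets.

## Networks and adaptive training

Two architectures, both numpy: a linear network (`θ̂ = wᵀS`, no bias) and a
one-hidden-layer ReLU network with bias and a linear output (ReLU on the
output would zero the gradient of every negative prediction). Default width
is 200 hidden nodes for `n = 40`; at least `2n` is advisable and widths
below `n` risk non-termination of the adaptive loop (warned).

The hidden-layer network is *zero-anchored*: its prediction is
`f(S) − f(0)`, so the empty spectrum maps to exactly 0. This encodes the
same boundary condition every model-based estimator satisfies (no
segregating sites ⇒ estimate 0) and is load-bearing for the adaptive
procedure: the lowest θ-subset's normalized MSE `E[(θ̂−θ)²/θ]` is dominated
by near-zero-θ draws whose SFS is empty, where an unconstrained network
contributes its residual bias `c` as `c²/θ → ∞`, making the stopping rule
unattainable on generic validation draws. The anchor removes that term at
no cost in capacity (the output bias becomes inert).

Training minimizes the weighted relative squared error
`mean(ω(θ_i)·((θ̂_i−θ_i)/θ_i)²)` by Adam (lr 10⁻³, batch 64, up to 50
epochs, early stopping with patience 5 on validation loss, and
reduce-on-plateau: on a stall the best weights are restored and the
learning rate is multiplied by 0.3, up to two reductions). The loss
denominator is clamped at `θ_floor = 0.1` so the rare near-zero θ draws
cannot dominate the gradient; this touches ~0.1% of a U(0, 100) sample.

The six θ-subsets `(t_{k−1}, t_k]` fix `t_0 = 0, t_1 = 1, t_6 = 100`;
interior boundaries equalize `V(t_{k−1},t_k) = Σ_j |a_j(t_k) − a_j(t_{k−1})|`,
the total variation of Fu's coefficient vector (absolute values — the
"range of coefficients" motivates magnitudes), via nested root-finding
(outer bisection on the common V, inner Brent steps), after verifying V's
monotonicity on a dense grid. For `n = 40`:
`(0, 1, 2.00, 3.62, 6.71, 14.88, 100)`.

Adaptive loop: floors `b_k = min(nMSE_k)` over Watterson, θ̂_ItV, θ̂_ItMSE
and the trained linear network are computed once on a *second*, held-out
validation set; after each training round the network's per-subset nMSE is
compared and lagging subsets get
`ω_k += R·max(D_k/b_k,0)/max_k(…)` with `R ~ U(0.25, 0.5)` — the worst
subset gains exactly R, and ties share the normalization. Termination
requires `nMSE_k ≤ 1.02·b_k` for all k; a configurable round cap (default
100) returns the best round seen with `converged=False`. Two normalizations
are deliberately distinct: the floors/updates use `nMSE = MSE/θ` (per-sample
`(θ̂−θ)²/θ`), while the training loss divides by θ².

Two departures from a literal re-training loop, both adopted after the
literal variant oscillated at reduced data scale: refinement rounds
warm-start from the previous weights with a reduced learning rate
(3×10⁻⁴, `refine_epochs = 15`), and the second validation set is
θ-stratified (equal rows per subset via `build_stratified_set`) — under
θ ~ U(0, 100) the lowest subsets would hold ~1% of rows each, making the
1.02 check a test of floor noise rather than of the network. Stratification
does not bias the conditional per-subset nMSE.

## Evaluation and genome scan

`compare_estimators` simulates fresh replicates per (θ, ρ) cell — training
data is never reused — and reports nMSE, bias and variance with Monte-Carlo
standard errors (variance uses the 1/R convention so `MSE = Var + bias²`
holds exactly). The genome scan reads biallelic SNVs from VCF
(REF = ancestral unless an `AA` INFO tag flips a site; sites with missing
genotypes are excluded and logged), aggregates 0-based half-open windows
anchored at 0 (final partial window kept and flagged), and annotates windows
with the integrated scaled ρ of a piecewise-constant recombination map plus
a regime bin (low (0,1], medium (30,40], high > 150). Block maps built by
`make_block_recomb_map` stand in for real human maps: alternating
zero-recombination and hot blocks reproduce the qualitative behavior —
strongly correlated, wider-scattered estimates in cold blocks — without any
external data.

## Problem sizes and what the tests show

Monte-Carlo checks use 10⁴–2×10⁵ replicates per condition and 3-to-4-SE
bands computed from empirical fourth moments. The adaptive-training
acceptance check trains on a composite set of 1.8×10⁵ rows (the full study
condition is 6×10⁵; smaller sets train networks that visibly lag the
model-based estimators at high recombination) with 6×10³ validation and
3.6×10⁴ stratified floor rows, and evaluates at θ = 40 on 10⁴ fresh spectra
at ρ = 0 and 2–3×10³ at ρ ∈ {20, 1000} (msprime); bounds checked at
reduced replication allow two paired Monte-Carlo standard errors.
Synthetic data matches the generating model
exactly — real data deviates through population-size change, selection,
ancestral-state misassignment and missingness, none of which are modeled —
so passing tests demonstrate correctness of the estimators and training
procedure under the stated model, not field performance.

## Known limitations

* Sample size is fixed per trained network; retrain for a different `n`.
* Networks can learn the simulation range: estimates outside (0, 100) are
  flagged, and applications with larger θ need a retrained network.
* No demography, selection or population structure in any sampler; no
  recombination-rate estimation.
* The predicted θ is reported raw (possibly negative for the linear
  network); downstream users decide about clamping.
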
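# thetanet

Estimation of the population-scaled mutation rate **θ = 4N<sub>e</sub>μ** from
the site frequency spectrum (SFS), robust to unknown recombination rates.

Given `n` haploid sequences, the unfolded SFS is `S = (S_1, …, S_{n−1})`,
where `S_i` counts segregating sites whose derived allele is carried by
exactly `i` sequences. Linear estimators `θ̂ = aᵀS` with known optimality
properties exist at the two extremes of recombination:

- **Watterson's estimator** `θ̂_W = Σ S_i / h_n` with `h_n = Σ_{i<n} 1/i` —
  unbiased at every recombination rate, and the minimum-variance unbiased
  estimator in the unlinked-loci limit (ρ → ∞), where
  `S_k ~ Poisson(θ/k)` independently.
- **Fu's estimator** — the best linear *unbiased* estimator at ρ = 0,
  `a(θ)ᵀ ∝ αᵀ(D_α + θΣ)⁻¹` with `α_i = 1/i`, `D_α = diag(α)` and `Σ` the
  quadratic-coefficient matrix of `Cov(S) = θD_α + θ²Σ` under the Kingman
  coalescent.
- **The Futschik–Gach estimator** — drops unbiasedness and minimizes the MSE
  at ρ = 0: `aᵀ = αᵀ(D_α/θ + Σ + ααᵀ)⁻¹`.

The optimal coefficients depend on the unknown θ, so practical estimation
iterates a fixed point (`θ̂_{k+1} = f_{θ̂_k}(S)`, starting from Watterson),
giving the θ-free estimators **θ̂_ItV** and **θ̂_ItMSE**.

For *intermediate* recombination no closed-form optimum is known. `thetanet`
trains a small feedforward network (one ReLU hidden layer) on simulated SFS
data spanning recombination regimes, with an **adaptive loss reweighting**:
training rounds alternate with a held-out comparison of the network's
per-θ-subset normalized MSE (`nMSE = MSE/θ`) against the best of the
model-based estimators and a linear network; lagging subsets get their loss
weight raised, and training stops only when the network is within a factor
1.02 of every floor. The result is a single estimator that matches the best
model-based estimator at low and high recombination and beats both in
between — without ever being told the recombination rate.

## Worked example

```python
import numpy as np
from thetanet import (CoalescentParams, simulate_kingman_sfs, watterson,
                      iterate_estimator)

ds = simulate_kingman_sfs(CoalescentParams(n=40, theta=40.0), reps=1,
                          rng=np.random.default_rng(1))
sfs = ds.sfs[0]
print(watterson(sfs))                        # 39.261
print(iterate_estimator(sfs, "fu"))          # (34.234, 3, True)
print(iterate_estimator(sfs, "futschik"))    # (32.706, 3, True)
```

One spectrum simulated at true θ = 40 with no recombination: Watterson reads
off the 167 segregating sites (`167/h_40 = 39.26`); the iterative Fu and
Futschik estimators reweight the spectrum's frequency classes and land at
34.23 and 32.71 after 3 fixed-point iterations each. Their larger deviation
on this particular draw is within one standard deviation — at ρ = 0
Watterson's SD is 12.35 while the iterative estimators' is about 8.

The `examples/` directory holds one short script per capability: single-SFS
estimation, estimator comparison grids, adaptive network training, and a
windowed scan of a synthetic chromosome with a block recombination map.
A `thetanet` CLI (`simulate`, `train`, `estimate`, `evaluate`, `scan`)
wraps the same functions for shell use; every run writes a JSON manifest
with its seed and parameters.

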
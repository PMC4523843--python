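# rfmflow

Steady-state translation rate and sensitivity analysis for the **ribosome
flow model** (RFM), with exclusion-process (TASEP) validation machinery.

## The problem

During mRNA translation, ribosomes initiate at the 5' end of a transcript,
elongate codon by codon — queueing behind slow neighbours, since two
ribosomes cannot occupy the same stretch of mRNA — and terminate at the 3'
end, releasing a protein. The standard stochastic model of this traffic is
the totally asymmetric simple exclusion process (TASEP); its dynamic
mean-field approximation, the RFM, replaces binary site occupancies by
continuous densities `x_i ∈ [0, 1]` on `n` sites governed by

    dx_1/dt = λ₀(1 − x₁) − λ₁x₁(1 − x₂)
    dx_i/dt = λ_{i−1}x_{i−1}(1 − x_i) − λ_i x_i(1 − x_{i+1})
    dx_n/dt = λ_{n−1}x_{n−1}(1 − x_n) − λ_n x_n

with initiation rate `λ₀`, elongation rates `λ₁…λ_{n−1}` and termination
rate `λ_n`. Every trajectory converges to a unique equilibrium `e`, and the
steady-state protein production rate is `R = λ_n e_n`.

The question this package answers quantitatively: **which rate along the
transcript matters most?** I.e., the sensitivities `s_i = ∂R/∂λ_i` — the
effect of a small mutation (a codon change, an initiation-context change)
on protein output.

## The spectral method

Build the `(n+2) × (n+2)` symmetric tridiagonal matrix `A` with zero main
diagonal and off-diagonal entries `λ_i^{−1/2}`. Its largest eigenvalue
`ζ` (the Perron root — `A` is nonnegative and irreducible) encodes the
steady state:

    R = ζ⁻²,     s_i = ∂R/∂λ_i = 2 ζ⁻³ λ_i^{−3/2} v_{i+1} v_{i+2} > 0,

where `v` is the unit-norm positive Perron eigenvector. This turns steady
state and sensitivity computation into a symmetric-tridiagonal eigenproblem
— `O(n)` storage, fast and stable even for chains of thousands of sites —
and yields analytic results:

* every `s_i` lies strictly between 0 and 1 (a small rate change can at
  most move `R` by the same amount);
* Euler's theorem for the degree-1 homogeneous map `λ ↦ R` gives
  `Σ_i λ_i s_i = R`;
* **THRFM** (all rates equal `λ_c`): `R = λ_c/(4cos²θ)`,
  `s_i = sin((i+1)θ)sin((i+2)θ)/(2(n+3)cos³θ)` with `θ = π/(n+3)`; the
  sensitivity peaks mid-chain, and the center-to-edge ratio
  `Δ(n) = s_{⌊n/2⌋}/s₀` grows without bound (`Δ(2)` is the golden ratio);
* **HSRFM** (equal interior rates, boundaries coupled by
  `λ₀ + λ_n = λ_c`, `α = λ₀/λ_c`): `R = λ_c α(1−α)`, interior
  sensitivities decay geometrically with ratio `α/(1−α)`, and the coupled
  boundary sensitivities are `s₀ = 1 − 2α = −s_n`.

Independent oracles ship alongside: ODE integration, bisection on the
continued-fraction steady-state equation, central finite differences, a
kinetic Monte Carlo TASEP simulator, the exact `2^N` master equation, and
the closed-form homogeneous-TASEP current `J = Z(N−1)/Z(N)`.

## Worked example

A 10-site chain with slow initiation (`λ₀ = 0.3`), unit elongation rates
and coupled termination (`λ₁₀ = 0.7`):

```python
from rfmflow import make_profile, sensitivities_spectral, translation_rate_spectral

prof = make_profile("hsrfm", n=10, lambda_c=1.0, alpha=0.3)
ss = translation_rate_spectral(prof)
s = sensitivities_spectral(prof).s
print(ss.R)           # 0.21000000000000013
print(ss.e[:3])       # [0.3 0.3 0.3]
print(s[0], s[1])     # 0.4000358388662872 0.05143317928280836
print(s[2] / s[1])    # 0.4285714285714285  (= 3/7 = alpha/(1-alpha))
```

Initiation is rate-limiting: `R = λ_c α(1−α) = 0.21`, the densities sit at
`α = 0.3` along the interior, the initiation sensitivity `s₀ ≈ 0.4`
dominates, and each elongation rate matters `3/7` as much as the previous
one — sensitivity decays geometrically towards the 3' end, which is why
mutations near the start of an initiation-limited gene have the largest
effect on protein output.

The same computations from the shell:

```console
$ rfmflow rate --homogeneous 2 1.0 --method spectral
0.38196601125
$ rfmflow closed-form --edge-effect 2
1.61803398875
$ rfmflow tasep exact --N 2 --alpha 1 --beta 1
0.4
```

`rfmflow experiment --name rfm_vs_tasep` (and the other four experiment
drivers) write TSV tables plus JSON provenance sidecars for the standard
analyses: slow-codon-cluster scans, sensitivity profiles along a
transcript, closed-form vs numeric comparisons, and the mean-field vs
exact-TASEP sensitivity comparison across the phase transition.

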
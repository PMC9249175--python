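# scratchabc

Likelihood-free Bayesian calibration of a mechanistic cell-migration model
against high-throughput scratch-assay (wound-healing) screens, using
**minibatch ABC-SMC**: approximate Bayesian computation with sequential
Monte Carlo in which each proposed parameter is scored on a small random
batch of the observations instead of the whole dataset.

## Who this is for

Scratch assays image a monolayer of cells before and 24 h after a strip is
scratched away.  Screens produce hundreds of such image pairs (one per
gene knockdown), usually summarised only by cell counts and wound areas.
This package fits a stochastic individual-based model (IBM) of
density-dependent cell behaviour to the *cell-centre point patterns*
themselves, giving each experimental condition an interpretable,
mechanistic parameter estimate — at a fraction of the simulation cost of
classical ABC-SMC.

## The model and the sampler

Each cell at position **x**ₙ moves, divides and dies as a Poisson process
with rates

    Mₙ = max{0, m − γₘ Σ_{i≠n} exp(−‖xₙ−xᵢ‖²/2σ²)}   (movement)
    Pₙ = max{0, p − γ_p Σ_{i≠n} exp(−‖xₙ−xᵢ‖²/2σ²)}  (proliferation)
    d                                                  (death, constant)

simulated exactly with the Gillespie algorithm on a periodic 180 × 512-px
field of view (2.97 µm/px).  Moves and daughters displace by one cell
diameter φ in a direction ϕ ~ vonMises(arg **B**ₙ, ‖**B**ₙ‖), where
**B**ₙ = −∇B(**x**ₙ) is the negative gradient of the crowding potential
B(**x**) = Σⱼ γ_b exp(−‖**x**−**x**ⱼ‖²/2σ²), and σ = φ/2.

A snapshot is summarised by its cell count, a 20-bin pair correlation
function (Δr = 5 µm, CSR-normalised) and a 64-bin density profile across
the wound; simulated and observed snapshots are compared by a composite
squared-relative distance.  Inference is sequential importance sampling:
per generation, N_gen proposals are drawn (prior, then a 2×-covariance
normal perturbation kernel), each scored by the mean distance over N_bs
observations drawn with replacement — one IBM realisation per draw, each
started from that observation's own initial condition — and the N_acc
best are accepted with weights π/q̂.  Setting N_bs = N_obs reproduces
classical ABC-SMC; N_bs = 10 cuts simulation effort ~12× on a 117-well
control dataset while the chance of never touching a given well in a
generation is below e⁻²⁰⁰⁰⁰.

See `docs/methods.md` for assumptions, parameter meanings, numerical
choices and limitations.

## Worked example

Generate a synthetic 20-well dataset under built-in "regime I" (fast
movers whose motility is enhanced by crowding: m = 1.5 h⁻¹,
p − d = 0.01 h⁻¹, γₘ = −1 h⁻¹, γ_p = 0.01 h⁻¹, γ_b = 20 µm), then infer
the parameters back:

```bash
scratchabc generate --regime I --n-obs 20 --seed 11 --out regime1/
cat > abc.yaml <<EOF
n_gen_samples: 1600
n_accept: 80
n_batch: 10
n_generations: 3
EOF
scratchabc -v infer --data regime1/ --config abc.yaml --seed 12 --out posterior/
```

which prints (numbers from this exact invocation):

```
posterior mean (m, p, d, gamma_m, gamma_p, gamma_b): [ 1.3706e+00  2.1089e-02  9.0196e-03 -1.2419e+00  2.5975e-02  3.2563e+01]
```

The intrinsic motility rate m ≈ 1.37 h⁻¹ and the crowding–motility
coupling γₘ ≈ −1.24 h⁻¹ recover the generating values within the
posterior's spread; p and d are only identified through their difference
(here p − d ≈ 0.0121 h⁻¹ against a true 0.01), and γ_p, γ_b sit near
their prior means — both are weakly identified from two snapshots 24 h
apart, and the surplus γ_p is compensated by the slightly raised p − d.  `posterior/generation_3.csv` holds the weighted
particles; `summarize` and `analyze` produce per-snapshot summary JSONs
and screen-level cluster/fold-change tables.

The same run through the Python API:

```python
from scratchabc import ABCConfig, generate_regime_dataset, run_abc_smc
from scratchabc.screen import posterior_mean

data = generate_regime_dataset("I", 20, rng=11)
gens = run_abc_smc(data, ABCConfig(n_gen_samples=1600, n_accept=80,
                                   n_batch=10, n_generations=3), rng=12)
print(posterior_mean(gens[-1]))   # (m, p-d, gamma_m, gamma_p, gamma_b)
```

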
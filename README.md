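# sasmc

**DLVO Monte Carlo structure factors and neural-network inversion of
colloidal SAXS curves.**

Small-angle X-ray scattering probes the interactions of charged
nanoparticles in solution: the structure factor S(q) of a concentrated
sample encodes the interparticle correlations that the pair potential
creates.  Classical analysis fits S(q) with closed-form models (e.g.
Hayter–Penfold RMSA) that are valid only inside a narrow parameter
envelope.  `sasmc` takes the simulation route instead, aimed at
scattering practitioners who need interaction parameters outside that
envelope:

1. **Simulate.**  N spheres in a periodic box interact through the DLVO
   potential — non-retarded Hamaker attraction plus screened-Coulomb
   (Yukawa) repulsion,

   βU(d) = −(H_A/6k_BT)·[2r²/(d²−4r²) + 2r²/d² + ln(1−4r²/d²)]
         + Z_eff²·L_B·[e^{κr}/(1+κr)]²·e^{−κd}/d,

   sampled by single-particle Metropolis Monte Carlo.  Snapshot-averaged
   radial distribution functions g(r) give the structure factor

   S(q) = 1 + 4πn_p ∫ [g(r)−1]·sin(qr)/(qr)·r² dr,

   and I(q) = P(q)·S(q) with the analytic sphere form factor P(q)
   (diameter 3.97 nm by default, or a user-supplied curve).

2. **Learn.**  A dense network (8 hidden layers, 512 halving to 4, ReLU,
   Adam at 0.001, MSE, early stopping with patience 10) maps a curve to
   (Z_eff, κ⁻¹); an inverse network (128, 512, 512, 512 → 225 grid
   points) emulates the simulator ~10³–10⁴× faster than a Monte Carlo
   run.  Training corpora sample Z_eff ∈ [10, 70], κ⁻¹ ∈ [3, 7] nm and
   split 8:1:1; a q-cutoff sweep selects how much of the 0.012–0.501 Å⁻¹
   grid the forward net should consume.

3. **Infer.**  The inverse network serves as the likelihood engine of an
   affine-invariant ensemble MCMC sampler (emcee) with uniform priors
   over the training box and the χ² likelihood
   log L = −½ Σ_k (F_k − D_k)²/σ_k², yielding maximum a posteriori
   estimates, central credible intervals and the Z_eff–κ⁻¹ correlation
   structure for a measured curve.

## Worked example

```python
import numpy as np
from sasmc import (InteractionParams, SamplerConfig, build_dataset,
                   generate_curve, map_estimate, run_mcmc,
                   train_surrogate)
from sasmc.dataset import DEFAULT_BASE_PARAMS
from sasmc.fixtures import desk_config
from sasmc.models import TrainingConfig

corpus = build_dataset(600, desk_config(seed=0), seed=0)
surrogate = train_surrogate(corpus, config=TrainingConfig(seed=0, batch_size=16))

truth = (32.0, 5.5)   # held-out "measurement": fresh MC curve + 2% noise
curve = generate_curve(
    InteractionParams(**{**DEFAULT_BASE_PARAMS, "z_eff": truth[0],
                         "kappa_inv": truth[1]}),
    desk_config(seed=9001), noise_fraction=0.02,
    rng=np.random.default_rng(7))

posterior = run_mcmc(curve, surrogate,
                     config=SamplerConfig(n_walkers=32, n_steps=2000, seed=5))
estimate = map_estimate(posterior, data=curve, surrogate=surrogate, refine=True)
print(f"MAP: Z_eff = {estimate.z_eff:.2f}, kappa_inv = {estimate.kappa_inv:.2f} nm")
print("95% CI (Z_eff):", estimate.credible_intervals["z_eff"][95])
```

Output from this exact script:

```
MAP: Z_eff = 35.52, kappa_inv = 5.35 nm
95% CI (Z_eff): (28.52, 52.79)
```

The MAP lands within ~11% and ~3% of the generating Z_eff = 32 and
κ⁻¹ = 5.5 nm, and the truth sits inside the 95% intervals.  The wide,
tilted Z_eff interval is real physics, not sloppiness: raising either
parameter strengthens repulsion, so the posterior is a narrow
anti-correlated ridge (Pearson r ≈ −0.95) and single-point estimates
slide along it.

A command-line interface mirrors the library
(`sasmc simulate | build-dataset | train-forward | train-surrogate |
select-qcutoff | predict | mcmc-fit | make-fixtures`).

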
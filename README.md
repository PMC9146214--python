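# flimelm

Fast fluorescence-lifetime inference for time-domain FLIM with an extreme
learning machine, plus the synthetic TCSPC simulator, classical baseline
estimators and evaluation metrics needed to study it.

## The problem

Fluorescence lifetime imaging microscopy (FLIM) contrasts tissue by how long
fluorophores stay excited, not by how bright they are.  A TCSPC microscope
records, per pixel, a histogram of photon arrival times whose expectation is

    h(t) = IRF(t) * P Σ_k α_k e^(−t/τ_k) + b,

an exponential mixture blurred by the instrument response function (IRF) and
corrupted by Poisson counting noise.  Recovering the lifetimes τ_k, fraction
α and the averages τ_A = Σ α_k τ_k and τ_I = Σ α_k τ_k² / Σ α_k τ_k
pixel-by-pixel is ill-posed at the low photon counts that fragile, easily
photobleached samples permit, and iterative deconvolution fitting is slow
and sensitive to its starting point.

`flimelm` regresses lifetimes directly from the 256-bin histogram with an
extreme learning machine (ELM): a single hidden layer of L random frozen
sigmoid features, with only the linear output layer learned by one
ridge-regularized solve,

    β̂ = (AᵀA + λI)⁻¹ AᵀY,   A_il = σ(w_l·x_i + b_l).

Training is a single linear solve — no back-propagation, no iteration — so a
model retrains in well under a second when the lifetime range changes, and
inference is a matrix product.  The package is aimed at FLIM method
developers and microscopists who want a fast per-pixel estimator, the
classical baselines it should be judged against (deconvolution NLSF,
center-of-mass CMM/BCMM, phasors), and a fully seeded synthetic testbed.

## Worked example

```python
import flimelm as fl
from flimelm import elm_core

# 20,000 simulated decays (tau uniform in [0.1, 5] ns, 25-2000 photons,
# Gaussian IRF, Poisson noise), then one ridge solve:
ts = fl.sample_training_set(fl.TrainingConfig(model="mono", n_samples=20000), seed=42)
model = fl.train_elm(ts, L=500, lam=1e-3, seed=7)

# a dim test pixel: tau = 2.2 ns, 500 detected photons
y = fl.noiseless_decay(fl.DecayModel.mono(2.2, intensity=500),
                       fl.make_irf(fl.IRFSpec()), 0.039)
hist = fl.add_poisson(y, seed=1)
pred = elm_core.predict(model, hist)
print(f"tau_hat = {pred.tau:.3f} ns   (ground truth 2.200 ns, 500 detected photons)")
```

which prints

```
tau_hat = 2.360 ns   (ground truth 2.200 ns, 500 detected photons)
```

a single-pixel error of 0.16 ns at 500 photons.  Over 1000 such decays with
lifetimes across [0.1, 5] ns the same model reaches

```
R2 = 0.9740 over 1000 decays at 500 counts
median |error| = 0.105 ns
```

Bi-exponential models regress (τ1, τ2, α) and derive τ_A and τ_I; image
cubes are processed with `pipeline.reconstruct` behind an intensity filter,
and `phasor_analysis.phasor_cloud_from_cube` builds phasor projection images
that separate short-lifetime nanoprobes from cellular autofluorescence
without fitting any decay.

The same workflows are scriptable from the shell:

```bash
flimelm simulate --layout three_region_counts --dims 64x64 --seed 1 -o cube.h5
flimelm make-train --model bi --n 20000 --seed 1 -o train.h5
flimelm train --trainset train.h5 --hidden 500 -o model.h5
flimelm fit --method elm --model model.h5 --cube cube.h5 -o result.h5
flimelm eval --pred result.h5 --gt cube.h5 -o report.json
```

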
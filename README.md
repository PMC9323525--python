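# ateem

Chemometric analysis of A-TEEM data — simultaneous UV–vis **a**bsorbance and
fluorescence **e**xcitation–**e**mission **m**atrix (EEM) measurements — for
beverage characterisation and authenticity testing. The package implements the
complete workflow used to discriminate direct (freshly squeezed) from
processed (pasteurized commercial) strawberry beverages:

1. **Preprocessing** — inner-filter-effect (IFE) correction
   `F_corr = F_obs · 10^{(A(λ_ex)+A(λ_em))/2}`, excision of first- and
   second-order Rayleigh scatter ridges (`λ_em ≈ λ_ex`, `λ_em ≈ 2λ_ex`), and
   replicate averaging.
2. **PARAFAC** — non-negative trilinear decomposition
   `X_ijk = Σ_f a_if · b_jf · c_kf + e_ijk` of the samples × emission ×
   excitation array by multi-start alternating least squares that skips
   scatter-masked cells, with the standard diagnostics: explained variance,
   the core consistency diagnostic (CORCONDIA), split-half validation with
   Tucker-congruence component matching, and component-number selection.
3. **PCA** — exploratory analysis of absorbance matrices and sample-mode
   unfolded EEMs (uEEMs) with leave-one-out predictive residuals.
4. **PLS-DA** — two-class partial least squares discriminant analysis on
   dummy-coded class membership, leave-one-out (or venetian-blinds)
   cross-validated latent-variable selection, confusion-matrix metrics

       sensitivity = TP/(TP+FN),  specificity = TN/(TN+FP),
       misclassification error = (FP+FN)/(TP+TN+FP+FN),

   and variable importance in projection (VIP, normalised so mean VIP² = 1)
   refolded onto the excitation–emission plane.
5. **Synthetic data** — a generator that emulates the study design (15 direct
   + 20 processed samples, four Gaussian-profile fluorophores, anthocyanin-
   and browning-like absorbance, scatter ridges, IFE attenuation, triplicate
   measurements) with full ground truth, so every stage is testable without
   measured spectra.

## Worked example

```python
from ateem import (default_config, simulate_dataset, fit_parafac,
                   match_components)
from ateem.parafac import ParafacModel
from ateem.preprocess import ScatterSpec, preprocess_dataset
import numpy as np

sim = simulate_dataset(default_config(seed=1))          # 35 samples, 64 x 29
labels = dict(zip(sim.sample_ids, sim.labels))
ds = preprocess_dataset(sim.replicates, sim.absorbance, labels,
                        ScatterSpec(), apply_ife=True)

model = fit_parafac(ds, 4, seed=7, n_starts=2, tol=1e-6, max_iter=600)
print(f"fit {model.fit_percent:.2f}%  CORCONDIA {model.corcondia:.1f}%")

truth = ParafacModel(4, sim.truth.scores, sim.truth.em_profiles,
                     sim.truth.ex_profiles)
perm, _, _ = match_components(model, truth)
c4 = int(np.where(perm == 3)[0][0])
proc = np.array(sim.labels) == "processed"
print(f"processed-class mean browning score {model.scores[proc, c4].mean():.0f}")
```

prints

```
fit 99.98%  CORCONDIA 100.0%
processed-class mean browning score 9168
```

The fit recovers essentially all structure (the residual is measurement
noise), the near-100% core consistency confirms four trilinear components,
and the recovered processed-class mean of the browning-product component
reproduces the generator's empirical draw (configured distribution
8403 ± 5346) — the signature that separates pasteurized from fresh juice.

The full study reproduction — simulation through the per-block
classification table — runs from the shell:

```bash
ateem run-all --seed 1 --outdir scratch/run1
```

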
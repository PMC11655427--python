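# npqunmix

Unmix chlorophyll-fluorescence **NPQ induction curves** into a small
number of kinetic components.

Nonphotochemical quenching (NPQ) protects photosystem II by dissipating
excess excitation energy.  Measured by saturating-pulse PAM fluorometry,
NPQ(t) = (Fm − Fm′)/Fm′ rises during illumination through the combined
action of several mechanisms — PsbS protonation, xanthophyll-cycle
(zeaxanthin) quenching, photoinhibition — that overlap in time and cannot
be separated from a single curve.  `npqunmix` separates them from a
*dataset* of induction curves measured across many actinic-light
intensities, using the steady-state closed-centre fraction
x = (1 − qP)_ss as the light index:

1. **PCA** of the mean-centred curve matrix counts the strongly varying
   components via the scree elbow (maximum second difference of the
   explained-variance sequence).
2. **Full-harmonic phasor analysis** maps each curve to
   (G, S) = mean over harmonics of (Re Fₙ/F₀, −Im Fₙ/F₀).  Mixtures map
   to exact area-weighted barycentres of their component phasors, so a
   triangle anchored on the leading principal components — third vertex
   extrapolated as 3·centroid − v1 − v2, then refined to the minimum-area
   simplex enclosing the cloud — yields per-curve component abundances,
   including one weakly varying component PCA cannot rank.
3. **Guided NMF** (Lee–Seung multiplicative updates on ‖X − HW‖²_F,
   initialised from those abundances) refines non-negative induction
   profiles W and per-curve NPQ contributions H.
4. **Downstream models**: component contributions versus closure are
   fitted with sigmoid / sloped-sigmoid / linear trends, and the
   zeaxanthin-linked component is compared against a two-step
   de-epoxidation ODE cascade (dV/dt = −2kV, dA/dt = 2kV − kA,
   dZ/dt = kA) with quenching either ∝ Z ("direct") or ∝ a bound
   quencher formed at rate k_b·Z·(1 − Q/Q_max) ("indirect"; the binding
   step produces the t³ onset lag that distinguishes the models).

A synthetic-data generator plants wild-type-like (α, β, γ) and
*npq1*-like (β, γ, δ — no zeaxanthin) datasets with known profiles,
light-dependent mixing and leaf-to-leaf biological noise, so every stage
is testable by parameter recovery.  See `docs/methods.md` for the models,
defaults and limitations.

## Worked example

```python
import numpy as np
from npqunmix import decompose, fit_contribution_trend, generate_dataset

dataset, truth = generate_dataset(seed=1, genotype="wt")   # 85 curves, 26-1074 umol m^-2 s^-1
result = decompose(dataset)
print("elbow:", result.elbow.elbow_index, "| components:", result.n_components)
print("labels:", result.components.labels)
print("adjusted r2 >= 0.8:", f"{np.mean(result.components.adj_r2 >= 0.8):.1%}")

j = result.components.labels.index("alpha")
fit = fit_contribution_trend(dataset.closures(),
                             result.components.contributions[:, j], "sigmoid")
print(f"alpha trend: x0 = {fit.params['x0']:.3f} +/- {fit.stderr['x0']:.3f}, "
      f"A = {fit.params['A']:.2f} +/- {fit.stderr['A']:.2f}")
```

prints

```
elbow: 3 | components: 3
labels: ['alpha', 'beta', 'gamma']
adjusted r2 >= 0.8: 98.8%
alpha trend: x0 = 0.475 +/- 0.034, A = 2.91 +/- 0.27
```

Reading the output: the scree elbow at 3 means two strongly varying
principal components; adding the phasor-extrapolated third gives K = 3
components, which the shape library labels α (zeaxanthin-like, lagged
sigmoidal rise), β and γ (pH-associated).  Three components reconstruct
98.8% of curves with adjusted r² ≥ 0.8.  The α contribution follows a
sigmoid of closure; on this particular noise realisation the planted
amplitudes themselves fit to x0 = 0.472 and A = 2.88 (leaf-to-leaf
scatter is multiplicative and large), so the recovered trend matches what
is actually in the data — the recovered contributions track the planted
ones with correlation > 0.999.

The same flow from a shell:

```bash
npqunmix simulate --genotype wt --seed 1 --out-dir data/
npqunmix decompose --curves data/curves.csv --meta data/metadata.csv --out-dir results/
npqunmix fit --results-dir results/
npqunmix report --results-dir results/        # writes results/report.md
```

`decompose` writes the PCA summary, the phasor table and triangle, the
normalised profiles with per-curve contributions and fit scores, and a
provenance record sufficient to reproduce the run.  Measured data enter
either as curve tables (`curve_id, time_s, npq, qp, phase` plus a
metadata table) or as raw PAM traces via `npqunmix extract`.

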
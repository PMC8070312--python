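# photokin

Kinetic and optical modeling for photo-assisted degradation of
pharmaceutical pollutants over doped spinel-ferrite photocatalysts.

Batch photocatalysis experiments produce a normalized concentration time
course C/C₀(t) per catalyst composition, and a diffuse-reflectance spectrum
per catalyst.  This package turns those raw series into the quantities a
photocatalysis study reports, for the reference system of penicillin G
degrading over Cd-doped Mn–Zn spinel ferrites
(Mn₀.₅Zn₀.₅)[Cd_x Fe₂₋ₓ]O₄ with doping level x ∈ [0, 0.5]:

* **Pseudo-first-order kinetics** — ln(C/C₀) = −k₁t, with three estimators
  (through-origin slope, OLS with intercept, nonlinear fit in ratio space)
  and the per-m² intrinsic rate k₁′ = k₁ / (S_BET · load · volume).
* **Pseudo-n-order kinetics** — C/C₀ = [(n−1)kₙt + 1]^(−1/(n−1)), fitted
  jointly over many series with a shared order n.
* **Modified (quadratic-log) law** — ln(C/C₀) = −a₁t + a₂t² = −a₁t(1−αt);
  the increment α = a₂/a₁ measures deviation from true first order.
* **Intra-diffusion kinetics** — ln(C/C₀) = −K_d·√t, with the
  characteristic time τ = 1/K_d², its exponential composition law
  τ(x) = τ₀·e^(−θ(x−x₀)) over up to three domains, implied
  K_d(x) = K_d0·e^(+θ/2·(x−x₀)) with K_d0 = 1/√τ₀, and exhaustive
  piecewise-linear breakpoint segmentation.
* **Arrhenius propagation** — ln k₁(x) = ln A(x) − E_a(x)/(RT) with
  E_a(x) = E_a0 + RT[(ln A(x) − ln A₀) − εx], where ε is the slope of
  ln k₁ versus x.
* **Band-gap extraction** — Kubelka–Munk transform F(R) = (1−R)²/(2R),
  Tauc plot (F·hν)^(1/n) versus hν, automatic linear-window detection, and
  the Spearman/Pearson correlation of rate constants with band gaps.

The printed tables of the reference study ship as packaged fixtures
(`photokin.load_fixture`), and a synthetic-data module generates decay
curves, reflectance edges and τ profiles with known ground truth so every
estimator has parameter-recovery tests.

## Worked example

```python
import numpy as np
from photokin import load_fixture, fit_first_order, fit_intradiffusion
from photokin.kinetics import degradation_percent

series = sorted(load_fixture("table2"), key=lambda s: s.x)
for s in series:
    k1 = fit_first_order(s).k1          # min^-1, through-origin estimator
    tau = fit_intradiffusion(s).tau     # min
    print(f"x={s.x}: removal {degradation_percent(s):5.2f}%  "
          f"k1 = {1e3*k1:7.4f}e-3/min  tau = {tau:7.1f} min")
```

prints

```
x=0.0: removal 14.68%  k1 =  1.0703e-3/min  tau =  6773.1 min
x=0.1: removal 24.69%  k1 =  1.8848e-3/min  tau =  2220.6 min
x=0.2: removal 37.62%  k1 =  3.1440e-3/min  tau =   817.6 min
x=0.3: removal 44.71%  k1 =  3.8820e-3/min  tau =   534.0 min
x=0.4: removal 66.66%  k1 =  7.0829e-3/min  tau =   155.5 min
x=0.5: removal 88.73%  k1 = 13.7995e-3/min  tau =    42.9 min
```

Heavier Cd doping removes more antibiotic, speeds up the first-order rate
constant about 13-fold, and collapses the characteristic intra-diffusion
time by two orders of magnitude — the monotone trends the analysis scripts
under `analysis/` examine in detail (domain segmentation, τ(x) law,
band-gap correlation, Arrhenius propagation).

A CLI mirrors the library: `photokin fit|diffusion|tauc|simulate|reproduce`.

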
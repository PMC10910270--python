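# ammeg — adaptive multipole models for OPM-MEG

Wearable optically-pumped magnetometers (OPMs) sample the brain's
magnetic field directly on the scalp, where environmental interference
is orders of magnitude stronger than neural signal and where the
classic spherical-harmonic cleaning methods (Signal Space Separation,
SSS) struggle: no reference sphere can enclose the brain while keeping
every on-scalp sensor outside it, and many OPM array designs (radial
single-axis, dual-axis) yield badly conditioned harmonic models.

`ammeg` implements **adaptive multipole models (AMM)** for arbitrary
OPM sensor arrays:

* **Prolate spheroidal harmonic bases.** The magnetic scalar potential
  is expanded in solutions of Laplace's equation in prolate spheroidal
  coordinates adapted to a head-shaped reference spheroid (semi-axes
  *a* ≥ *b*, focus *c* = √(a²−b²)). The radial dependence of the
  spherical solid harmonics, (r_ref/r)^(l+1) and (r/r_ref)^l, is
  replaced by ratios of associated Legendre functions of the second and
  first kind, Q_l^m(r_maj/c)/Q_l^m(a/c) and P_l^m(r_maj/c)/P_l^m(a/c),
  which reduce to the spherical forms as c → 0. An internal order of
  l = 9 (99 harmonics) suffices on-scalp where spherical harmonics need
  l = 11 (143 harmonics).
* **Two projectors.** With H = [H_in H_out] the channels × harmonics
  basis and R_out = I − H_out H_out⁺ the rejector of the external
  (interference) span:
  * SSS-style *oblique* projector P = H_in (R_out H_in)⁺ — reproduces
    the internal span exactly but can amplify noise when the basis is
    ill-conditioned;
  * AMM *orthogonal* projector P = (R_out H_in)(R_out H_in)⁺ — projects
    onto the part of the internal span orthogonal to interference;
    symmetric, idempotent, and never increases variance.
* **Temporal CCA cleaning.** Residual interference (sensor nonlinearity,
  model truncation) leaks into both the retained inner space and the
  intermediate space; canonical temporal directions correlated above a
  limit (default 0.98) between the two are removed. The limit can be
  chosen from the closed-form chance-correlation bound
  ρ_max = αβ / √((β² + k)(α² + k)), k = T σ_ε² / (τ σ_X² n_c).
* **Simulation & metrics.** Scalp-array generation on a spheroid,
  single-sphere dipole lead fields, homogeneous-field + first-order-
  gradient interference with channel-wise multiplicative nonlinearity,
  shielding factors, white-noise reduction, PSD shielding curves and
  across-trial t-statistics.

The package is aimed at MEG methods researchers and OPM system
designers who want to predict, from the hardware specification alone
(channel count, axes per sensor, linearity), how well a multipole model
will separate brain signal from interference.

## Worked example

```python
import numpy as np
import ammeg as am

head  = am.default_head()                      # 90 x 70 mm scalp spheroid
array = am.generate_scalp_array(head, spacing=0.035, offset=0.0065,
                                axes=3, seed=1)  # 47 triaxial OPMs, 141 channels

# simulate brain activity + a 50 Hz interference line + sensor noise
rng = np.random.default_rng(0)
pos, ori = am.cortical_source_set(head, n_src=20, seed=0)
lf = am.leadfield_matrix(array, pos, ori, head.centre)
fs, n_t = 500.0, 2000
t = np.arange(n_t) / fs
data = (lf.matrix @ (5e-8 * rng.standard_normal((20, n_t)))
        + np.outer(am.random_interference(array, rng),
                   2e-12 * np.sin(2 * np.pi * 50.0 * t))
        + 3e-13 * rng.standard_normal((array.n_channels, n_t)))
rec = am.Recording(data=data, fs=fs, names=list(array.names))

res = am.AdaptiveMultipoleModel(rec, array, spheroid=head).fit()
print(res.summary())
```

```
Adaptive multipole model results
==================================
method:              AMM (orthogonal projection)
harmonic family:     internal=spheroidal, external=spherical
orders:              L_in=9 (99 harmonics), L_out=2 (8 harmonics)
channels / samples:  141 / 2000 at 500 Hz
reference spheroid:  a=90.0 mm, b=70.0 mm, c=56.6 mm
projector rank:      99
cond(Hin, Hout, H):  3.42, 1.07, 4.24
variance ratio:      0.1942
expected noise cut:  1.54 dB (rank law, orthogonal projection)
temporal stage:      limit=0.98, removed 0 component(s)
```

The triaxial basis is well conditioned (joint condition number 4.2);
the orthogonal projector keeps the rank-99 internal model and discards
80% of the raw variance — the interference line and part of the sensor
noise. The frequency-resolved shielding curve confirms where the
rejected power lived:

```python
f, db = res.shielding_curve(nperseg_s=2.0)
print(f"shielding at 50 Hz: {db[np.argmin(np.abs(f - 50.0))]:.1f} dB")
# shielding at 50 Hz: 31.3 dB
```

The same pipeline is scriptable from the shell:

```bash
ammeg simulate-array --spacing 0.035 --axes 3 --offset 0.0065 --seed 1 --out array.tsv
ammeg simulate-data  --geom array.tsv --out raw.tsv
ammeg project --method amm --in raw.tsv --geom array.tsv --limit 0.98 --out clean.tsv
ammeg benchmark figure3 --axes 1,2 --seed 0 --out shielding.tsv
```

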
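# Methods

## The model

Measured OPM data Y (channels × samples, Tesla) are modelled as a
linear combination of harmonic field patterns plus noise,
Y = Hβ + ε, where the columns of H = [H_in H_out] are the channel-space
signatures of solutions of Laplace's equation for the magnetic scalar
potential V (B = −μ₀∇V, valid in the current-free region occupied by
the sensors). Internal harmonics decay with distance from the
reference surface and model fields generated inside the array (brain);
external harmonics grow with distance and model distant interference.

Each basis column is the directional derivative of one potential
harmonic along a channel's orientation at its position. Column
(kind, l, m) of the matrix therefore encodes a physical field
topography; μ₀ and the overall sign are absorbed into per-column
normalization factors that are retained so model output stays in Tesla.

### Spherical and prolate spheroidal families

For the spherical family the potentials are the solid harmonics
(r_ref/r)^(l+1) S_lm(θ, φ) (internal) and (r/r_ref)^l S_lm (external),
with S_lm the real, orthonormal surface harmonics. For the spheroidal
family the radial factors become ratios of associated Legendre
functions evaluated in the confocal coordinate r_maj (half the sum of
the distances to the two foci of the reference spheroid):

* internal: Q_l^m(r_maj/c) / Q_l^m(a/c)
* external: P_l^m(r_maj/c) / P_l^m(a/c)

normalized to 1 on the reference surface r_maj = a. The Q-ratio is
evaluated through its hypergeometric-type series in (c/r_maj)², with
gamma factors in log space, truncated when the next term contributes
less than a relative tolerance (default 1e−12, hard cap 200 terms); the
P-ratio is a finite sum with upper index ⌊(l−m)/2⌋. Both reduce to the
spherical factors as c → 0; this limit is enforced by tests at
c/a = 1e−6 and the series agree with independent library evaluations of
P_l^m and Q_l^m to 1e−9 for all l ≤ 11.

Why spheroidal: on-scalp sampling of a head whose anterior–posterior
axis is longer than the other two violates the premise of a reference
*sphere* that contains the brain with all sensors outside. A prolate
spheroidal frame adapts to that geometry, and the internal expansion
converges at order 9 (99 harmonics) where the spherical family needs
order 11 (143 harmonics). Both degree counts follow from starting the
expansion at l = 1: the l = 0 term has a constant potential whose
gradient carries no field.

### Projectors

With R_out = I − H_out H_out⁺ (orthogonal rejector of the external
span), the joint least-squares fit of both blocks gives the internal
coefficients β_in = (R_out H_in)⁺ Y, and two ways to replace the data
with the internal model:

* **SSS-style (oblique):** Ŷ = H_in (R_out H_in)⁺ Y. Reproduces H_in
  exactly and annihilates H_out, but ‖P‖₂ grows with the conditioning
  of R_out H_in, so white noise and unmodelled residuals can be
  amplified on radial or dual-axis arrays.
* **AMM (orthogonal):** Ŷ = (R_out H_in)(R_out H_in)⁺ Y, the orthogonal
  projection onto the part of the internal span orthogonal to the
  interference span. Symmetric and idempotent, hence output variance
  never exceeds input variance; for iid noise the expected variance
  ratio is rank(P)/n_c, giving the white-noise reduction
  10·log₁₀(n_c/rank) dB. The price is that brain-signal components
  spatially correlated with interference are removed.

Pseudoinverses are SVD-based with singular values below rtol·σ_max
(default rtol = 1e−10) truncated; no further regularization is applied
by default, deliberately exposing the conditioning behaviour of the
oblique projector. Basis columns are normalized to unit norm before
any inversion (both projectors; this is the standard conditioning
practice, and whether the oblique variant historically normalized
identically is immaterial to its span properties).

### Temporal stage

The recording decomposes exactly into inner (P_amm Y), outer
(H_out H_out⁺ Y) and intermediate (the remainder) parts with pairwise
orthogonal images. Interference that survives the spatial model —
through sensor nonlinearity or truncation — appears in the inner *and*
the intermediate space with a common time course. Per analysis window
the canonical correlations between the two temporal subspaces are the
singular values of the product of their orthonormal temporal bases
(obtained by SVD, retaining components above 1e−10 of the largest —
this formulation avoids inverting covariance matrices); every canonical
direction with correlation ≥ limit (default 0.98) is projected out of
the inner data. The intermediate rather than the outer space is used
because it has more degrees of freedom. The default window is the whole
recording; a windowed mode exists for long sessions. Removal is an
orthogonal temporal projection, so total power never increases.

The chance-correlation bound used to set the limit is

ρ_max = αβ / √((β² + k)(α² + k)),   k = T σ_ε² / (τ σ_X² n_c),

with α, β the fractions of neural signal in the inner and intermediate
spaces, T the window length, τ the longest interval over which neural
activity stays correlated (default 0.25 s, the scale of an evoked
response), σ_X²/σ_ε² the signal and per-channel noise variances and n_c
the channel count. It is monotone increasing in σ_X², n_c and τ and
decreasing in T and σ_ε²; with no noise it is 1, with no signal 0 (by
continuity). The Monte-Carlo check in the test suite builds a sinusoid
with coherence time τ (random phase per τ-segment, 10 Hz carrier,
1000 Hz sampling) split across two 100-channel groups through rank-one
unit-norm spatial patterns in unit white noise, and verifies the bound
dominates the empirical first canonical correlation in ≥95% of 200
replicates. Because α and β are scene-dependent, no single printed
value of ρ_max is treated as a reference result.

## Synthetic data

The generator produces everything the characterization protocols need;
no external dataset is used anywhere.

* **Head and arrays.** The scalp is a prolate spheroid with semi-axes
  90 × 70 mm, major axis anterior–posterior (+y). Sensors are packed
  quasi-uniformly (Fibonacci lattice + greedy spacing thinning; the
  seed rotates the lattice) on the full spheroid surface, displaced
  6.5 mm along the outward normal — point magnetometers standing off
  the scalp. Channel axes: outward normal, then the tangential
  direction obtained by zeroing the normal's third component, swapping
  the first two and negating the first, then the cross product —
  1-, 2- or 3-axis sensors. Real helmets cover only the upper scalp;
  the closed surface used here is symmetric and keeps the packing
  contract simple, and is one reason reduced-scale numbers differ
  moderately from published array studies.
* **Forward model.** Analytic field of a current dipole in a
  homogeneous conducting sphere (Sarvas' closed form), centred at the
  spheroid centroid with radius b. This replaces a realistic
  single-shell anatomical model: it preserves the essential physics
  (radial dipoles silent, volume currents radially silent) at the cost
  of geometric fidelity, so worst-case reconstruction numbers are
  approximate by design. On a spheroidal head some legitimate sources
  lie beyond the *closest* sensors — exactly the geometry problem that
  motivates the spheroidal basis — so only sources beyond the
  *outermost* sensor shell are rejected.
* **Sources.** `cortical_source_set` places quasi-uniform dipoles on an
  inner spheroidal surface (default 0.9 × scalp) with surface-normal
  orientations. For protocols that emulate "the whole brain",
  `cortical_volume_sources` concatenates three shells at 0.60, 0.72 and
  0.85 of the scalp semi-axes (deep cortex ≈ 3.5 cm, mid cortex, gyral
  crowns ≈ 1 cm below the scalp): worst cases for interference
  separability come from deep smooth lead fields, worst cases for basis
  convergence from shallow ones, and a single shell cannot produce
  both.
* **Interference.** A physical static field: homogeneous component plus
  symmetric traceless first-order gradient tensor (8 degrees of
  freedom, curl- and divergence-free). Random draws scale the gradient
  coefficients by the array extent so both terms contribute comparably,
  then normalize the channel pattern to unit rms. Any such pattern lies
  exactly in the span of the order-2 spherical external basis — which
  is why that is the default external family regardless of the internal
  one.
* **Nonlinearity.** Channel-wise multiplicative gain errors drawn from
  the same low-order family, rescaled so the largest channel error is
  e_max (0.5%–10% in the protocols). Multiplying interference by such
  a topography creates spatial structure the external model cannot
  represent; the worst-case shielding over many interference ×
  nonlinearity draws is then the reciprocal of e_max to good accuracy
  (log-log slope −1), which the tests assert.
* **White noise.** iid Gaussian, explicit generator everywhere.

What passing these tests shows — and does not. The generator captures
array geometry, dipolar source physics, low-order interference and
multiplicative gain errors. It does not contain anatomy, correlated
sensor noise, movement, cross-talk dynamics or real interference
spectra, so the reduced-scale numbers characterize the algorithms, not
any particular hardware; the empirical shielding of a real recording
(tens of dB at mains frequency) is outside what synthetic tests can
certify.

## Protocol sizes and observed behaviour

Chosen so the whole suite runs in ~1 minute on one CPU:

* White-noise protocol: triaxial arrays closest to 200 and 400 channels
  (packing yields 204 and 396), 50 noise draws of 1000 samples; the
  measured reduction matches the rank law within 0.05 dB.
* Shielding protocol: 50 interference × 20 nonlinearity draws per grid
  point over e_max ∈ {0.5, 1, 2, 5, 10}%, radial and dual-axis ~100-
  sensor arrays, paired draws for both projectors.
* Reconstruction protocol: 510 three-shell sources, ~104-sensor arrays,
  spheroidal order 9 / external order 2.

Two known shortfalls of the substitute geometry, kept deliberately
rather than tuned away: on the full-spheroid *radial* array the joint
basis is so ill-conditioned (cond(R_out H_in) ≈ 1e5 at any density
10–25 mm) that the oblique projector destroys even well-represented
lead fields — its worst-case square-root-of-variance-explained is ~0
where anatomical-array studies report ≥0.95 — and the worst-case AMM
correlations on radial/dual arrays (≈0.24 and ≈0.64) bracket, but do
not match, the ≈1/3 and ≈1/2 reported for cortical-mesh sources,
because no single depth profile of spheroidal shells reproduces both
simultaneously. The corresponding acceptance checks are left asserting
the published values and fail honestly.

## Numerical choices

* Gradients of the potentials by central differences with step
  1e−6·a (~0.1 µm), validated against symbolic differentiation of the
  spherical solid harmonics to 1e−6 relative; analytic differentiation
  of the spheroidal series was rejected as error-prone.
* cos θ in the confocal transform is clamped to [−1, 1] (focal-line
  safety); the azimuth fallback for a polar radial axis is [1, 0, 0].
* Spheroid fitting: PCA for the axis, then a linear solve (least
  squares, in 1/a², 1/b²) or a 1-D bounded volume minimization
  (enclose). Oblate outcomes fall back to the tightest sphere.
* The spherical harmonic family uses the reference spheroid's own axes
  (polar axis = major axis) so the spheroidal basis reduces to it
  continuously as c → 0.
* Sensors inside the reference spheroid trigger a warning, not an
  error: on-scalp sampling can legitimately violate the spherical
  convergence region, which is the method's starting point.
* Degenerate inputs: zero-norm lead fields are flagged NaN with a
  warning (silent sources of the sphere model); an exactly zero
  across-trial standard error yields a large finite t-value; zero
  signal variance gives ρ_max = 0.

## Limitations

* The forward model and closed-surface arrays are substitutes;
  absolute worst-case correlations carry ~0.05–0.15 uncertainty.
* No regularized SSS variants (fine calibration, component selection)
  are provided; the oblique projector is deliberately plain.
* FIF/BIDS interop is out of scope; TSV (and the in-memory API) is the
  interchange format.
* The temporal stage assumes interference is temporally shared between
  spaces and brain activity decorrelates beyond τ; rhythmic brain
  activity with very long coherence times could be attenuated if the
  limit is set below its inner/intermediate correlation.
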
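# Methods

This note documents the models and numerical choices behind `qeegnorm` —
what each stage computes, the assumptions it makes, and what the
synthetic-data generator does and does not emulate.

## Spectral estimation

Epochs are expert-selected, artifact-free windows of multichannel EEG in
microvolts. The analysis grid is the DFT grid of one epoch with DC
excluded: bins `k * fs/N` for `k = 1 .. floor(fmax / (fs/N))`, strictly
below `fmax` (passing `fmax = fs/2` exactly yields the full one-sided
grid including the un-doubled Nyquist bin). For the canonical recording
conditions — 2.56 s epochs sampled at 200 Hz — the spacing is
0.390625 Hz, displayed as 0.39 Hz, and the default `fmax = 19.5` Hz
retains 49 bins whose rounded labels run 0.39 … 19.11 Hz. Display labels
are `k` times the rounded spacing; band bookkeeping uses the labels,
physics (mean frequency) uses the exact frequencies.

Cross-spectral matrices are Bartlett averages of per-epoch periodogram
outer products: per epoch the channel mean (DC) is removed, an optional
Hann taper applied, and

    S(f_k) = w_k / E * sum_e V_e(:, k) V_e(:, k)^H,
    w_k = 2 / (N^2 U)   (interior bins; half that at Nyquist),

with `U` the mean squared taper weight. This normalization makes the
one-sided diagonal sum exactly the epoch-mean channel variance
(Parseval), and a bin-aligned sinusoid of amplitude `A` contributes
`A^2/2` at its bin. No taper is the default: epochs are short and
pre-selected, and the rectangular window keeps Parseval exact. No
multitaper, Welch overlap or parametric spectra are provided.

Coherence is the magnitude-squared coherence
`|S_ij|^2 / (S_ii S_jj)` in [0, 1] (recorded in output metadata, since
both the squared and unsquared conventions circulate); phase is
`arg(S_ij)` with the numpy forward-DFT sign, so a channel that lags
another by `tau` at frequency `f` shows phase `-2 pi f tau` in the
(lagging, leading) entry. With a single epoch the coherence is
identically 1 — a documented degeneracy, not an error. Pairs with a zero
auto-spectrum at a bin are flagged undefined (NaN) rather than raised.

## Broad-band model

Absolute Power is the band sum of narrow-band power; Relative Power the
fraction of the Total band (so RP sums to 1 over the four bands); Mean
Frequency the power-weighted mean of the exact bin frequencies. Default
edges on the 0.39 Hz label grid — Delta 1.56–3.51, Theta 3.90–7.41,
Alpha 7.80–12.48, Beta 12.87–19.14 Hz — are the first/last bin labels of
each band and are interpreted as closed intervals, which partitions bins
4..49 exactly; edges are configurable and written into every output
header. A zero-power band gets its midpoint as MF with a degeneracy
flag.

## Global Scale Factor

Recording gain (amplifier settings, electrode impedance, skull
conductivity) multiplies all spectral power by a subject-specific
constant carrying no physiological information. In the log10-power
domain this is an additive offset; its maximum-likelihood estimate under
an i.i.d. Gaussian log-residual model is the grand mean of `y - mu(age)`
over all channels and bins (the full grid — no sub-band restriction),
and subtracting it makes the corrected residual grand mean exactly
zero. Consequently z-maps are invariant under any global amplitude
rescaling of the raw EEG (checked to 1e-9 end-to-end). During norm
fitting, when no norms exist yet, a two-pass scheme is used: fit
preliminary norms, estimate each subject's GSF against them, remove it,
refit once (one iteration, fixed). The scalp-estimated factor is also
applied to source spectra, since a single sensor gain propagates
linearly through the inverse operator.

## Head model and source imaging

The forward model is the analytic potential of a current dipole inside a
homogeneous conducting unit sphere (insulating exterior, conductivity
0.33 S/m, electrode on the surface):

    V(r) = (1 / 4 pi sigma) q . [ 2 (r - r0)/d^3 + (r + (r - r0)/d) / F ],
    d = |r - r0|,  F = 1 - r.r0 + d,

the gradient with respect to source position of the monopole surface
kernel `(2/d - ln F)/(4 pi sigma)`. Source voxels sit on a regular cubic
grid inside the 0.85-radius ball (default 7 points per axis: 123 voxels
at 0.28 head-radius spacing); gain columns are the three Cartesian
moment components per voxel (or the radial projection) and are returned
average-referenced. This is a deliberately simple stand-in for realistic
head geometry — no BEM/FEM, no MRI.

The inverse is the ridge-penalized minimum-norm operator
`T = K'(K K' + lambda I)^{-1}`, computed by Cholesky factorization, never
an explicit inverse. Per frequency bin, source power is the per-voxel
diagonal of `T S(f) T'`, extracted as row sums of `(T S) o conj(T)`
without materializing the voxel-by-voxel matrix, and summed over the
voxel's moment components. Before inversion each voxel's gain block is
scaled to unit Frobenius norm (depth-bias mitigation, toggleable), with
the scaling undone on the output moments; at `lambda = 0` with a square
invertible gain the round trip is exact either way.

`lambda` is selected by generalized cross-validation on the
epoch-stacked Fourier coefficients over all retained bins. GCV only
needs the second moment `M = sum_k Re S(f_k)`, and in the eigenbasis of
`K K'` reduces to `(sum r_i^2 m_ii / n) / (sum r_i / n)^2` with
shrinkage residuals `r_i = lambda/(g_i + lambda)`; ties resolve to the
smaller candidate. One global `lambda` over all bins is the default —
cheaper and stabler at desk scale — with a per-bin mode behind a flag.

## Normative model

For every location (channel or voxel) and bin, log10 power is regressed
on polynomials of `u = log10(age)` (default degree 3; the degree is a
recorded model field, so alternative norms stay interchangeable). The
age-dependent SD comes from a second least-squares fit on the same
basis of `|r| * sqrt(pi/2)` — the half-normal correction making the fit
consistent for `sigma(age)` — where the fitted residuals `r` are first
studentized by `1/sqrt(1 - h_ii)`: OLS residuals shrink most exactly at
the sparsely sampled high-leverage ages, and without the correction the
SD is biased low there. A floor of 0.01 log10-units keeps `sigma`
strictly positive. A subject's z-spectrum is `(y - mu(age)) / sigma(age)`
elementwise, after GSF correction; ages outside the cohort range are
evaluated with an extrapolation warning. Note that z of a *new* subject
at a sparsely sampled age legitimately spreads slightly beyond unit SD
(prediction leverage); pooled over the cohort's age distribution the
fresh-subject z is standard normal to within a few percent.

Scalp and source norms are independent instances of the same model.
Broad-band parameters go through the same machinery with AP and MF
log10-transformed and RP logit-transformed (bounded support). Channel
matching between data and norms is by label, case-insensitive and
order-free; missing channels are an error, extra channels are dropped
with a warning. Norms serialize to a versioned JSON container
(`qeegnorm-v1`) with base64 float64 arrays — a lossless, text-only
round trip.

## Multiple comparisons

Two-sided maximum-statistic thresholds control the family-wise error
rate over all locations x bins jointly (a per-map threshold; joint
testing is the default, per-level maps get their own `m`). The analytic
i.i.d. form solves `(2 Phi(t) - 1)^m = 1 - alpha`; it is exact for
independent z and conservative under positive dependence. The empirical
alternative takes the inclusive (type-7) `(1-alpha)` quantile of
per-field max |z| over the normative cohort's residual z-fields (at
least 20 required), respecting the dependence structure of real maps; it
is preferred automatically when a norms file retains residual fields.
No cluster inference, FDR, or group statistics.

## Synthetic data

The cohort generator draws ages uniformly on the normative range
(default 5–87 years, n = 211) and, per location and bin, log10 power as
Gaussian (`sigma` = 0.2) around a mean that is linear in `u`: a 1/f-like
background (`1.5 - 1.2 log10 f`) declining with age (`-0.45 u`) plus a
fixed 10 Hz alpha peak (Gaussian in frequency, width 1.2 Hz) whose
amplitude grows with log-age (`0.3 + 0.25 u`) — a caricature of resting
eyes-closed EEG chosen to sit inside the model class the norms assume.
Cohorts can be realized as time-domain epochs by inverse-DFT spectral
shaping: coefficients with deterministic magnitude `N sqrt(p/2)` and
uniform random phase, so every epoch's periodogram reproduces the drawn
spectrum exactly. Dipole recordings are a bin-aligned sinusoid with
per-epoch random phase projected through the lead field plus white
sensor noise scaled to a target SNR at the oscillation bin. Every
generator is a pure function of (spec, seed).

What the generator does *not* emulate: EEG nonstationarity, artifacts,
1/f fine structure beyond the polynomial background, spatial correlation
between channels, or age-varying peak frequency. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-data violations of it.

## Problem sizes and determinism

Test and demonstration runs use the canonical desk scale: 19 channels,
49 bins, 24–50 epochs of 512 samples, 123 source voxels, cohorts of
60–211 subjects, 50-seed localization batches and 2000-subject null
simulations. All randomness flows through explicit integer seeds of
`numpy.random.default_rng`; identical config, inputs and seed reproduce
byte-identical exports.

## Known limitations

- The spherical head model ignores skull/scalp conductivity layers; use
  an external lead field (text format) for anything anatomical.
- The GSF model assumes a single frequency-independent gain.
- Norms fitted from small cohorts extrapolate poorly outside the
  observed age range; the extrapolation warning is not decorative.
- The ridge inverse shares minimum-norm's depth bias; unit-norm column
  scaling mitigates but does not remove it.
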
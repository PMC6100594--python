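# Methods

## The problem

Ultrasound pretreatment of wheat-gluten suspensions changes the protein's
free-thiol (SH) and disulfide (SS) content, which in turn controls how well
the protein hydrolyses. The goal is a calibration that maps in-situ NIR
spectra (fibre-optic probe in the sonication reactor, 256 channels over
850–2500 nm) to SH and SS in µmol/g, so the treatment endpoint can be read
off the spectrometer instead of an off-line DTNB assay. The package
implements the whole chain — preprocessing, interval-based variable
selection, linear (PLS) and nonlinear (neural network) calibration, and the
standard chemometric metrics — plus a synthetic-data generator, since the
original experimental spectra are not public.

## Synthetic data generator

**Trajectories.** Each analyte's time course at power density *P* is

    y(t) = baseline + shift·(P/160) + (amp0 + amp1·P/160) · e^(−γt) · sin(2πt/T + φ) + ε

with a random phase per treatment run, period T = 12 min, damping
γ = 0.01 min⁻¹, and white reference noise (SD 0.08 µmol/g for SH,
1.2 µmol/g for SS — roughly the repeatability of a DTNB assay). The
oscillation amplitude is non-decreasing in power density, reproducing the
observed "the stronger the sonication, the wilder the fluctuation"
behaviour, and the defaults keep SH in ≈[1.95, 5.42] and SS in
≈[32.3, 75.4] µmol/g, the physical ranges of the system. The net shift
(+0.3 µmol/g SH, −3 µmol/g SS at 160 W/L) encodes sonication's mild net
reduction of disulfides. The default design is 4 power densities × 16
timepoints (t = 0 included, so 4 × 16 = 64 aliquots) × 3 replicate spectra.

**Spectra.** A replicate spectrum is

    a(λ) = g · [ Σ_b L_b · G_b(λ) · c_b + baseline(λ) ] + o + ε(λ)

Gaussian bands G_b with loadings L_b sit inside the wavelength regions where
thiol/disulfide-linked secondary-structure signal is expected (SH: 869–947,
1207–1284, 1458–1536, 2205–2274 nm; SS: 933–992, 1388–1446, 2091–2148,
2217–2274 nm), alongside broad water/starch interferent bands whose
per-aliquot levels are random but shared across that aliquot's replicates.
Scatter is a per-replicate gain g ~ 1 + N(0, 0.05) and offset o ~ N(0, 0.01)
with detector noise SD 10⁻³ au. The SS band level can saturate as
c_eff = SS/(1 + SS/K); K = 50 µmol/g (the middle of the SS range) gives the
qualitatively nonlinear SS response, K = ∞ (default) is linear. The
wavelength grid is 256 equally spaced channels over 850–2500 nm (≈6.47 nm
spacing); the instrument's printed resolution (6.4 nm), step (9.5 nm) and
channel count are mutually inconsistent over that range, and the channel
count is taken as authoritative.

**What the generator does not emulate:** temperature drift, probe fouling,
wavelength-dependent (rather than flat multiplicative) scatter, correlated
detector noise, or any acoustic physics. Passing tests demonstrate that the
algorithms behave correctly on data with the assumed structure, not that the
instrument achieves these figures in a reactor. One honest consequence: with
the default mild scatter (5 % gain SD), raw spectra calibrate about as well
as SNV-corrected ones; SNV's advantage emerges when multiplicative scatter
dominates, as the scatter-dominated comparison test shows.

## Preprocessing

SNV standardises each spectrum to zero mean and unit sample (n−1) SD —
exactly invariant to per-spectrum gain/offset. MSC regresses each spectrum
on a reference and removes the fitted slope/intercept; the reference is the
calibration-set mean, and prediction spectra are corrected against the
calibration reference to avoid leakage. Savitzky–Golay derivatives default
to window 11, polynomial order 2, with scipy's polynomial edge handling so
the channel count is preserved. Methods are compared by full-spectrum PLS
RMSECV, ranked ascending.

## PLS kernel

PLS1 by NIPALS with X-deflation, mean-centring only (no variance scaling —
SNV already normalises). The regression vector is b = W(PᵀW)⁻¹q; score
vectors are mutually orthogonal by construction. The latent dimension is the
argmin of RMSECV over 1..max_pc (default cap 10), leave-one-out by default
(n ≤ ~100 throughout) with contiguous k-fold available; ties resolve to the
smaller count. Degenerate cases (constant y, vanishing X–y covariance)
raise rather than silently truncate to a meaningless model.

## Si-PLS interval search

The channel axis is partitioned into k contiguous intervals, the first
(n mod k) of size ⌈n/k⌉ and the rest ⌊n/k⌋. For each k and every 2-, 3- or
4-interval combination, the combination's channels are concatenated, the PLS
dimension is selected by calibration RMSECV, and the combination with the
lowest RMSECV wins; prediction-set metrics are computed for winners only and
never used for selection. Ties break toward fewer components, then fewer
intervals, then the lexicographically smallest index set, so the result is
independent of enumeration order. Intervals are reported 1-based; wavelength
ranges come from the instrument grid (the original study's printed
interval-to-wavelength correspondences are not consistent with any uniform
partition of 850–2500 nm, so this package reports its own grid-derived
ranges). The full k = 15–30 sweep with up to 4-interval combinations is
supported but costs ~C(30,4) cross-validated fits; the analysis drivers and
acceptance checks run a reduced sweep (k = 10–12, sizes {2,3}), which
exercises every property of the selection at tractable size.

## BP-ANN

The selected channels are compressed by mean-centred PCA (scikit-learn,
full SVD); the basis is refit on each training fold during input-width
selection so no held-out information leaks in. The network is three layers:
n_pc inputs, 5 sigmoid hidden units (configurable; the width is not
performance-critical at these sample sizes), one linear output. Inputs are
standardised per component — PCA scores span orders of magnitude and would
otherwise pin the sigmoids — and y is affinely scaled into [0.1, 0.9] and
unscaled on prediction. Training is full-batch gradient descent with
momentum (learning rate 0.05, momentum 0.9, up to 2000 epochs, early stop
when the loss change falls below 1e−8), weights initialised uniformly in
[−0.5, 0.5] from the run seed; identical seeds give bitwise-identical
weights. A NaN loss raises a divergence error naming the epoch and learning
rate. The input PC count is the argmin of the cross-validated network RMSECV
(5-fold contiguous by default; a leave-one-out network sweep is
affordable but slower).

## Evaluation

Samples are ordered by power density then time and split one-in-three:
1-based positions 3, 6, 9, … form the prediction set (64 → 43/21). Metrics:
Pearson R on calibration (R_c) and prediction (R_p) sets, RMSEC/RMSECV/RMSEP,
and RPD = SD(prediction-set reference, n−1)/RMSEP, flagged infinite when
RMSEP = 0. The (n−1) SD convention is validated by the closed-form identity
checks on published summary statistics. Model comparison declares the winner
by higher R_p, ties by lower RMSEP.

## Reproducibility and numerical choices

All randomness flows from a single user seed through named
`numpy.random.Generator` instances; derived stages use fixed small offsets
of the seed. End-to-end runs are bitwise reproducible. CSV round-trips use
pandas' round-trip float parser. The replicate spectra of an aliquot are
averaged before modelling (the calibration is over 64 samples, not 192
spectra); a flag preserves replicates for robustness studies.

## Known limitations

* The generator's linear band mixture makes full-spectrum PLS nearly exact
  at low noise, so absolute error levels are optimistic; only qualitative
  orderings (SNV vs raw under scatter, ANN vs PLS under saturation,
  selected vs full spectrum) transfer to real data.
* MSC inside the preprocessing comparison corrects all spectra against the
  batch mean before cross-validation; the slight within-comparison leakage
  affects ranking only, not any reported model.
* The network uses plain momentum backprop with no regularisation beyond
  early stopping; with dozens of calibration samples that is adequate, but
  larger studies would warrant weight decay or a modern optimiser.
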
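# Methods

This note documents the models, numerical choices and limitations of
`guvchol`, in the spirit of a methods section: everything here is what the
code does, not what it aspires to.

## Spectral GP analysis

A lambda-scan stack holds photon counts in 14 emission channels (10 nm bands
centred 565–695 nm).  The pipeline, per field of view:

1. **Registration** — each channel is aligned to the brightest channel by
   phase cross-correlation.  Shifts are estimated to 0.1 px but *applied
   rounded to whole pixels*, so photon counts are preserved exactly;
   subpixel estimates are reported in the run log.  A channel whose
   estimated shift exceeds a cap (default 10 px — e.g. a structureless
   noise channel) is left unshifted with a warning.
2. **Maximum-intensity projection** across channels.
3. **Bright-outlier exclusion** — pixels above either an absolute count or
   an upper quantile (default: 99.9th percentile) are excluded from the
   mask.  On clean synthetic data the quantile mode necessarily flags the
   brightest ~0.1% of pixels (all on the membrane); this is harmless because
   the GP estimator is unbiased under any selection on total intensity (see
   below).
4. **Contrast stretch** to [0, 1] clamping at user percentiles (default
   1/99), then **Otsu thresholding** on a 256-bin histogram.  Only the
   largest connected component is kept (one vesicle per field of view);
   discarded components are counted in the log.
5. **Pixel-wise GP** from the channels nearest 570 and 640 nm.  On the
   565…695 grid both wavelengths fall exactly between two centres; ties
   resolve to the shorter wavelength, so the analysis bands are 565 and
   635 nm (logged).  Pixels with $I_B + I_R$ below a floor (default 10
   counts) are dropped: the ratio's *variance* explodes at low counts even
   though its mean does not.
6. **Vesicle mean** — the unweighted mean over defined pixels.

**Why per-pixel GP is unbiased.** Conditional on the total $N = I_B + I_R$,
$I_B \sim \mathrm{Binomial}(N, p)$ with $p$ set by the spectrum, so
$E[\mathrm{GP} \mid N] = 2p - 1$ independent of $N$.  Photoselection and the
count floor select on $N$ only, hence do not bias the mean GP; they only
reweight pixel noise.  The pixel mean is taken over pixels (not ring
angles): photoselection-bright arcs contribute more pixels above the floor,
which is accepted because the noise-free GP is identical at every membrane
angle.

## TCSPC reconvolution fitting

The decay model is a sum of $n \le 2$ exponentials convolved with the IRF
and wrapped at the repetition period $T = 50$ ns (20 MHz), plus a uniform
background, fitted by **Poisson maximum likelihood** — least squares is
mis-weighted in the low-count tail of counting data.

The forward model is evaluated in the Fourier domain: the periodically
wrapped exponential with unit mass has exact Fourier coefficients
$D_k = 1/(1 + i\omega_k\tau)$, $\omega_k = 2\pi k/T$, so multiplying the FFT
of the *binned* IRF by $D_k$ reproduces the bin-integrated continuous
convolution exactly — the bin box-integration factor is already inside the
IRF's FFT and carries through.  Remaining error is Fourier aliasing of the
narrow IRF (FWHM 0.2 ns vs 0.195 ns bins at the default 256 bins); this
biases fitted lifetimes by up to ~0.3% on the study's lifetime range, and
vanishes when the IRF is resolved (≲0.01% at 2048 bins).  Rarely the
aliased model rings marginally negative before the rise; those bins are
clamped to zero with matching gradient masking.

Optimization is L-BFGS-B on log-parameters $(\log\tau_k, \log I_k, \log B)$
with the **analytic gradient** (numerical gradients are rounding-noise
limited near the optimum at $10^5$–$10^6$ photons).  Initialization is
deterministic: a method-of-moments lifetime guess $\hat\tau$ from the mean
arrival time minus the IRF centroid, with two starts
$(0.5\hat\tau, 2\hat\tau)$ and $(0.9\hat\tau, 1.1\hat\tau)$; the better
likelihood wins, so fits are seed-independent.  Components are reported
sorted by ascending lifetime; a component carrying $<10^{-3}$ of the total
intensity is collapsed (monoexponential data degenerate gracefully).  Fits
require ≥500 photons in the window (default 0.2–45 ns); parameter
covariance is the inverse observed information from a central-difference
Hessian in natural parameters; goodness is Pearson's reduced $\chi^2$.

Per vesicle, all membrane photons are aggregated into one decay and fitted
once (one lifetime per GUV); per-pixel analysis is reserved for phasors.

## Phasor analysis

$g + is$ is the photon-weighted first Fourier coefficient of the decay at
$\omega = 2\pi h / T$.  Two corrections are applied:

* **Midpoint/sinc correction** — bin-integrated counts phased at bin centres
  underestimate the continuous coefficient by $\mathrm{sinc}(\omega\Delta/2)$;
  it is divided out.
* **IRF division** — the complex phasor is divided by the IRF's phasor (the
  phasor analogue of reconvolution), removing instrument phase delay and
  modulation.

With these, noise-free monoexponentials sit on the universal semicircle to
$10^{-16}$ at 4096 bins; at the default 256 bins IRF aliasing limits the
identity to ~$10^{-4}$.  Cloud selection is a circle in $(g, s)$ units
(default radius 0.02 — vendor software counts this radius in screen pixels,
a conversion that is not documented anywhere, so the package specifies it in
phasor units); the cloud lifetime is the phase lifetime
$\tau_\phi = \bar s / (\omega \bar g)$ of the photon-weighted mean phasor.
Phasor-image denoising is a median filter of odd kernel size (commercial
packages use a proprietary wavelet filter here; a median filter is the
transparent equivalent for tightening photon clouds, and photon totals are
untouched).

## Calibration and error propagation

The calibration line $y = c + mx$ is fitted to condition means by weighted
least squares with weights $1/\mathrm{SD}^2$ (statsmodels WLS).
Inverse-variance weighting is the default because it reproduces the
published regression parameters from the reference table, which unweighted
fitting of the means does not; equal weights (= OLS) remain available.

Inversion is $\hat x = (y - c)/m$; its delta-method variance is

$$\sigma_x^2 = \frac{\sigma_y^2 + \mathrm{se}_c^2}{m^2}
 + \hat x^2 \frac{\mathrm{se}_m^2}{m^2}
 + 2\hat x \frac{\mathrm{cov}(c, m)}{m^2},$$

with $\sigma_y = \mathrm{SD}/\sqrt{n}$ the SEM of the condition mean (the
magnitudes of the published propagated errors are only consistent with
SEM-scale, not SD-scale, inputs).  The covariance cross-term carries the
sign the Jacobian $(\partial\hat x/\partial c, \partial\hat x/\partial m) =
(-1/m, -\hat x/m)$ dictates — positive; since $\mathrm{cov}(c,m) < 0$ for
positive-mean regressors it usually shrinks the error.  A covariance-free
mode is provided for comparison, and a negative total variance (possible
only with a pathological hand-built model) falls back to the
covariance-free sum with a warning.

Group comparisons use the tie-corrected Kruskal–Wallis $H$ with the
$\chi^2_{k-1}$ approximation (appropriate at ≥50 vesicles per group; no
exact permutation, no post-hoc pairwise tests).  The cross-modality
agreement check pools per-GUV estimates across conditions within each
modality and tests the two pooled samples — per-condition two-sample rank
tests would flag the small systematic offsets between the probes'
calibrations even when the dose-response is identical.

## Phantom generators

The generators define the study conditions; their defaults are the
acquisition settings of the emulated experiment and are not tuned.

**Spectral phantoms.** 256×256 px field, one membrane ring (random radius
40–80 px, annulus FWHM 4 px, radial Gaussian profile
$\sigma = \mathrm{width}/2.355$, i.e. a diffraction-limited cross-section).
Each pixel's emission spectrum is a two-Gaussian-band mixture (580 and
635 nm centres, 35 nm sigma) whose weight is solved so the 565/635-channel
ratio encodes the prescribed GP exactly — only the two analysis channels
matter; intermediate channels just need to be smooth.  The representable GP
interval of this model is about [−0.76, 0.51], covering every tabulated
condition; batch draws are clamped to it.  Photoselection is multiplicative,
$(1-d) + d\cos^2(\theta - \theta_0)$ with default depth $d = 0.6$,
wavelength-independent.  The brightest membrane pixel expects 1000 photons
summed over channels (photon-counting detector at realistic accumulation),
background 2 counts/pixel spread over channels; counts are independent
Poisson.  Condition batches draw per-vesicle true GP from
$\mathcal N(\text{mean}, \text{SD})$ of the tabulated condition.

**Decay phantoms.** 256 bins over 50 ns; Gaussian IRF (FWHM 0.2 ns, centred
at 2 ns — a standard desk substitute for the uncharacterized
vendor-generated IRF); expected bin masses are exact integrals of the
exponentially modified Gaussian, wrapped over 3 preceding pulses (wrap
truncation < $10^{-4}$ for τ ≤ 7 ns); $10^5$ photons per decay.  Pile-up is
*not* simulated (the emulated acquisition kept rates below 0.5
photons/pulse precisely to avoid it).  A condition batch parametrized only
by a target $\tau_{m,\mathrm{int}}$ uses a fixed biexponential composition:
25% of photons at $\tau_m/2$ and 75% at $7\tau_m/6$, whose intensity-weighted
mean is $\tau_m$ exactly.  Two-domain vesicles give each pixel a
monoexponential decay at its domain's lifetime.

Seeding is counter-based (`SeedSequence([seed, index])`), so batches are
order-independent and every output is bit-reproducible from `(spec, seed)`.

**What the phantoms do not emulate** — and hence what passing recovery
tests do *not* demonstrate about real data: optical blur beyond the ring
profile (no PSF), chromatic aberration or real inter-channel drift
(registration is exercised on constructed shifts only), detector afterpulse
and pile-up, the true NR12A spectral lineshape, IRF asymmetry, autofluorescent
background structure, vesicle polydispersity beyond ring geometry, and
membrane heterogeneity other than the idealized two-domain split.

## Experiment sizes and runtimes

Recovery experiments use 50 vesicles per condition (the stated study
minimum) for per-condition grand-mean checks, and 100 per condition for the
end-to-end estimate-consistency experiment, where the ~2 mol% comparison
band would otherwise sit at ~2 standard errors of the GP condition mean
(SD ≈ 0.1, slope ≈ 0.0104 ⇒ 1.1–1.5 mol% per-mean sampling noise at
n = 50).  The full test suite runs in ~1 minute; the acceptance script in
~20 s.

## Known limitations

* The fitted-lifetime bias from IRF aliasing (~0.3% at 256 bins) is a
  genuine discretization effect of fitting with an under-resolved binned
  IRF; use a finer grid when the IRF matters.
* Calibration is linear over 0–40 mol% only; no nonlinear or Bayesian
  calibration, and no domain-resolved cholesterol estimation for
  phase-separated vesicles.
* Vendor file formats (.lif/.ptu) are not read; I/O is plain TIFF/CSV/JSON.
* Registration is translation-only; rotational drift is out of scope.
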
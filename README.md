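# guvchol

Quantify cholesterol in the membranes of giant unilamellar vesicles (GUVs)
from two complementary fluorescence readouts, and validate the whole analysis
chain on synthetic phantoms with known ground truth.

The package is aimed at membrane biophysicists who image GUVs on a confocal
microscope with environment-sensitive probes:

* **NR12A** (a solvatochromic Nile Red derivative) reports lipid packing
  through a blue-shift of its emission spectrum.  From a lambda-scan stack
  the package computes the pixel-wise **generalized polarization**

  $$\mathrm{GP} = \frac{I_B - I_R}{I_B + I_R},$$

  with $I_B$ and $I_R$ the photon counts at the 570 nm and 640 nm analysis
  wavelengths, and averages it over the segmented membrane of each vesicle.

* **Flipper-TR** (a mechanosensitive flipper probe) reports lateral packing
  through its fluorescence lifetime.  TCSPC decays are fitted with a
  double-exponential **reconvolution model** (IRF-convolved, periodically
  wrapped, Poisson maximum likelihood), and the headline readout is the
  intensity-weighted mean lifetime

  $$\tau_{m,\mathrm{int}} = \frac{\sum_k I[k]\,\tau[k]}{\sum_k I[k]},\qquad k = 1,2.$$

  **Phasor analysis** maps each decay to its first Fourier coefficient
  $(g, s)$ at the 20 MHz repetition frequency; monoexponential decays lie on
  the universal semicircle $g^2 + s^2 = g$, and coexisting lifetime domains
  (liquid-ordered vs liquid-disordered) separate into distinct photon clouds.

* **Calibration inversion.** Reference GUVs of known cholesterol content give
  a line $y = c + m x$ ($x$ = mol% cholesterol, $y$ = GP or lifetime), fitted
  by inverse-variance weighted least squares.  An unknown population's mean
  readout is inverted, $\hat x = (y - c)/m$, with delta-method error
  propagation combining the readout SEM and the fit's parameter covariance.

* **Phantoms.** A synthetic-data module emulates the microscope: GUV membrane
  rings with cos² photoselection brightness modulation and Poisson counting
  noise for the spectral channel stacks, and IRF-convolved wrapped
  biexponential decays for TCSPC — every stage of the pipeline is testable
  without real data.

## Worked example

```python
from guvchol import datasets
from guvchol.calibration import LinearCalibration
from guvchol.experiment import recover_condition_mean

# calibration line from the bundled gel-swelling reference table
model = LinearCalibration(datasets.calibration_points("GP"), "GP").fit()
print(model.summary())

# simulate a treated condition (mean GP -0.44 +/- 0.08), analyze, invert
mean, records = recover_condition_mean("GP", -0.44, 0.08, 10, seed=7)
est = model.propagate(mean, records["value"].std(ddof=1), len(records))
print(f"recovered mean GP over {len(records)} synthetic GUVs: {mean:.3f}")
print(f"estimated cholesterol: {est.chol_molpct_hat:.1f} +/- {est.se:.1f} mol%")
```

prints

```
Linear calibration (GP vs mol% cholesterol)
====================================================
weighting          : inverse_variance
n calibration pts  : 4
intercept c        : -0.5395 +/- 0.0150
slope m            : +0.01041 +/- 0.00091 per mol%
cov(c, m)          : -8.633e-06
wtd RMS residual   : 0.0164

recovered mean GP over 10 synthetic GUVs: -0.456
estimated cholesterol: 8.1 +/- 2.0 mol%
```

The intercept is the GP of a cholesterol-free DOPC membrane; the slope says
each mol% of cholesterol raises the GP by ~0.0104.  The ten phantoms were
generated around GP −0.44 (a mildly treated population), the pipeline
recovered −0.456, and inverting through the line estimates ~8 mol%
cholesterol with a ~2 mol% propagated uncertainty.

A command-line interface mirrors the library:

```sh
guvchol simulate decay --config spec.json --seed 3 --out sim/
guvchol flim --in sim/decay.csv --out fits/
guvchol calibrate --in table.csv --out model.json
guvchol estimate --model model.json --records records.csv --out estimates.csv
guvchol experiment --config experiment.json
```

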
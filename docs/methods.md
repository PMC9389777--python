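# Methods

## Signal model

The simulator treats each analyte as a single fluorophore with
separable Gaussian excitation and emission bands. A measured
excitation–emission matrix (EEM) is

```
I(λex, λem) = Σᵢ cᵢ · responseᵢ · enhancementᵢ · recovery · Exᵢ(λex) · Emᵢ(λem)
              + background (+ noise)
```

with `Ex`/`Em` unit-peak Gaussians `exp(−4 ln2 (λ−center)²/fwhm²)`.
The model is exactly bilinear: a noiseless mixture EEM equals the sum of
the single-analyte EEMs plus one background. All downstream operations
(synchronous extraction, Savitzky–Golay differentiation, blank
subtraction, amplitude readout) are linear, so the derivative amplitude
at any wavelength is affine in the concentration vector — the property
the whole quantification scheme rests on.

Assumptions baked into the model: no inner-filter effects, no
photobleaching, no Rayleigh/Raman scatter ridges, no instrument drift,
and plasma chemistry reduced to a recovery factor plus elevated
background. Passing tests therefore demonstrate the *method logic*
(resolution, zero-crossing selectivity, linearity, statistics), not
robustness to those real-instrument artefacts.

## Parameter defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| band centres | FEX 267/294 nm, PSE 261/286 nm | the drugs' published excitation/emission maxima |
| band FWHM (ex = em) | 10 nm, both analytes | reconstruction, see below |
| response | FEX 0.5, PSE 0.625 a.u. per ng/mL | equal ~500 a.u. peaks for the 1000/800 ng/mL illustration pair |
| enhancement | 1.0 | reference = optimised SDS (2 mL, 0.5 %) + HCl buffer pH 2 conditions; scenarios scale it |
| scan grids | 220–340 nm, 1 nm pitch | covers both band pairs; integer Δλ stays grid-commensurate |
| Δλ | 25 nm | the method's working offset; confirmed by the packaged grid-search optimiser |
| derivative | Savitzky–Golay, quadratic, 5 points | the "data points = 5" vendor convention; central differences available for sensitivity analysis |
| background | 2 a.u. solvent/tablet, 12 a.u. plasma | small constant offsets; removed exactly by the derivative and by blank correction |
| noise | additive Gaussian, σ = 0.3 a.u. | ≈0.06 % of full scale, chosen so simulated recovery RSDs land near the reported ~0.5–2 % |
| recovery factor | 1.0 solvent/tablet, 0.95 plasma | mirrors the ~95 % spiked-plasma recoveries |
| calibration | 6 levels/analyte within 100–1500 (FEX) / 50–1000 (PSE) ng/mL, 3 scans per level, unweighted OLS | the reported linear ranges; no weighting is described for the assay |
| LOD/LOQ σ | calibration residual SD | one of the ICH options; blank-SD or intercept-SD can be passed instead |

**Band widths are the one strongly constrained reconstruction.** No
band widths or absolute intensities are published for this assay, but
two qualitative facts pin them down. First, the synchronous spectrum of
a 1:2 mixture must show two distinguishable maxima ~7 nm apart while the
conventional emission bands (8 nm apart) merge — with Gaussian bands
this forces FWHM ≈ 10–11 nm (wider bands merge the synchronous maxima
too; at 30–35 nm the mixture trace is unimodal). Second, equal
excitation and emission widths make each analyte's synchronous band
*exactly symmetric* about a grid point, which makes the zero-crossing
readout exact (below). The defaults are therefore ex = em = 10 nm for
both analytes, configurable per fluorophore.

## Zero-crossing geometry and the 293 nm readout

With Δλ = 25 nm the PSE synchronous band peaks exactly at 286 nm,
because PSE's Stokes shift (286 − 261 = 25 nm) equals Δλ: both Gaussian
factors are centred on 286. Its Savitzky–Golay derivative at 286 nm is
zero to machine precision (an odd-symmetric operator on an even
function), so 286 nm reads FEX with no PSE contribution.

FEX's Stokes shift is 27 nm, so at Δλ = 25 its synchronous band centre
is pulled between λex + Δλ = 292 and λem = 294; for equal band widths it
lands exactly midway, at **293 nm**, again on a grid point with exact
symmetry. The package therefore reads PSE at 293 nm — the zero crossing
of the simulated FEX band — rather than the instrument's printed
294 nm. This is a deliberate choice: the published wavelength reflects
the real (asymmetric, non-Gaussian) band shapes of the instrument, and
in the Gaussian reconstruction no choice of finite widths places the
FEX zero crossing at 294 (reading there would incur a FEX cross-signal
larger than the PSE signal itself). By default the pipeline does not
hard-code either value: it locates the analytical wavelengths from
noiseless pure-standard scans at the working Δλ (`locate_analytical_
wavelengths`), which yields 286/293 under the defaults and adapts
automatically if the band model or Δλ changes.

The Δλ grid-search optimiser scores each candidate offset by the
smaller of the two per-unit-concentration derivative sensitivities at
the located readout wavelengths, subject to a <5 % cross-sensitivity
constraint. Even offsets on the 1 nm grid put the band centres between
grid points (half-integer centres), breaking the exact symmetry and
failing the constraint; among the feasible odd offsets, 25 nm maximises
sensitivity because it best matches the two Stokes shifts.

## Numerical choices

- **No interpolation anywhere.** Δλ must be an integer multiple of both
  grid steps; amplitude readout takes the nearest grid point, ties
  toward the lower wavelength. This keeps every run bit-reproducible.
- **Derivative endpoints** use scipy's polynomial-extension rule
  (`mode="interp"`): the same local quadratic fitted to the first/last
  window, evaluated at the edge points, so output length equals input
  length and lines/quadratics are differentiated exactly end to end.
- **Degenerate inputs** raise typed errors: identical calibration
  concentrations, spectra shorter than the window, even windows,
  off-grid Δλ, zero slopes, zero-variance F-tests.
- **Negative predicted concentrations** are returned with a flag, never
  clipped — recovery statistics near the LOD would otherwise be biased.
- **Display rounding** mirrors the assay's tables: percent recoveries
  to 2 dp *before* mean/RSD (the published summary lines are
  reproducible only under this convention), RSD shown to 3 dp; all
  comparisons in code use tolerances, not strings.
- **Seeding.** Every stochastic routine takes a seed; study generation
  spawns per-sample child seeds (< 2³¹) from one root generator, and
  manifests/reports are byte-identical across runs with equal seeds.

## Validation statistics

Recovery is 100·found/added; RSD uses the sample (n−1) SD. The method
comparison uses the classical pooled-variance two-sample t statistic
(Welch available) and the variance-ratio F with the larger variance in
the numerator; critical values come from the dfs implied by the group
sizes (2.306 and 6.388 for two groups of five at P = 0.05). Computing
t/F from raw replicate vectors or from their (mean, RSD, n) summaries
is equivalent to machine precision, which the tests exploit as an
oracle. Two published inconsistencies are handled explicitly: the
standard-addition FEX RSD prints 1.431 but its own three rows give
1.413 (the package asserts the mean only), and the printed t values
(0.759/1.540) recompute to 0.746/1.533 from the rounded printed
means/RSDs (treated as agreement within input rounding, tolerance 2 %).

### Robustness semantics

Δλ ± 1 nm is an *instrument setting*: calibration standards and test
samples are both scanned at the shifted offset and the readout
wavelengths are re-located on the perturbed pure-standard spectra, as
an analyst re-reads zero crossings on the recorded traces. The
robustness runner uses 0.5 nm grids so the half-step band shifts of an
odd→even Δλ change stay on-grid. pH ± 0.1 and buffer volume ± 0.1 mL
are *sample-chemistry* variations, modelled as ±1 % / ±0.5 %
enhancement multipliers applied to the test samples against a nominal
calibration — so an x % enhancement change shifts recovery by exactly
x % in the noiseless limit. All perturbations replay the same noise
stream, making the null perturbation an exact replica of the
unperturbed assay.

## Study sizes

The shipped defaults keep the full simulated study light: 6 calibration
levels × 3 scans per analyte, 5 mixture and 5 plasma pairs × 3 scans,
3 blanks per matrix, and 8 robustness replicates × 3 scans per
perturbation; the large-sample check uses 100 independent noisy 1:2
mixtures (20 replicates of each of the 5 tablet-ratio levels). A full
pipeline run completes in a few seconds on one core.

## Greenness

The eco-scale, AGREE and NEMI/GAPI *engines* are general: ledgers and
profiles are user-supplied JSON/CSV. The packaged fixtures for this
assay are **reconstructions** — the published assessment reports only
the totals (eco-scale 79; AGREE 0.81 vs 0.58; GAPI 5 green/1 red vs
4 green/3 red) — built from the reagent list and procedure so that the
engines reproduce those totals: reagent penalties ethanol 4,
acetonitrile 4, HCl buffer 2, SDS 1 (pictograms × signal word × amount
bracket), instruments 2, waste 8, totalling 21 penalty points. Each
fixture file carries a comment flagging the decomposition as synthetic.
AGREE principle transfer functions (raw input → score) are out of
scope; users supply the 12 principle scores directly, and the reported
value is the weighted mean rounded half-up to 2 decimals.

## Known limitations

- Gaussian bands cannot reproduce the instrument's exact band shapes;
  published slopes/intercepts/LOD/LOQ are instrument-specific and are
  shipped only as reference constants, not regenerated.
- The ~10 nm default widths are narrower than typical solution-phase
  emission bands; they are the price of reproducing the method's
  resolution narrative with symmetric Gaussians (see above).
- Surfactant/solvent/pH chemistry is represented only as enhancement
  multipliers; the package does not predict which conditions win.
- Constant-energy synchronous scanning, higher-order derivatives, and
  multivariate calibration are out of scope.
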
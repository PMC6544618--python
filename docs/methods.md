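# Methods

## Model

`osteotex` treats a cortical-bone region of interest as an unordered
population of 8-bit gray levels and characterizes its normalized histogram
$P_k$, $k = 0..255$, by first-order statistics: mean, population standard
deviation (sigma), skewness, excess kurtosis, energy (sum of squared bin
probabilities), Shannon entropy, and the Nakagami parameter
$m = \mathrm{E}^2(X^2)/\mathrm{Var}(X^2)$. All moments use the population
convention (divide by $N$), so a histogram-path computation and a
raw-pixel-path computation coincide exactly; at the $\sim 10^5$ voxels of a
typical ROI the sample-size correction would be negligible anyway. The
eighth reported quantity is the fraction of mass at gray levels 0–64
inclusive — the first quartile of the 8-bit range — which proxies the
share of low-density bone.

Conventions that required a decision:

* **Entropy** is the standard negative sum, natural log by default with a
  selectable log2 base. The natural log is the default because the
  analytic worked-example values only come out right in nats (a unit-bin
  Gaussian of scale 25 has differential entropy
  $\tfrac12\ln(2\pi e\,625) \approx 4.64$).
* **Energy** is $\sum_k P_k^2$ — a plain square of the probabilities. Its
  maximum of 1 is attained exactly when one bin holds all mass, which is
  also the only case with entropy 0; both facts are asserted as invariants.
* **Sums run over all 256 levels.** The $k=0$ term vanishes in the mean
  but not in energy or entropy.
* **Degenerate inputs raise.** A constant ROI has undefined skewness,
  kurtosis and Nakagami parameter; these raise typed errors rather than
  return sentinels, so cohort summaries can never silently average
  infinities.

## Analytic worked examples

Three densities on $x \in [0,255]$ — Normal(128, 25), Normal(128, 50),
Rayleigh(100) — are discretized by **point evaluation at the integer
levels** (not bin integration); this is the simplest convention and the
one that reproduces the reference first-quartile percentages. Two
normalization conventions coexist deliberately:

* entropies use the **renormalized** discretization (total mass forced to
  1), giving 4.638, 5.281, 5.418 nats;
* first-quartile percentages use the **un-renormalized** discretization
  (total mass 0.9999, 0.9895, 0.9618 — the tail truncated outside the
  8-bit range is simply lost), giving 0.554 %, 9.695 %, 18.78 %.

No single convention reproduces both published triplets at once; each
value sits within the stated tolerance of its reference. Note that the
discretized Normal(128, 25) has mean 127.9999959, not 128 exactly: the
integer grid is asymmetric about 128 (level 0 has no mirror image at 256).
The Rayleigh's analytic mean is $100\sqrt{\pi/2} \approx 125.3$; nothing
asserts 128 for it. The squared Pearson correlation between entropy and
quartile mass is computed on whatever triplets are supplied;
`worked_example_table` reports it for its own computed triplets (≈ 0.88),
while the reference value 0.9221 belongs to the published, differently
rounded triplets and is recovered by `pearson_r2` on those numbers.

The demonstration image pair contrasts a constant 16×16 image (energy
exactly 1, entropy 0) with a shuffled multiset built from 128 antithetic
pairs $(k, 256-k)$, $k \in [1,255]$, whose pixel sum is exactly
$256 \cdot 128$ — the two images share mean 128 *exactly* while differing
maximally in texture.

## Region of interest

The ROI is a slab of `round_half_up(length_mm·1000 / voxel_size_um)`
slices (minimum 1) centered on `floor(center_fraction · nz)`; the default
0.5 mm at 9 µm gives 56 slices. A slab that does not fit raises — it is
never clipped. Within the slab, voxels at or above `mask_threshold` count
as bone, a procedural stand-in for manual contouring. The default
threshold is **25**: background and marrow sit at level 0 in the synthetic
volumes while cortex is ≈ 100, and the left tail of a broad, left-skewed
cortical distribution must survive — a cutoff of 50 would discard ~1.4 %
of the control distribution's mass, bias sigma and skewness visibly, and
even reverse the sign of the between-group skewness difference. Whether
real marrow-cavity voxels should be excluded by contouring instead of
thresholding is a genuinely open question; the threshold is configurable.

## Synthetic data generator

**Cortical cohorts.** Each specimen is an annular cylinder (default outer
radius 40 voxels, canal radius 20, 56 slices ≈ 2.1×10⁵ shell voxels at
9 µm) whose shell voxels are i.i.d. draws from a skew-normal whose
*analytic* mean, SD and skewness equal the group targets. The shape
parameter is found by bracketed root-finding on the standard skewness
formula in $\delta = \alpha/\sqrt{1+\alpha^2}$; scale and location follow
in closed form. The family covers $|\gamma_1| < 0.9953$, enough for both
default groups: control (98.1, 17.8, −0.906) and low-magnesium
(105, 12.6, −0.729), 7 specimens per arm — the study conditions the
pipeline is designed to compare. Draws are rounded half-to-even (unbiased)
and clipped to [0, 255]; with the default targets the clip probability is
below 10⁻⁴, so recovered moments stay within 0.5 (mean), 0.3 (sigma) and
0.1 (skewness) of the targets. Between-specimen variability beyond
sampling noise is not modelled — the dispersion printed next to the
reference group means is ambiguous (SD vs SEM), so only the means are
matched. Voxels are spatially independent; the histogram analysis is
order-blind, so spatial correlation, partial-volume blur and
reconstruction artifacts of real scanners are deliberately out of scope.
Consequently, passing tests show the *pipeline* recovers what the
generator encodes — not that real bone follows a skew-normal.

**BMD phantom.** Five parallel cylindrical inserts (radius 10, length 40
voxels) at densities 200–1000 mg-HA/cm³, mapped linearly to gray levels
with defaults 200→60 and 1000→220 (slope 0.2, intercept 20; no published
attenuation-to-gray mapping exists, so the defaults simply keep all
inserts on-scale), plus Gaussian noise of sigma 5 gray levels and a base
material at level 30. For a constant-plus-noise insert the Nakagami
parameter is $(\mu^2+\sigma^2)^2/(4\mu^2\sigma^2+2\sigma^4) \approx
\mu^2/4\sigma^2$, strictly increasing in $\mu$ and nearly quadratic in
density; over the default range its OLS fit against density has
$r^2 \approx 0.97$, emulating the linear correlation seen with real
phantoms without asserting any real-phantom number.

## Statistical comparison

Per parameter, a two-sided F-test (larger sample variance in the
numerator) at α = 0.05 chooses between the pooled t-test and Welch's
unequal-variance t-test; α = 0.05 mirrors the global significance
convention. Percent change is signed, on the raw parameter scale, relative
to the first group; for parameters that are negative on the raw scale
(skewness, often kurtosis) the sign of the change and the direction "toward
zero" can disagree, and the report deliberately carries the raw-scale
value. No multiple-testing correction is applied across the seven
parameters; rows carry raw p-values. Type-I calibration of the full
gate-then-test procedure is verified by simulation: with both arms drawn
from the control specification, each parameter's rejection rate over 200
replicate cohorts stays within three binomial standard errors of 0.05.
Calibration replicates use a reduced shell (outer radius 16, canal 8, 8
slices ≈ 4.8×10³ voxels): the rejection rate under the null does not
depend on voxel count, and the small geometry keeps the simulation to a
few seconds.

## Numerical choices

* Histograms built from pixels must sum to 1 within 1e-9; analytic
  (density-discretized) histograms may carry a truncation deficit, with
  total mass in (0, 1].
* Round-half-up for the slab slice count (0.5 mm at 9 µm must give a
  definite 56); round-half-to-even for intensity quantization.
* Slice files in a directory are stacked in lexicographic filename order;
  only 8-bit input is accepted — 16-bit data must be converted upstream,
  since every parameter is defined on the 0–255 levels.
* Seeds: each specimen draws from `SeedSequence([group_seed,
  specimen_index])`, so cohorts are reproducible per specimen and
  independent across specimens.

## Limitations

* The generator matches first-to-third moments only; kurtosis is whatever
  the skew-normal implies, and no spatial structure is simulated.
* Trabecular bone is out of scope: partial-volume mixing at thin
  trabeculae invalidates the single-population histogram model.
* No attenuation-unit calibration is attempted; gray levels are
  dimensionless, and the phantom's density-to-gray mapping is a synthetic
  convention, not a scanner calibration.
* The analytic worked-example values depend on the discretization
  convention at the third significant digit; the package documents its
  convention rather than guessing any other implementation's.
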
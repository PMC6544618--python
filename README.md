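# osteotex

First-order gray-level texture analysis of micro-CT bone volumes.

## The problem

Bone mineral density (BMD) summarizes a region of cortical bone by a single
average, but two regions with the same mean attenuation can have very
different internal structure. `osteotex` quantifies that structure from the
*distribution* of 8-bit gray-scale intensities (0–255) in a mid-diaphysis
region of interest, for studies that compare cortical bone quality between
cohorts — for example, rodent diet experiments imaged at ~9 µm voxel size.

For the normalized gray-level histogram $P_k$ ($k = 0..255$) of the ROI it
computes seven parameters:

$$\bar m = \sum_k k P_k,\qquad
  \sigma = \Big[\sum_k (k-\bar m)^2 P_k\Big]^{1/2},\qquad
  \gamma_1 = \frac{1}{\sigma^3}\sum_k (k-\bar m)^3 P_k,$$

$$\gamma_2 = \frac{1}{\sigma^4}\sum_k (k-\bar m)^4 P_k - 3,\qquad
  E = \sum_k P_k^2,\qquad
  H = -\sum_k P_k \ln P_k,$$

$$m_{\text{Nak}} = \frac{\mathrm{E}^2(X^2)}{\mathrm{Var}(X^2)},$$

plus the fraction of histogram mass at or below gray level 64 (the first
quartile of the 8-bit range), a proxy for the share of low-density bone.
The Nakagami parameter $m_{\text{Nak}}$, a concentration statistic borrowed
from ultrasound backscatter analysis, tracks mineral density linearly in a
calibration phantom.

Around the parameters sit:

* **I/O** for multi-page TIFF, slice directories, and raw+JSON volumes
  (`osteotex.io`), with CSV output for all tables;
* **ROI extraction** — a 0.5 mm slab at the mid-diaphysis with an intensity
  threshold separating cortex from marrow/background (`osteotex.roi`);
* **analytic worked examples** — two Gaussians (location 128, scales 25 and
  50) and a Rayleigh (scale 100) discretized on the gray axis
  (`osteotex.analytic`);
* **a synthetic data generator** — annular cortical shells drawn from
  skew-normal distributions moment-matched to target (mean, σ, skewness),
  and a five-insert BMD phantom (200–1000 mg-HA/cm³)
  (`osteotex.synthetic`);
* **group comparison** — per-parameter two-sample t-tests gated by an
  F-test on the variances, with signed percent change
  (`osteotex.compare`);
* **a CLI** — `osteotex simulate | analyze | compare | worked-examples`.

## Worked example

```python
import osteotex as ot

# Entropy vs. low-intensity mass for the three analytic densities
rows, r2 = ot.worked_example_table()
for r in rows:
    print(f"{r.family:12s}  H = {r.entropy_nats:.3f} nats   "
          f"below-quartile = {r.quartile_pct:.2f} %")
```

prints

```
gaussian_25   H = 4.638 nats   below-quartile = 0.55 %
gaussian_50   H = 5.281 nats   below-quartile = 9.70 %
rayleigh_100  H = 5.418 nats   below-quartile = 18.78 %
```

Although the two Gaussians share mean 128, the wider one carries 18× more
mass below the first quartile, and the Rayleigh twice that again — entropy
rises in step, which is why it serves as a heterogeneity index.

A full synthetic two-cohort study:

```python
control = ot.control_group_spec(seed=11)   # mean 98.1, sigma 17.8, skew -0.906
treated = ot.low_mg_group_spec(seed=12)    # mean 105,  sigma 12.6, skew -0.729
vols_a, vols_b = ot.generate_cohort(control, treated)   # 7 + 7 specimens

spec = ot.RoiSpec()   # 0.5 mm slab, threshold 25
pa = [ot.texture_profile(ot.extract_roi_pixels(v, spec)) for v in vols_a]
pb = [ot.texture_profile(ot.extract_roi_pixels(v, spec)) for v in vols_b]
for row in ot.compare_groups(pa, pb):
    print(f"{row.parameter:10s} {row.group_a_mean:9.4f} -> {row.group_b_mean:9.4f}"
          f"   {row.percent_change:+7.2f} %   p = {row.p_value:.2e}")
```

prints

```
mean         98.1555 ->  104.9852     +6.96 %   p = 5.15e-25
sigma        17.6647 ->   12.6080    -28.63 %   p = 2.82e-16
skewness     -0.8542 ->   -0.7269    -14.90 %   p = 2.07e-10
kurtosis      0.5028 ->    0.5739    +14.13 %   p = 1.41e-04
energy        0.0176 ->    0.0238    +34.82 %   p = 3.17e-24
entropy       4.1956 ->    3.9027     -6.98 %   p = 2.46e-24
nakagami      9.4944 ->   19.3472   +103.78 %   p = 1.13e-25
```

The treated arm's tighter, brighter intensity distribution shows up as a
higher mean and energy, lower sigma and entropy, skewness closer to zero,
and a doubled Nakagami parameter.

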
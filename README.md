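# octametrics

Quantitative analysis of en face OCT angiography (OCTA) images, for
researchers comparing acquisition protocols or reproducing ImageJ-style
vascular quantification in scripted, testable form.

OCTA maps retinal and choroidal blood flow without dye. From an exported
en face image of a vascular slab — superficial capillary plexus (SCP), deep
capillary plexus (DCP) or choriocapillaris (CC) — the package computes the
standard metrics:

* **Perfusion density** PD = 100·|vessel mask|/|frame| (%),
* **Vessel length density** VLD = 100·|skeleton|/|frame| (%), from
  topology-preserving thinning of the mask,
* **Vessel diameter index** VDI = |mask|/|skeleton| (mean caliber, px),
* **CC flow deficits**: count and total signal-void area (%) of the
  choriocapillaris.

SCP/DCP binarization is the dual-path chain: white top-hat, then (A) Frangi
Hessian vesselness followed by a Huang fuzzy-entropy global threshold and
(B) a median local threshold, combined by pixelwise AND. CC binarization
uses the Phansalkar local threshold (radius 15 px) with 8-connected
particle analysis of the signal voids.

For paired single-volume (V1) vs four-volume-average (V4) acquisitions of
the same eyes, the agreement module reports a normality-gated paired test
(Shapiro–Wilk → paired t or Wilcoxon), Lin's concordance correlation
ρc = ρ·C_b with 95% CI and categorical reading, and Bland–Altman bias with
95% limits of agreement — the difference always oriented V1 − V4.

Because no public dataset accompanies this protocol, the package also ships
a seeded synthetic-angiogram generator (vessel-network and CC-texture
phantoms with exact ground-truth masks, speckle-like frame noise, V1/V4
averaging) used by the test suite for parameter-recovery and
direction-of-effect checks. See `docs/methods.md` for the science and the
design choices.

## Worked example

```python
import octametrics as om

# a seeded SCP phantom with known ground truth, imaged as V1 and V4
truth = om.generate_plexus_phantom(om.PhantomSpec.scp(seed=3))
v1 = om.simulate_acquisition(truth, om.NoiseModel.speckle(sigma=0.35, n_volumes=1, seed=1))
v4 = om.simulate_acquisition(truth, om.NoiseModel.speckle(sigma=0.35, n_volumes=4, seed=2))

for img in (v1, v4):
    m = om.compute_vascular_metrics(img)
    print(f"{img.acquisition_mode.value}: PD {m.pd_percent:.2f}%  "
          f"VLD {m.vld_percent:.2f}%  VDI {m.vdi_pixels:.2f} px")
print(f"truth: PD {truth.true_pd:.2f}%  VLD {truth.true_vld:.2f}%  "
      f"VDI {truth.true_vdi:.2f} px")
```

prints

```
V1: PD 31.87%  VLD 11.69%  VDI 2.73 px
V4: PD 33.35%  VLD 10.51%  VDI 3.17 px
truth: PD 30.13%  VLD 9.81%  VDI 3.07 px
```

Relative to the averaged acquisition, the single-volume image reads lower
in perfusion density (speckle breaks vessels), higher in vessel length
density (ragged fragments spawn skeleton spurs) and hence lower in the
diameter index — the same directions of change reported for real eyes, and
the V4 values sit closer to the phantom's truth for VLD and VDI.

The command line runs the whole workflow on a simulated cohort:

```bash
octametrics simulate --config config.json --out run/
octametrics quantify --config config.json --input-dir run/ --out run/
octametrics report --metrics run/metrics.csv --out run/
```

where `config.json` contains e.g.
`{"simulate": {"n_eyes": 28, "seed": 7}}`. `report` prints a per-metric
table (arm means ± SD, Δ(V1−V4), p, CCC with CI and category, Bland–Altman
bias and limits) and writes it as CSV/JSON plus the per-eye Bland–Altman
plot data.

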
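# paquant

**Quantitative 3D photoacoustic/ultrasound oxygen-saturation analysis for
breast-tumour characterization.**

Dual-wavelength photoacoustic (PA) imaging measures blood oxygen saturation
(SO₂) non-invasively: deoxy-haemoglobin absorbs more strongly at 750 nm,
oxy-haemoglobin at 830 nm, so two co-registered PA volumes determine the
oxygenated fraction of haemoglobin voxel by voxel. Malignant breast tumours
tend to be hypoxic — their intra- and peri-tumoral SO₂ runs several
percentage points below that of benign lesions — which makes volumetric SO₂
a candidate biomarker for differentiating small (T1-stage) invasive cancers
from benign tumours.

`paquant` implements the full quantification chain for swept-probe 3D PA/US
acquisitions, plus a synthetic phantom generator so every stage is
verifiable against known ground truth:

1. **Unmixing** (`paquant.unmixing`) — laser-energy normalization and the
   two-wavelength estimator. With the PA amplitude modelled as
   `PA(λ, r) = Γ F(λ, r) (C_HbO₂ ε_HbO₂(λ) + C_Hb ε_Hb(λ))` and fluence
   F approximately equal at the two wavelengths,

   ```
   SO₂ = [PA₁ ε_Hb(λ₂) − PA₂ ε_Hb(λ₁)] /
         [PA₁ (ε_Hb(λ₂) − ε_HbO₂(λ₂)) + PA₂ (ε_HbO₂(λ₁) − ε_Hb(λ₁))]
   ```

   Negative estimates are removed; slightly over-unity ones are clipped;
   voxels without signal are marked invalid (NaN).
2. **3D ROI geometry** (`paquant.roi3d`) — rasterizes physician-drawn
   per-slice tumour contours into a voxel mask, fits the minimum-volume
   enclosing ellipsoid (MVEE, by Khachiyan-type reweighting with away
   steps), scales each semi-axis by 1.2 to obtain the extension ellipsoid,
   and defines the *surrounding* (peri-tumoral) region as extension minus
   tumour. ROIs can be mirrored across the sagittal midline for the
   contralateral (normal) breast.
3. **Biomarkers** (`paquant.quantify`) — volumetric mean SO₂ per region with
   a 40% lower threshold (artefact suppression), and the strict
   40% < SO₂ < 100% vessel mask used for 3D network rendering.
4. **Statistics** (`paquant.stats`) — two-tailed Mann-Whitney U (exact null
   distribution for small tie-free samples), Hodges-Lehmann shift estimate
   with a 95% CI by test inversion, ROC/AUC in the "lower SO₂ ⇒ malignant"
   direction (the trapezoid AUC equals U/(n₁n₂) identically), and exhaustive
   size-matched subgroup enumeration.
5. **Phantoms** (`paquant.phantom`) — ellipsoidal tumours, capsule vessels
   and a peri-tumoral shell with known haemoglobin fields, forward-projected
   at 750/830 nm with depth-decaying fluence, per-frame laser-energy jitter
   and additive noise; cohort simulation at configurable group SO₂
   distributions.
6. **Pipeline & CLI** (`paquant.pipeline`, `paquant` command) — per-case and
   cohort orchestration with deterministic seeding and manifest output.

## Worked example

Simulate a 24-case cohort (8 benign, 16 malignant; benign tumour SO₂
centred at 78.5%, malignant 7.7 points lower) and run the full analysis:

```sh
cat > demo_cfg.json <<'EOF'
{"grid_shape": [40, 48, 56], "voxel_size": [0.5, 0.5, 0.5],
 "size_range_mm": [6.0, 10.0]}
EOF
paquant run --config demo_cfg.json --seed 7 --out demo
```

prints

```
tumour: malignant-benign HL = -6.9 pp (95% CI -9.1, -4.5), P = 0.000, AUC = 0.95
surrounding: malignant-benign HL = -5.6 pp (95% CI -8.7, -2.1), P = 0.000, AUC = 0.92
```

i.e. the pipeline recovers a malignant tumour-region SO₂ deficit of 6.9
percentage points (Hodges-Lehmann estimate, close to the simulated group
difference) with a significant Mann-Whitney comparison, and the
peri-tumoral deficit of ~5 points alongside it. `demo/` then contains
`cohort.csv` (per-case regional means), `comparisons.csv`, per-region ROC
tables, the ground-truth table and a reproducibility manifest; rerunning
with the same seed reproduces every file byte for byte.

The same run is available from Python:

```python
from paquant.pipeline import RunConfig, run_cohort
result = run_cohort(RunConfig(grid_shape=(40, 48, 56), voxel_size=(0.5,) * 3,
                              size_range_mm=(6.0, 10.0), seed=7))
print(result.cohort.groupby("group")["tumour_mean_so2"].mean())
```

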
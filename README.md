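# autoaif

Automated image-derived arterial input functions for dynamic ¹⁸F-FDG brain
PET, with the kinetic models that consume them.

Quantitative FDG PET needs the arterial input function (AIF) — the tracer
concentration in arterial blood over time — as the driving term of
compartment models. Arterial cannulation is invasive, and manually
delineated carotid regions suffer severe partial-volume bias. `autoaif`
extracts an input function directly from the dynamic brain image, with no
blood sampling, no anatomical atlas and no manual region drawing:

1. brain voxels are masked and arranged into a voxel × frame matrix
   `F̂(M, n)`;
2. each time–activity curve is scanned with a continuous wavelet transform
   (Morlet, scales 1–100) to find its peak; the curve tail is the mean of
   the last two frames (55–65 min);
3. curves survive iff `peak > (1 − a1)·Mean_peak` and
   `tail < ((1 − a2)·Mean_tail) + Mean_tail`, where `Mean_peak` /
   `Mean_tail` average the ten largest peaks and ten smallest tails;
4. survivors are split by Ward hierarchical clustering into an arterial
   (early-peak) and a venous (late-peak) family, averaged across threshold
   levels a1 ∈ {0.4, 0.5, 0.6};
5. the automatic input function `IDIF_auto` splices the arterial peak onto
   the peak-aligned venous tail on a 2 s grid — arteries give correct bolus
   timing, the much thicker veins give an unbiased tail.

The library also provides the irreversible two-tissue compartment model

    C_T(t) = (1 − v_b)·[(K₁k₂/(k₂+k₃))·e^{−(k₂+k₃)t} + K₁k₃/(k₂+k₃)] ⊗ C_p(t) + v_b·C_b(t)

with bounded least-squares fitting (init 0.01, box [0, 1]), the net influx
rate Ki = K₁k₃/(k₂+k₃), Patlak graphical analysis on the 40–65 min window,
parametric maps, evaluation metrics (AUC error, NRMSE, peak delays,
quadrature FWHM combination, resolution-degradation studies), and a
synthetic dynamic FDG head phantom with ground truth for end-to-end
validation (see `docs/methods.md`).

Intended users: PET methodologists and quantitative-imaging researchers who
want non-invasive input functions on standard field-of-view scanners, and
anyone needing a controlled phantom to study partial-volume effects on
blood-pool signals.

## Worked example

```python
import autoaif as aa

# simulate a dynamic FDG head acquisition with known ground truth
image, truth = aa.build_phantom(aa.PhantomSpec(seed=0))

# run the extraction pipeline
mask = aa.brain_mask(image)                      # threshold-1 + 20 cm crop
tacs = aa.extract_tac_matrix(image, mask)        # voxel x frame matrix
ext = aa.IDIFExtractor().fit(tacs, schedule=image.schedule)

print(f"cohort: {tacs.n_voxels} voxels")
print(f"artery/vein voxels (mean over levels): "
      f"{ext.count_artery_:.0f}/{ext.count_vein_:.0f}")
print(f"AUC error of IDIF_auto vs true AIF: "
      f"{aa.auc_error(ext.idif_auto_, truth.true_aif_fine):.2f}%")

# fit kinetics to a deep grey-matter mean curve against the extracted input
from scipy import ndimage
core = ndimage.binary_erosion(truth.gm_mask.to_bool(image.shape), iterations=2)
tac = image.values[core].mean(axis=0)
res = aa.fit_2tcm(tac, ext.idif_auto_, image.schedule)
print(f"K1={res.params.K1:.3f} k2={res.params.k2:.3f} "
      f"k3={res.params.k3:.3f} Ki={res.params.Ki:.4f} ml/cm3/min")
```

Output (seed 0):

```
cohort: 6354 voxels
artery/vein voxels (mean over levels): 84/127
AUC error of IDIF_auto vs true AIF: -2.56%
K1=0.204 k2=0.167 k3=0.053 Ki=0.0488 ml/cm3/min
```

The extracted input function underestimates the true AIF area by ~2.6% at
the default 3.83 mm effective resolution — arteries alone would err by
about −20% (partial volume), veins alone by about −2%; the hybrid keeps the
arterial timing with the venous accuracy. The grey-matter fit illustrates
the framework's central robustness property: the micro-parameters shift
with the residual input-shape error (generating values were K₁ 0.173,
k₂ 0.137, k₃ 0.053), but the net influx rate lands within 2% of the
expected 0.048 mL/cm³/min.

A command-line interface mirrors the library
(`autoaif simulate | extract-tacs | peaks | cluster | idif | da-idif |
fit | evaluate | resolution-study`); run `autoaif --help`.

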
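# capnonet

COPD detection and severity grading from volumetric capnography.

Volumetric capnography plots exhaled CO2 concentration against cumulative
exhaled volume over a single breath.  Its three phases — dead-space
baseline, ascending branch, alveolar plateau — deform characteristically
under airflow obstruction: the plateau (phase III) steepens and the
ascending branch (phase II) flattens.  This package turns each breath into
an image and classifies it with a compact CNN:

1. **Preprocess**: resample CO2/flow to 200 Hz, zero-phase third-order
   Butterworth low-pass, segment exhalations from the flow signal,
   integrate flow to volume, and reduce each CO2-vs-volume curve to 224
   samples by piecewise aggregate approximation (PAA).
2. **Encode**: min-max normalize to [−1, 1], map to polar angles
   φᵢ = arccos x̃ᵢ, and form the Gramian angular fields
   GASF = [cos(φᵢ+φⱼ)] and GADF = [sin(φᵢ−φⱼ)], quantized to 224×224
   8-bit grayscale images.
3. **Augment** (training folds only): expand 3× with Gaussian pixel noise
   (mean 0, variance 15) and elastic deformation (alpha 200, sigma 20,
   alpha_affine 10).
4. **Classify**: CapnoNet — a 3×3 stem (32 channels) and two inception
   blocks with parallel 1×1/3×3/5×5/7×7 branches (26 and 108 channels per
   branch), BN after every convolution, 2×2/s2 max pooling, global average
   pooling, dropout 0.4, and a softmax head.  1.02 M parameters, 0.23
   GFLOPs per forward pass.
5. **Evaluate**: ten-fold cross-validation stratified at the subject
   level, majority vote over a subject's breaths, accuracy / precision /
   recall / F1 from pooled confusion matrices.

Clinical capnography datasets are not redistributable, so the package
ships a synthetic generator (`capnonet.synthetic`) producing three-phase
capnograms with GOLD-graded severity, on which the entire pipeline is
exercised and tested.  The CNN and its training loop (backprop, Adam) are
implemented directly on numpy — no deep-learning framework required.

## Worked example

```python
from capnonet import synthetic, preprocess, gaf, train_eval

# a synthetic cohort: 20 normal + 20 GOLD-3 subjects, one breath each
cfg = synthetic.CohortConfig(n_per_class=20, class_set=("normal", "GOLD3"),
                             breaths_per_subject=1, seed=7)
manifest, records = synthetic.simulate_cohort(cfg)

# one breath through the pipeline
series = preprocess.preprocess_record(records["S0000_b0.csv"])[0]
image = gaf.encode_image(series, kind="gasf")
print(len(series), image.shape)          # 224 (224, 224)

# ten-fold stratified subject-level cross-validation (reduced epochs)
cv = train_eval.CVConfig(task="detect", encoding="gasf", k=10, epochs=3, seed=7)
result = train_eval.run_cv(manifest, records, cv)
print(result.pooled.accuracy)            # 1.0
print(result.pooled.confusion)           # [[20  0]
                                         #  [ 0 20]]
```

On this clearly separated synthetic cohort the pooled subject-level
accuracy is 1.0: every normal and every GOLD-3 subject is classified
correctly from a single GASF-encoded breath.  Real clinical performance is
a property of clinical data and is not claimed here.

The same stages are available from the shell:

```sh
capnonet simulate --n-per-class 5 --seed 7 --out cohort/
capnonet encode cohort/S0000_b0.csv --kind gasf --out images/
capnonet evaluate --data cohort/ --epochs 3 --out results/
capnonet complexity
# params_M=1.02 gflops=0.23
# params=1015666 flops=230949312
```

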
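# rgdfusion

Radiomics + graph-fused deep features for benign/malignant lung-nodule
classification on CT.

Early lung-cancer screening hinges on deciding whether a small pulmonary
nodule seen on CT is benign or malignant.  `rgdfusion` implements the RGD
fusion classifier for this task: per nodule it combines

* **FR** — a 3D texture radiomics vector: a volume local-binary-pattern
  histogram (16384 bins for L=1, P=4, R=1), a 3D histogram of oriented
  gradients (azimuth × elevation, 1024 dims), and energy / entropy /
  contrast / homogeneity of 3D grey-level co-occurrence matrices over the
  13 unique 26-neighbourhood directions (208 features);
* **F_i** — feature vectors from five convolutional backbones (AlexNet,
  VGG13, ResNet34, Attention56, GoogLeNet motifs), trained with the focal
  loss L = −α(1−y′)^γ log y′ (y=1), −(1−α)y′^γ log(1−y′) (y=0);
* **FG** — a fused vector from a two-layer GCN,
  H^(l+1) = σ(D̃^(−1/2) Ã D̃^(−1/2) H^(l) W^(l)), Ã = A + I, run on the
  5-node *model-divergence* graph A_ij = 1 − similarity(Net_i, Net_j),
  where similarity is the training-set agreement fraction of the two
  models' hard predictions.

Each backbone gets a fusion head over [F_i | FR | FG]; the five head
probabilities are combined with accuracy-proportional weights
W_i = Acc_i / Σ_j Acc_j into P = Σ W_i P_i.  Evaluation reports accuracy,
sensitivity, specificity, precision, F1 and the pairwise-ranking AUC under
patient-disjoint k-fold cross-validation.

A synthetic phantom generator (smooth ellipsoids vs. spiculated,
texture-heterogeneous blobs in 56×56×8 crops) makes the whole pipeline
trainable and testable at desk scale without a CT archive.  The neural
parts run on a small numpy autodiff engine bundled with the package — no
GPU or deep-learning framework required.

## Worked example

```python
from rgdfusion.pipeline import RunConfig, run_cv

cfg = RunConfig.phantom_default(n_per_class=30, k_folds=3, seed=1)
result = run_cv(cfg)
for name, (mean, sd) in result.aggregate.items():
    print(f"{name:>12}: {mean:.3f} +/- {sd:.3f}")
print(f"best single backbone: {result.best_single_backbone_accuracy():.3f}")
```

prints (one CPU, ~40 s):

```
    accuracy: 0.983 +/- 0.024
 sensitivity: 1.000 +/- 0.000
 specificity: 0.970 +/- 0.043
   precision: 0.967 +/- 0.047
          f1: 0.982 +/- 0.025
         auc: 1.000 +/- 0.000
best single backbone: 0.883
```

The fused ensemble (0.983) clearly beats the best single tiny backbone
(0.883): the heads see the radiomics and GCN-fused blocks on top of each
backbone's own features, so a weakly trained backbone still contributes a
strong fused prediction.

The same pipeline is scriptable from the shell:

```bash
rgd phantom generate cohort/ --n-per-class 50 --seed 0
rgd features radiomics cohort/manifest.csv features.csv
rgd run --seed 0 --k 5 --outdir out/
rgd ablate cnn_1 cnn_1+g rgd --seed 0
```

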
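# mviradiomics

Peritumoral CT radiomics benchmarking and multi-disciplinary-team (MDT)-like
classifier fusion for predicting **microvascular invasion (MVI)** in
hepatocellular carcinoma.

MVI — tumor cells inside small vessels at histopathology — is a strong
predictor of recurrence after resection but is only known post-operatively.
This package implements a non-invasive analysis of quadriphasic dynamic
contrast-enhanced CT (early/late arterial, portal venous, equilibrium:
EAP/LAP/PVP/EP) that asks three questions at once: *which phase(s)*, *how far
beyond the tumor margin*, and *which model* best predict MVI — and then fuses
the best models the way an MDT fuses specialist opinions.

The pipeline:

1. **Regions** — from a tumor-core mask `V_tc`, build peritumoral shells
   `V_pt(d)` for d ∈ {2,…,14} mm by physical-distance expansion that stops at
   large vessels (caliber ≥ 2 mm), bile ducts and the liver boundary, plus the
   combined regions `V_tc+V_pt(d)`; paired delineations are merged only above
   Dice 0.9.
2. **Features** — a native 94-feature radiomics catalogue per (phase, region):
   19 first-order + 24 GLCM + 16 GLSZM + 16 GLRLM + 5 NGTDM + 14 GLDM, with
   fixed-bin-width discretization; phase concatenation gives the 15 feature
   groups (94/188/282/376 columns).
3. **Benchmark** — 15 phase combos × 15 regions × 15 feature selectors × 10
   classifiers = 33,750 configurations, each scored by stratified ten-fold
   cross-validation with in-fold feature selection; ranked by validation AUC.
4. **Fusion** — the top-3 models are fused by plurality voting (PV) and by
   weighted fusion (WF), `H(x) = Σ wᵢ cᵢ(x)` with weights proportional to
   validation accuracy; models are compared by the net reclassification
   improvement (NRI) on an independent chronological test split.

Because no patient data ship with the package, a first-class synthetic-phantom
module generates liver cohorts whose MVI-positives carry elevated peritumoral
intensity and zone-size heterogeneity on the PVP analog — so every stage is
testable and the whole analysis validates against *known injected truth*.

## Worked example

```python
from mviradiomics import MDTFusion
from mviradiomics.studies import reduced_study_spec
from mviradiomics.synthetic import generate_cohort

# 32 synthetic patients; MVI-positives carry a +6 HU peritumoral shift and
# extra zone-size heterogeneity on the PVP analog within 12 mm of the margin
spec = reduced_study_spec(n_patients=32, seed=7)
cases, table = generate_cohort(spec)

model = MDTFusion.from_cohort(cases, distances_mm=(4.0, 8.0, 12.0),
                              region_ids=["core", "combined:4",
                                          "combined:8", "combined:12"])
res = model.fit(selectors=("t_score", "f_score", "trace_ratio"),
                classifiers=("logistic",), n_train=26, seed=0)
print(res.summary())
```

Output of this exact script:

```
MDT-like radiomics fusion results
================================================================
cohort: 26 train / 6 test (chronological split), seed=0
benchmarked configurations: 180
best phase combination: Fpha3 (pooled_auc, region class combined)
best peritumoral distance: 12 mm

top models (CV on training/validation set):
  1. Fpha3|combined:12|trace_ratio|logistic  AUC=0.900 ACC=0.900
  2. Fpha3|combined:12|f_score|logistic  AUC=0.850 ACC=0.783
  3. Fpha3|combined:12|t_score|logistic  AUC=0.850 ACC=0.783

independent test set:
  Fpha3|combined:12|trace_ratio|logistic: AUC=1.000 ACC=1.000 SEN=1.000 SPE=1.000
  Fpha3|combined:12|f_score|logistic: AUC=1.000 ACC=0.833 SEN=0.750 SPE=1.000
  Fpha3|combined:12|t_score|logistic: AUC=1.000 ACC=0.833 SEN=0.750 SPE=1.000
  PV: AUC=0.875 ACC=0.833 SEN=0.750 SPE=1.000
  WF: AUC=1.000 ACC=0.833 SEN=0.750 SPE=1.000

phase-group Kruskal-Wallis omnibus p = 0.0128
```

Reading it: the benchmark recovered the injected structure — the portal
venous phase (`Fpha3`) and the tumor+12 mm combined region win, and that is
exactly (and only) where the generator placed the class effect.  The fused
models sit at or above the typical single member on the 6-case test split;
single-replicate numbers at this size are noisy, and the replicate studies
below quantify the behavior properly.

The same analysis runs from the shell:

```bash
mviradiomics synth --out cohort/ --seed 7          # NIfTI volumes + cohort.csv
mviradiomics voi --case cohort/case0000 --out voi/ # region masks
mviradiomics features --image cohort/case0000/PVP.nii.gz \
    --mask voi/combined_12.nii.gz --out feats.csv
mviradiomics run --out results/ --seed 7           # full reduced study
```

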
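# kmcdce — k-means-clustered kinetics of ultrafast breast DCE-MRI

`kmcdce` analyzes bilateral breast DCE-MRI acquired at ultrafast temporal
resolution (3-9 s per frame over the first minute after contrast
injection) to predict pathologic complete response (pCR) to neoadjuvant
chemotherapy *before* treatment starts. It is written for quantitative
imaging researchers who want a tested, reproducible implementation of the
cluster-based bilateral-asymmetry analysis, driven by a synthetic phantom
and cohort simulator in place of clinical data.

The core idea: tumors alter the perfusion of the *normal-appearing*
parenchyma around them, so asymmetry between the tumor-bearing
(ipsilateral) and healthy (contralateral) breast in background
parenchymal enhancement kinetics (kBPE) carries predictive signal that
tumor kinetics alone do not.

## Method in brief

1. **Enhancement.** Per voxel, percent signal enhancement
   PSE(t) = 100·(S(t) − S̄pre)/S̄pre is fit with the empirical uptake model
   PSE(t) = A·αt²/(1+αt²); A·α is the maximum enhancement-rate proxy.
2. **Clustering.** Tumor, ipsilateral and contralateral parenchyma are each
   partitioned into K = 5 clusters by 1D k-means on A·α, relabeled
   ascending by cluster mean (deterministic quantile initialization).
3. **Cluster kinetics.** Cluster-mean signal curves are fit with the
   three-parameter model A·αt²/(1+αt²)·e^(−βt) plus AUC30 (integral over
   the first 0.5 min), converted to concentration by SPGR inversion, and
   fit with the extended Tofts model (Ktrans, ve, vp; Kep = Ktrans/ve)
   driven by a population arterial input function.
4. **Biomarkers.** Parenchymal parameters are collapsed per breast as
   (2c₂+3c₃+4c₄)/9 and expressed as the I/C ratio; tumor parameters as
   (3c₃+4c₄+5c₅)/12.
5. **Prediction.** Wilcoxon/chi-square group comparisons; exhaustive
   ≤3-feature logistic model search over seven feature-pool families;
   apparent ROC AUC with 1000-resample bootstrap CIs, paired bootstrap
   z-tests, and Youden operating points.

Details, defaults and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

Run the per-patient pipeline on the bundled synthetic phantom, which
imposes a ground-truth parenchymal A·α asymmetry of I/C = 1.4 and 2%
Rician noise:

```bash
python analysis/02_patient_kinetics.py --seed 0
```

prints (abridged):

```
bilateral asymmetry (I/C) of the weighted parenchymal averages:
  A        I/C = 0.9727
  alpha    I/C = 1.4194
  A_alpha  I/C = 1.3804
  AUC30    I/C = 1.2609
  Ktrans   I/C = 1.0959
  ve       I/C = 1.0000
  Kep      I/C = 1.0959

imposed A*alpha I/C = 1.4, recovered = 1.380 (1.4% off)
tumor volume: 3.40 cm^3
```

The amplitude ratio stays near 1 while the rate ratios (alpha, A·α) carry
the imposed asymmetry — the phantom scales the ipsilateral uptake *rate*,
and the pipeline recovers that ratio to within a few percent under noise.

Cohort-level analysis on a simulated 56-patient cohort (30 non-pCR /
26 pCR) whose features follow the published group distributions:

```bash
python analysis/03_cohort_comparisons.py --seed 0   # group tables
python analysis/04_response_models.py --seed 0      # model search
```

The model search prints, per family, the selected features, apparent AUC
with bootstrap CI, and the Youden operating point, e.g.

```
(  i)  age+postmenopausal+grade3        0.69 [0.60, 0.83]  0.96  0.43  0.68
( ii)  kT_alpha+kT_AUC30+kT_Ktrans      0.78 [0.66, 0.91]  0.69  0.80  0.75
(iii)  kBPE_A_alpha_IC+kBPE_Kep_IC+...  1.00 [1.00, 1.00]  1.00  1.00  1.00
```

Models with kBPE I/C features dominate the clinical-only and
tumor-kinetics-only families, mirroring the qualitative ordering of the
clinical finding (the simulator draws features independently within group,
so multi-feature apparent AUCs run higher than reality — see the methods
note).

The same steps are available as a CLI (`kmcdce phantom`, `kmcdce
run-patient`, `kmcdce cohort-stats`, `kmcdce predict`, `kmcdce run-all`)
for NIfTI series + label-map inputs with a JSON frame-timing sidecar.

## Layout

    src/kmcdce/       library: io_core, phantom, kinetics, clustering,
                      pharmacokinetics, summary, stats, pipeline, cli
    analysis/         numbered narrative drivers (phantom -> patient ->
                      cohort -> models), outputs under results/
    tests/            pytest suite incl. end-to-end property tests
    docs/methods.md   models, assumptions, defaults, limitations
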
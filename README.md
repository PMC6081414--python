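# icnvar

Inter-network phase-variability features and linear-SVM diagnostic
modelling for resting-state fMRI.

## The problem

Static functional connectivity (the Pearson correlation between two brain
networks' time-courses) ignores how the coupling between networks
fluctuates over a scan. `icnvar` implements a dynamic-connectivity
analysis built on a simple temporal-variability statistic: for each pair
of intrinsic connectivity networks (ICNs), take the instantaneous phase
of each network's time-course from its analytic signal, wrap the phase
difference to (−π, π], and measure its variance over time,

```
VAR_ij = Var_t[ wrap(φ_i(t) − φ_j(t)) ],    φ = angle(x + i·H[x])
```

where `H` is the Hilbert transform. A pair of networks that stays
phase-locked has `VAR ≈ 0`; a pair whose phase relation wanders freely
approaches the uniform-circle limit `π²/3 ≈ 3.29`. With 10 template ICNs
this yields `10·9/2 = 45` pairwise features per subject. The diagnostic
model is a linear SVM over

```
label = Σ_i w_1i · VAR_i + Σ_i w_2i · IQ_i + w_3·sex + w_4·age + w_5·mFD + b
```

(label 1 = patient, 0 = control; mFD = mean framewise displacement),
evaluated by leave-one-out CV and by repeated stratified 10-fold CV, with
signed discriminative weights and top-10 weight-frequency reports. The
intended users are neuroimaging researchers who want a tested, fully
reproducible reference implementation of this feature family — including
a synthetic two-group cohort generator, so every stage runs and is
verifiable without any imaging download.

## What is in the package

| module | role |
| --- | --- |
| `icnvar.synthetic` | two-group cohort generator: phase-coupled network time-courses with plantable pair-level group effects, blob template maps, 4D volume mixing, Table-style phenotypes, motion traces |
| `icnvar.preprocess` | zero-phase 0.01–0.1 Hz Butterworth band-pass, framewise displacement, motion-based exclusion |
| `icnvar.timecourses` | network time-course extraction by spatial regression of template maps (per-map or joint per frame) |
| `icnvar.features` | instantaneous phase, phase wrapping, VAR / FC / PS pairwise metrics, predictor assembly |
| `icnvar.classify` | linear SVM (z-scored features), LOOCV, repeated stratified k-fold, ROC/AUC, weight reports |

A thin CLI (`icnvar simulate / preprocess / extract / features /
classify`) chains the stages through plain CSV/TSV/NIfTI files.

## Worked example

```python
import numpy as np
from icnvar import (SimulationConfig, simulate_cohort, cohort_feature_matrix,
                    loocv, repeated_kfold, top_k_frequency)

cfg = SimulationConfig(n_patients=60, n_controls=60, seed=1)   # 3 planted pairs
X, y, names = cohort_feature_matrix(simulate_cohort(cfg))
print(X.shape)                        # (120, 51): 45 VAR + viq,piq,fiq,sex,age,mean_fd

perf, _ = loocv(X, y)
print(f"LOOCV accuracy {perf.accuracy:.3f}, AUC {perf.auc:.3f}")
# LOOCV accuracy 0.975, AUC 0.999

perfs, W = repeated_kfold(X, y, k=10, repeats=50, seed=1)
acc = np.mean([p.accuracy for p in perfs])
print(f"10-fold accuracy {acc:.3f}")  # 10-fold accuracy 0.970

tab = top_k_frequency(W[:, :45], k=10, feature_names=names[:45]).to_frame()
print(tab[tab.feature.isin(["VAR_AN-RFPN", "VAR_CBN-SMN", "VAR_DMN-LFPN"])])
#      feature  top_k_count  mean_weight
# VAR_DMN-LFPN           50     0.257325
#  VAR_CBN-SMN           50     0.209462
#  VAR_AN-RFPN           50     0.233614
```

The planted pairs (AN-RFPN, CBN-SMN, DMN-LFPN — patients' pair phase
dispersion 0.3 rad vs 0.05 rad in controls) appear in the top-10
discriminative ranking in all 50 repeats, with positive weights (phase
variability elevated in patients), while a null cohort (identical group
generators) classifies at chance.

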
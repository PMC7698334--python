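# mrsidh — IDH-status prediction from single-voxel ¹H-MRS

Gliomas carrying an *IDH* (isocitrate dehydrogenase) mutation have a much
better prognosis than *IDH* wild-type tumors, but the genotype is normally
determined invasively, from resected tissue. In principle the mutation is
visible non-invasively: mutant IDH produces the oncometabolite
D-2-hydroxyglutarate (2-HG), whose protons resonate near 1.91 and 2.24 ppm.
In routine short-TE spectra at 3 T, however, those multiplets are buried
under glutamate, glutamine and GABA, so a 2-HG peak cannot be read off
directly. The alternative implemented here: classify the **whole spectrum**
with a linear support-vector machine, validated so that no information from
a test subject ever touches training.

`mrsidh` is a complete, reproducible implementation of that analysis for
researchers in MRS-based neuro-oncology and for anyone who needs a
carefully leakage-free nested cross-validation reference:

* a **synthetic cohort generator** (no patient data are required): sums of
  area-normalized Lorentzian resonances for Cho, Cr, NAA, Lac, Glu, Gln,
  M-ins, Gly, 2-HG, GABA and lipids, with class-dependent concentrations
  (M-ins ×1.5, Gly ×0.6, Glu ×0.8 in mutants; 2-HG only in mutants),
  frequency jitter, phase error, baseline and noise; plus a narrow-linewidth
  "ex vivo" mode in which the overlapped resonances resolve;
* the **preprocessing chain**: zero-order phase correction, chemical-shift
  referencing to choline at 3.20 ppm, equidistant binning of 4 points,
  restriction to 4.5–0.7 ppm (~100 bins), normalization to total intensity
  1, log₂ transform;
* the **classifier**: nested leave-one-out cross-validation with an inner
  leave-one-out loop that ranks features by the Welch two-sample *t*
  statistic and picks the number of kept features k ∈ {1, …, k_max};
  linear SVM (libsvm) with cost C = 1 on training-fold-standardized
  features;
* **reporting**: confusion metrics, exact Clopper–Pearson 95% binomial
  confidence intervals, ROC AUC (Mann–Whitney with ties counted ½),
  class-averaged spectra and metabolite annotation of the selected bins.

## The statistics in brief

For a held-out sample x the SVM decides by sign(w·z + b), z the
training-standardized selected bins. The outer loop leaves each of the n
subjects out once; the inner loop, run entirely on the remaining n−1,
evaluates every k by a second leave-one-out, re-ranking features within each
inner fold. Sensitivity/specificity CIs are the exact binomial
(Clopper–Pearson) intervals, lower bound the solution of
P(X ≥ x | n, p) = α/2 (beta-quantile form); AUC is the probability that a
random mutant scores above a random wild type, ties ½.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
22-mutant + 12-wild-type cohort:

```bash
python analysis/01_simulate_cohort.py   --seed 1
python analysis/02_preprocess_features.py --seed 1
python analysis/03_classify_nested_svm.py --seed 1
python analysis/04_performance_report.py  --seed 1
```

The final step prints (seed 1):

```
samples: 34 (22 IDHmut, 12 IDHwt)
confusion: tp=20 fn=2 tn=11 fp=1
accuracy:    91.2%
sensitivity: 90.9% (95% CI, 70.8-98.9%)
specificity: 91.7% (95% CI, 61.5-99.8%)
AUC: 0.958
mean number of selected features: 8.71
most frequently selected bins:
  [3.635, 3.597] ppm  freq=1.00  (M-ins)
  [2.266, 2.228] ppm  freq=1.00  (2-HG, GABA)
  [4.091, 4.053] ppm  freq=0.97  (Lac, M-ins)
  [4.053, 4.015] ppm  freq=0.97  (2-HG, M-ins)
  [3.521, 3.483] ppm  freq=0.97  (Gly, M-ins)
```

Reading it: two mutants were missed and one wild type was called mutant;
sensitivity refers to mutation detection (the mutant class is positive).
The bins the classifier relies on sit in the myo-inositol/glycine region
around 3.5–3.65 ppm and in the overlapped 2-HG/Glu/Gln region — the
metabolite signature of the mutation, recovered without ever fitting a
2-HG peak.

The same pipeline is scriptable through the CLI
(`mrsidh simulate|preprocess|run|predict`, see `mrsidh --help`), with a
YAML config whose hash is stamped into every artifact so outputs of
different configurations cannot be mixed. `mrsidh predict` trains once on
a labeled feature matrix and classifies new spectrum files.

## Layout

```
src/mrsidh/        library (spectra_io, synthetic, preprocess, nested_svm,
                   evaluate, pipeline, cli)
analysis/          numbered drivers for the study analysis
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    model, parameters, numerical choices, limitations
```
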
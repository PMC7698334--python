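# Methods

## Problem and data model

The pipeline classifies single-voxel short-TE ¹H-MR spectra of gliomas into
*IDH*-mutant vs wild type. A spectrum is a real-valued point list on a ppm
axis defined by the acquisition: spectral width 1200 Hz over 1024 real
points with the carrier on the residual water signal. The spectrometer
frequency (123.25 MHz, i.e. 3 T) and the water shift (4.70 ppm) are config
defaults, not constants: only the field strength and "carrier on water" are
fixed by the protocol. Index 0 is the highest chemical shift (NMR display
convention); the axis maps index i to
`carrier + ((n−1)/2 − i) · sw/(n·f)` ppm, so the points straddle the
carrier symmetrically and `index_of(ppm(i)) == i` exactly.

## Synthetic cohorts

No spectra are distributed with the package; the simulator produces labeled
cohorts with the statistical structure the analysis assumes.

Each metabolite is a set of Lorentzian components with proton-share weights
summing to 1, so a concentration draw equals the metabolite's spectral
area. Collapsing J-multiplets to a few weighted singlets is deliberate:
the analysis consumes 0.038-ppm bins, below which J-structure is invisible.
The complex lineshape (absorption + i·dispersion) is rotated by a
zero-order phase-error draw, shifted by one global frequency-jitter draw,
and the real channel receives a low-order polynomial baseline and i.i.d.
Gaussian noise (the imaginary channel gets independent noise). Subject
concentrations are normal draws truncated at 0.

Default in vivo conditions (all configurable):

| parameter | default | why |
|---|---|---|
| linewidth (FWHM) | 6 Hz | typical single-voxel linewidth at 3 T; makes 2-HG overlap Glu/Gln at 2.2–2.4 ppm |
| high-res linewidth | 1 Hz | ex vivo regime; resolves Gly (3.55) from M-ins (3.52/3.61) and 2-HG from Glu/Gln |
| noise sd | 1.5 | ~5% of the tallest metabolite peak, a realistic 100-average SNR |
| frequency jitter sd | 0.005 ppm | sub-point B₀ drift; exercised and removed by choline referencing |
| phase error sd | 5° | residual zero-order phase after manual phasing |
| baseline amplitude | 0.2 | small residual baseline — the chain has no baseline correction, so the generator models data for which that is adequate; a large baseline mainly corrupts the total-intensity normalization through its integral |
| cohort | 22 mutant + 12 wild type | the study-sized cohort |

Class effects (mutant vs wild type): myo-inositol ×1.5, glycine ×0.6,
glutamate ×0.8, and 2-HG present only in mutants. The 2-HG in vivo
amplitude is deliberately modest (0.6 ± 0.3 concentration units vs ~5 for
the M-ins pool): its J-coupled multiplets spread intensity, the genotype
changes global intensity only minimally, and the 1.9–2.3 ppm region stays
dominated by variable Glu/Gln/GABA/NAA neighbors — which is exactly why a
2-HG peak read-out is unreliable at 3 T while the M-ins/Gly region around
3.5–3.65 ppm carries the dominant class difference. Total choline is
elevated (4.5 ± 0.6) so that it is unambiguously the tallest resonance in
the 3.0–3.4 ppm referencing window; during development an earlier draft
basis with near-equal Cho and Cr(3.03) heights produced occasional
referencing onto creatine, which shifts the whole spectrum by 0.17 ppm and
dominates the error budget. Between-subject concentration spreads
(sd 0.3–1.5 units) are the main source of class overlap, so classification
accuracy sits in the imperfect high-80s/low-90s regime rather than at 100%.

`effect_strength` geometrically interpolates the multiplicative effects
(0 = no class difference, 1 = default) for difficulty sweeps.

What the generator does **not** model: J-coupling evolution with TE, B₀
inhomogeneity across the voxel, correlated residual-water noise,
macromolecule humps fitted to real data, Voigt lineshapes. Passing tests
therefore demonstrate the correctness and unbiasedness of the *procedure*
under realistic statistical structure, not clinical performance on real
spectra.

## Preprocessing

1. **Zero-order phase correction**: grid search over [−180°, 180°] in 1°
   steps maximizing the tallest real intensity inside the 3.0–3.4 ppm
   window; ties go to the smallest |φ| so a phased spectrum is a fixed
   point. Real-only input passes through unchanged. First-order phase is
   out of scope.
2. **Choline referencing**: circular integer shift placing the window
   maximum exactly at the point nearest 3.20 ppm. Circular (not
   truncating) because shifts are a few points and the wrap sits far
   outside the retained region; the shift is logged per sample.
3. **Binning**: sums (not means) of 4 consecutive points, high-ppm end
   first; `floor(n/4)` bins, trailing remainder dropped. Sums conserve
   total intensity, which makes "normalize to total intensity 1" well
   defined. 1024 points give 256 bins; the round figure of 250 sometimes
   quoted for this geometry is not reachable by any integer bin size and
   presumably reflects edge trimming — the ~100 bins surviving region
   selection are unaffected either way.
4. **Region selection**: bins whose ppm **midpoint** lies in [0.7, 4.5]
   (boundary bins follow the midpoint rule); drops residual water and
   empty regions, keeping ~100 bins.
5. **Normalization**: negative (noise) intensities are clipped to 0, then
   the vector is scaled to sum 1. Clipping keeps the log defined and
   affects only noise-level bins.
6. **log₂** with a floor of 1e−6 (≈ 2⁻¹⁹·⁹), bounding empty bins away from
   −∞ while leaving real intensities (≥ ~1e−4) untouched.

A stage marker (binned → region_selected → normalized → log2) travels with
every feature vector so stage preconditions are enforced rather than
silently recomputed. The whole chain is scale-invariant per sample and
fully deterministic.

## Classification

Linear soft-margin SVM: minimize `(1/(2C))‖w‖² + Σ hinge`, C = 1 (the
solver default, not tuned). Features are standardized with training-fold
mean and sd (sd 0 → 1), mirroring the default scaling of the common SVM
frontends; the model stores the scaling so prediction applies identical
transforms. The dual is solved by libsvm — the solver behind the R package
e1071 that is standard for this analysis — through scikit-learn's bundled
low-level interface (falling back to `sklearn.svm.SVC` if unavailable);
the orientation of (w, b) is fixed by choosing the sign with the smaller
training hinge loss, which provably recovers the optimizer's orientation.
A decision value of exactly 0 is classified as the positive class
(documented tie rule); the positive class is *IDH*-mutant throughout, so
sensitivity means mutation detection.

Feature filter: Welch's unequal-variance t statistic per bin (the safer
choice for 22 vs 12 groups), ranked by |t| descending; bins with zero
pooled standard error rank last with |t| treated as 0; ties break toward
the lower bin index (stable sort).

Nested leave-one-out CV: for each held-out subject, the inner loop runs a
second leave-one-out over the remaining n−1 to score every k from 1 to
k_max (default 15 — the stepwise search "until optimal" is operationalized
as the global maximum of inner accuracy with smallest-k tie-break; a
first-local-maximum mode exists behind `k_selection` for sensitivity
analysis). Features are re-ranked inside every inner fold (fully nested;
ranking once per outer training set is available behind
`rerank_per_inner_fold=False`), then the outer-training set is re-ranked,
the top-k bins selected, the SVM trained, and the held-out subject
predicted. The held-out sample influences nothing — not ranking, not k,
not standardization, not training — and a dedicated test verifies that
replacing it with arbitrary values leaves the fold's model bit-identical.
The CV contains no randomness: fixed matrix + config → identical result.

## Reporting

* Confusion counts and accuracy/sensitivity/specificity, percentages
  rounded half away from zero to one decimal (the ×100 is done in decimal
  arithmetic so half cases like 95.45 round up).
* Exact Clopper–Pearson 95% CIs via beta quantiles:
  lower = Beta(α/2; x, n−x+1), upper = Beta(1−α/2; x+1, n−x); x=0 → lower
  0, x=n → upper 1 (lower (α/2)^(1/n)). For 9/12 the exact lower bound is
  42.8% at one decimal (a printed value of 42.9 for this count reflects a
  rounding difference in the source of that figure; the package reports
  the exact value). Verified against brute-force bisection of binomial
  tail sums for all n ≤ 40 and against statsmodels' beta interval.
* AUC over the **pooled** outer-fold decision values (the standard
  construction when each fold yields one decision value), Mann–Whitney
  with ties counted ½; equality with exhaustive pair counting is tested.
* Class-averaged spectra are computed on the normalized, **pre-log** scale
  (averaging log intensities would distort the spectral shape), with the
  3.5–4.1 ppm window highlighted in the optional figure.
* Bin annotation: a bin is labeled with every metabolite having a
  resonance within ±0.03 ppm of the bin interval (linewidth-limited
  precision of in vivo shifts); bins matching nothing are "unassigned".

## Problem sizes used by the test and acceptance suites

Cross-validated runs use the study-sized cohort (22+12) throughout: 10
seeded replicates for signal recovery, 50 label permutations of one cohort
for the permutation null, and a 3-level effect-strength sweep (0.25 / 1 / 2)
with 6 replicates per level for the monotone-difficulty trend; the
module-level effect×noise grid runs at a reduced 8+7 cohort size. The
leakage check uses a 10+10 cohort. These sizes give stable means at a few
minutes of total runtime on one CPU.

## Known limitations

* Zero-order phasing only; spectra needing first-order correction must be
  phased upstream.
* Referencing assumes choline is the tallest peak in 3.0–3.4 ppm; spectra
  violating this (e.g. extreme Cr elevation) would be mis-referenced — the
  alignment log should be inspected for outlying shifts.
* The nested CV is O(n² · k_max) SVM fits; fine for n ≲ 100 subjects, not
  intended for large cohorts.
* Native Siemens ".rda" is not parsed; the supported input is the
  plain-text export produced by standard MRS software.
* The simulator's realism limits are listed above; no claim about real
  patient spectra follows from synthetic performance.
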
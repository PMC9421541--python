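# Methods

This note documents the models and procedures implemented in `microspect`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Microstate model

The analysis treats multichannel EEG as a sequence of quasi-stable
topographic states. A topography is the vector of instantaneous
average-referenced voltages across electrodes, considered *up to sign and
positive scale*: the generating dipole configuration is assumed fixed within
a state while its oscillatory activation waxes, wanes, and inverts polarity.
All similarity computations therefore use the absolute spatial correlation
|r| between average-referenced maps, and all prototype updates are
polarity-invariant.

### Segmentation (modified k-means)

Clustering operates on topographies at GFP peaks — moments of maximal
spatial signal-to-noise, where GFP(t) is the per-sample *population*
standard deviation across channels (equivalently the RMS of the
average-referenced sample; the population convention is the standard one in
this literature). At most `max_gfp_peaks` (default 1000) strict local maxima
are used, randomly subsampled under a seed when more exist.

The modified k-means alternates:

- **assignment**: each peak map joins the cluster of maximal |r|;
- **update**: each prototype becomes the dominant eigenvector of the
  outer-product sum Σ xᵢxᵢᵀ of its assigned (unnormalized,
  average-referenced) maps — the direction maximizing summed squared signed
  projections, which is the natural polarity-invariant mean.

The objective is the global explained variance
GEV = Σᵢ GFPᵢ²·rᵢ² / Σᵢ GFPᵢ², where rᵢ is each peak's correlation with its
assigned prototype. Iteration stops when the relative GEV change falls below
1e-6 or after 300 iterations; an empty cluster is re-seeded from the
worst-fit peak. The best of `n_repetitions` (default 100) random restarts by
GEV is returned. Restarts initialize prototypes from k distinct observed
peak maps.

### Map-set alignment, averaging, and k selection

Map sets are compared only after an optimal one-to-one alignment: the
permutation maximizing the mean |r| over matched pairs (Hungarian
assignment), with per-map signs chosen to make matched signed correlations
positive. Averaging across subjects or groups applies this alignment to a
common reference, takes the element-wise mean per label, and
re-average-references and re-normalizes.

The number of maps k is selected from 4…7 by *map reliability*: the mean
over subjects and maps of |r| between each subject map and its matched
group-mean map. Ties resolve to the smaller k (parsimony). With five planted
templates and adequate SNR the selection lands on k = 5; the two group map
sets are then checked for spatial equivalence (every matched |r| ≥ 0.95)
before being averaged into grand-mean maps. Grand-mean maps are labelled
A–E by best match to the canonical template library (two diagonal gradients,
an anterior–posterior gradient, a fronto-central peak, a centro-posterior
peak), constructed analytically on a schematic 2-D 10-20 layout.

Re-ordering is sometimes loosely described in this literature as minimizing
the spatial correlation across maps; we treat it as minimizing
*dissimilarity*, i.e. maximizing matched |r| — the only reading under which
averaging and reliability are meaningful. The signed correlation matrix is
exposed by `align_map_sets` should a different criterion be needed.

## Backfitting and temporal measures

Each sample of the band-filtered, average-referenced signal is labelled with
the grand-mean map of maximal |r|; samples whose best |r| falls below 0.50
(and zero-variance samples) are unassigned. The same broadband grand-mean
maps are backfitted to every band rather than re-clustering per band —
spatial configurations are empirically equivalent across bands, and shared
maps make features comparable across bands. (Per-band re-clustering is a
one-line change: run `fit_grand_maps` on band-filtered recordings.)

**Smoothing.** Temporal continuity is enforced by a windowed label-count
bonus: each sample's score for map m is its correlation plus
`factor/(2·window)` times the number of samples within ±`window` samples
(default ±7, factor 10) currently labelled m, iterated to a fixed point (cap
50 sweeps). `factor = 0` disables smoothing exactly. Unassigned samples are
reclaimed only when their adjusted score crosses the assignment threshold.
The exact arithmetic of the EEGLAB plug-in's smoothing is not published;
this window-count–penalized rule is the classical segmentation-smoothing
approach and is defined so that the factor has a transparent unit (bonus per
fully-supporting window).

**Minimum duration.** Labelled runs shorter than 3 samples are split at
their midpoint, the left half taking the left neighbour's label and the
right half the right neighbour's (boundary runs take their single
neighbour), iterated until no short run remains. The source text equates
7 samples with 56 ms and 3 samples with 24 ms, which is inconsistent at
250 Hz; both quantities are configured in samples here (±7-sample window,
3-sample minimum) and exposed in `BackfitParams`.

**Measures.** From the final run-length encoding: occurrence = runs per
second of total recording time; mean duration = mean run length in ms over
*interior* runs only (runs touching the recording ends or an
epoch-concatenation seam have censored lengths and are excluded from the
duration average, but still count toward occurrence and coverage);
coverage = fraction of samples carrying the label. Coverages plus the
unassigned fraction sum to one, and coverage ≈ occurrence × duration/1000
whenever boundary effects are negligible. Unassigned stretches break runs.

## Group statistics

Each measure × band × map cell (75 cells for 3 measures × 5 bands × 5 maps)
is tested with a two-sided permutation test on the difference of group
means, 10,000 label reshuffles, and the add-one estimator
p = (1 + hits)/(n + 1) so p is never zero. The Monte-Carlo permutations draw
from the *sorted* pooled values, making the estimate invariant to input
ordering. Bonferroni correction multiplies by the family size (the number of
cells actually tested). Cohen's d uses the (n−1)-weighted pooled SD and the
convention **patients (group 2) minus controls (group 1)** — stated in every
result record — so a patient deficit appears as negative d. Per-cell seeds
derive deterministically from the family seed and the cell identity, so the
family is reproducible and order-independent. The clinical correlation
(top-ranked aggregate-model feature vs normalized symptom scores) is a
Pearson r with a two-sided permutation p on |r| (1000 reshuffles).

## Classification

Linear SVMs (L2 penalty, squared hinge, C = 1; C exposed in the API) are
evaluated with 10-times-repeated stratified 10-fold cross-validation.
Within each training fold the features are standardized (means/variances
from the training fold only) and ranked with classical ReliefF
(`n_neighbors = 15` nearest hits and misses by Euclidean distance on
standardized features, differences normalized by feature range); the top-k
subsets for k = 1…15 are then scored on the untouched test fold. This
leakage-safe default was chosen over ranking once on the whole data set
(which is ambiguous in the source description); the optimistic whole-data
mode is available as `selection="whole_data"` for comparison, and
`selection="none"` disables selection (and equals the k = 15 model, a tested
invariant). Metrics — accuracy, sensitivity and specificity with patients
as the positive class, and AUC from decision-function scores — are means
over the 100 fold evaluations. Models sharing a CV design are compared by
fold-paired AUC differences with a two-sided sign-flip permutation test
(10,000 flips), and against label-permuted null models re-fitted end to end.
The reported "top feature" is the modal rank-1 feature across folds.

## Synthetic cohorts

The generator emulates exactly the phenomenology the pipeline measures:

- **State sequence**: semi-Markov with gamma dwell times (shape 2, mean
  80 ms by default, inside the 50–120 ms range; shape 2 avoids the
  memoryless exponential while keeping durations positive), uniform
  transition weights excluding self-transitions.
- **Expression**: the active map's template multiplied by a unit-RMS
  band-limited Gaussian carrier (default: all maps in the alpha band;
  configurable per map), with polarity flipped at random per segment.
- **Noise**: spatially correlated Gaussian sensor noise (squared-exponential
  kernel over the schematic electrode layout, random per-subject length
  scale, small white floor), scaled to a configured signal-to-noise RMS
  ratio (default 5).
- **Heterogeneity**: per-subject, per-map lognormal multipliers (σ = 0.3) on
  dwell means and transition weights. Without this, subjects are
  statistically identical, planted effects yield implausibly large cohort
  effect sizes (|d| ≈ 5) and classifiers saturate; σ = 0.3 produces
  cohort-level |d| of order 1–2, a realistic regime for method evaluation.
- **Group deficit**: group 2 scales map E's mean dwell and its transition
  weight (defaults 0.6), producing shorter and rarer map-E episodes.
- **Band-specific dynamics** (optional): a second, independent state process
  with carriers in another band (`background_band`) and *no* group effect is
  superimposed. Broadband analysis then sees the mixture of processes while
  a narrow-band analysis isolates one — the generative embodiment of
  frequency-specific microstate dynamics, used to study when band-wise
  features outperform broadband ones.

Ground truth stores the (primary) label sequence, and the true temporal
measures are computed through the same run-length code path as backfitting.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: volume-conducted superposition of
simultaneously active sources within a band, non-stationary spectra,
artifacts (blinks, EMG, line noise), electrode drift, and any topographic
difference between groups. Recovery results on this generator validate the
*pipeline*, not the biological claims.

A note on noise-free validation: temporal smoothing and the minimum-duration
rule are noise regularizers that deliberately absorb or split very short
runs. On noise-free data the raw assignment reproduces the true sequence
(and therefore the true measures) exactly, while the full default chain
still agrees with the truth on > 95% of samples but biases mean durations
upward by absorbing true sub-threshold runs. Recovery tests therefore
compare measures under assignment-only backfitting and label agreement under
the full chain.

## Problem sizes and determinism

Generator defaults follow the reference recording design (19 channels,
250 Hz, 180 s, 61 subjects per group). The test suite and
`scripts/acceptance.py` run the same pipeline at reduced sizes chosen to
keep full runs in the minutes range on one CPU: 30–60 s recordings, 4–61
subjects per group depending on the experiment, k-means restarts reduced
from 100 to 5–10, and 300–500 GFP peaks; detection power and recovery
margins remain wide at these sizes. Every stage seed derives from a single
global seed via SHA-256 of (seed, stage, unit), so runs are reproducible
end to end and independent of execution order; re-running a pipeline config
reproduces its measure table byte for byte.

## Known limitations

- The EDF writer emits a minimal single-record EDF (16-bit quantization over
  each channel's observed range); it round-trips through standard readers
  but carries placeholder acquisition metadata.
- Epoch rejection is a simple z-score rule on mean absolute amplitude
  (|z| > 2 over 1-s epochs), a stand-in for full artifact pipelines; ICA
  cleaning is out of scope.
- Occurrence counts boundary-truncated runs while mean duration excludes
  them; for very short recordings (few runs per map) the
  coverage ≈ occurrence × duration identity degrades accordingly.
- Narrow-band filtering (e.g. delta, 1–4 Hz) has an impulse response longer
  than a typical microstate, so band-wise durations are systematically
  longer than broadband ones; comparisons should stay within a band.
- `select_k_by_reliability` pools subjects across groups against the
  across-group mean map set; with strong topographic group differences
  (not part of the generative model here) a per-group selection would be
  preferable.
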
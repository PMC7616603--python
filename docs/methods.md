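# Methods

## The model

The package tests *when* multichannel EEG responses carry information
predicted by a model of the stimuli.  For a cohort of participants, each
with epoched data (trials × channels × timepoints, µV, millisecond time
axis) and per-trial metadata (scene, object concept, congruent/incongruent
condition), the analysis proceeds in four stages.

**1. Neural RDMs.**  At each timepoint t, trial i contributes the pattern
x_i(t) ∈ R^C of its C channel amplitudes.  The dissimilarity between
trials i and j is the correlation distance d_ij(t) = 1 − Pearson(x_i(t),
x_j(t)) ∈ [0, 2], collected into one symmetric, zero-diagonal RDM per
timepoint.  Patterns are single-timepoint channel vectors over all
channels; an optional centred boxcar (odd width, default off) can average
neighbouring timepoints for noise robustness.  A constant pattern makes
the distance undefined and raises an error naming the trial and timepoint
— simulated and recorded EEG is never exactly constant, so this condition
flags pipeline bugs rather than being silently converted to NaN.

**2. Model RDMs.**  The *congruency* model codes each kept trial 1
(congruent) or 0 (incongruent) and takes |c_i − c_j|, i.e. 0 within and 1
across conditions.  Model RDMs are participant-specific because the
counterbalanced design gives every participant their own scene→condition
assignment.  The *semantic* model represents each object by its
property-norm feature vector and takes the cosine distance
1 − u·v/(‖u‖‖v‖) ∈ [0, 1] between all pairs, built separately for
congruent and incongruent trials.  Object labels are matched to norm
concepts by exact case-insensitive equality, then by a user-supplied
alias table; there is deliberately no fuzzy matching, so every exclusion
is auditable.  Unmatched trials are excluded from the semantic analysis
only; the congruency analysis uses all kept trials.  Feature vectors are
used as given; a `binarize` switch thresholds them at value > 0.

**3. Per-subject fit.**  The fit at timepoint t is the Spearman rank
correlation ρ between the strictly-lower triangles (diagonal excluded) of
the model RDM and the neural RDM, with average ranks for ties — essential
because the binary congruency triangle is maximally tied.  The neural
series is automatically subset to the model's trial labels, so
per-condition models apply directly.

**4. Group inference.**  Per timepoint, a one-sample t = mean/(sd/√n)
(sd with n − 1) tests the subject ρ values against zero.  Contiguous runs
where |t| exceeds the two-tailed critical value at the cluster-forming
alpha (default 0.01), split wherever the sign changes, form clusters with
mass Σt.  Significance is assigned by a max-statistic sign-flip
permutation test: each of n_perm (default 10,000) permutations draws an
independent ±1 per subject, multiplies that subject's whole ρ time
series, recomputes the t series, and contributes its maximum |cluster
mass| (0 if none) to the null distribution.  Each observed cluster's
p-value is (#{maxima ≥ |observed mass|} + 1)/(n_perm + 1): the observed
statistic counts as a member of its own reference set, so p ≥
1/(n_perm + 1) always, and a larger |mass| never gets a larger p.  The
paired condition contrast applies identical machinery to per-subject ρ
differences (bit-identical to the one-sample test on the difference
matrix at a fixed seed).  Finally, the time-course analysis Pearson-
correlates the group-mean congruency fit with the group-mean semantic fit
difference (incongruent − congruent) across timepoints, with a two-tailed
p from the t distribution with n − 2 degrees of freedom.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` (cluster forming) | 0.01 | two-tailed per-timepoint t threshold that defines clusters |
| `n_perm` | 10,000 | sign-flip permutations; p-floor is 1/(n_perm+1) |
| `tail` | `two` | `two`: signed clusters, null = max absolute mass across both signs; `pos`: one-tailed threshold, positive clusters only |
| `seed` | required | generator for the sign flips; logged in every report |
| `baseline_window` | (−200, 0) ms | closed interval whose per-trial/channel mean is subtracted |
| `ptp_threshold_uv` / `zvar_threshold` | 200 µV / 4 | automatic trial rejection (below) |
| `window_samples` | 1 | odd boxcar width for neural patterns |

Design choices where the design was genuinely open:

* **Tail convention.**  The cluster-forming test is two-tailed with
  signed clusters, and the permutation maximum is taken over the absolute
  mass, controlling family-wise error across both signs.  This is
  conservative and symmetric; positive effects remain detectable, and a
  `pos` tail is available when a directional test is wanted.
* **Trial rejection.**  Manual visual inspection is not reproducible, so
  rejection is a deterministic two-rule heuristic: drop a trial when its
  worst-channel peak-to-peak amplitude exceeds 200 µV, or when the
  z-score (across trials) of its log-variance exceeds 4.  Rejection runs
  before baseline correction; flags are recorded in the trial table
  (`keep=False`) and amplitudes are never modified.
* **Order of operations.**  Rejection first, then baseline correction;
  baseline correction is idempotent and windows are closed intervals
  evaluated on the ms grid.
* **Time-course correlation window.**  Defaults to the full epoch and is
  configurable; no particular sub-window is asserted as canonical.
* **Seeds.**  The semantic analysis derives its three test seeds as seed,
  seed+1, seed+2 (congruent, incongruent, difference) so one user seed
  reproduces the whole run.
* **Float ties in the permutation count.**  A permutation that happens to
  reproduce the observed sign pattern recomputes the observed mass up to
  rounding; the ≥ comparison therefore uses a relative 1e-9 tie guard so
  such permutations are counted, keeping Monte-Carlo p-values consistent
  with exhaustive enumeration.

## The synthetic-data generator

`simulate_cohort` emulates the study design the pipeline targets:

* **Design.**  152 scenes per participant (even count required), each
  seen exactly once, half congruent and half incongruent (76/76); group B
  participants receive the complementary assignment of group A for every
  scene; each scene's congruent and incongruent objects are distinct
  concepts from the synthetic pool.
* **Norms.**  826 concepts × 3026 binary features with i.i.d.
  Bernoulli(0.005) entries (~15 features per concept, matching the scale
  of published property-norm sets); all-zero rows are resampled.  Eight
  planted categories, each owning a disjoint signature-feature block
  boosted by mixing weight 0.5, give within-category cosine distances
  smaller than between-category ones in expectation — without this the
  semantic RDM of sparse random vectors has too little variance to carry
  signal.
* **Epochs.**  64 channels, −200..900 ms at 5 ms (200 Hz sampling, 221
  timepoints).  Data = Gaussian white noise (sd 1 µV; optional AR(1)
  temporal correlation, default off, because cluster tests are sensitive
  to autocorrelation) plus two planted signals.  The *congruency* signal
  is one fixed random unit channel pattern per subject added with
  +amplitude on congruent and −amplitude on incongruent trials inside the
  congruency window (default 290–450 ms); the bipolar ±pattern makes the
  neural RDM match the binary model exactly at high SNR.  The *semantic*
  signal projects each trial's feature vector through a fixed random
  channel projection (per subject), normalised to unit pattern norm, and
  adds it inside that condition's semantic window (defaults 150–235 ms
  congruent, 150–360 ms incongruent).  Window edges carry a one-grid-step
  linear ramp (boundary samples at half weight) to avoid abrupt onsets.
  Default effect amplitude is 1.0; validation runs use amplitude 2.0
  against noise sd 1.0 as their "high SNR" condition.

Everything is deterministic under (config, seed): per-subject noise
streams derive from the master seed, and writing the same cohort twice
produces byte-identical files.

**What the generator does not emulate** — and hence what passing tests do
not show about recordings: 1/f spectra and channel covariance, ERP
waveform morphology (no N300/N400 shapes), eye/muscle artifacts,
volume-conduction topographies, graded production frequencies in the
norms, and any behaviour of the matching step on real object labels
(plural forms, multi-word labels).  Recovery results demonstrate that the
*pipeline* detects the geometry it is pointed at, not that real EEG
contains that geometry.

## Numerical choices

* Amplitudes are stored as float64 in the HDF5 container so read∘write is
  the identity, bit for bit.
* RDMs enforce symmetry to 1e-12 and an exactly zero diagonal; the
  batched per-timepoint computation symmetrises explicitly and clips
  correlation distances into [0, 2] (cosine into [0, 1]) before
  validation.
* Spearman ρ is computed as the Pearson correlation of average ranks
  (`scipy.stats.rankdata`), vectorised across timepoints; single-pair
  calls go through `scipy.stats.spearmanr` and the two paths agree to
  1e-12 in tests.
* A timepoint with zero between-subject variance yields t = ±∞ (sign of
  the mean), which exceeds any threshold; 0/0 is defined as t = 0.
* Degenerate inputs fail loudly: zero feature vectors, constant patterns,
  empty baseline windows, all-rejected cohorts, fewer than 3 subjects or
  item pairs.

## Validation problem sizes

The automated checks run at sizes chosen to exercise the full design
where it is cheap and scaled-down cohorts where many replications are
needed: structural checks use the full 152-trial × 64-channel × 221-
timepoint design; oracle-equivalence checks compare every distance, rank
and cluster statistic against brute-force reimplementations on 100+
random fixtures at 1e-10; Monte-Carlo sign-flip p-values are compared
against exhaustive 2¹⁰ enumeration for 10 subjects; type-I calibration
uses 500 pure-noise cohorts of 20 subjects (1000 permutations each); and
injected-effect recovery uses 50 simulations per scenario of 20-subject
cohorts scaled to 64 scenes × 32 channels on the full −200..900 ms grid.
`scripts/acceptance.py` re-runs the same machinery end to end and reports
the quantities it computes.

## Known limitations

* The pipeline reads only its own HDF5 interchange container; vendor EEG
  formats must be converted upstream (raw-EEG filtering, down-sampling
  and ICA are likewise assumed done upstream).
* Cluster on/offsets inherit the usual caveat of cluster-based inference:
  the test licenses a claim about the cluster as a whole, not about its
  exact boundaries.
* No cross-validated distances (crossnobis/LDA-t), TFCE, cluster-extent
  statistics or FDR across clusters; inference is cluster mass with
  max-statistic FWER only.
* Concept matching is intentionally exact-plus-alias; corpora whose
  labels need morphological normalisation require an explicit alias
  table.
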
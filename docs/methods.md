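# Methods

`erpconsensus` identifies the time window and scalp topography of a target
event-related potential (ERP) component — here the frontal N2 and the
centro-parietal P3 — for *each individual subject* from single-trial EEG
epochs, instead of reading both off a grand average. The device that makes
this workable at single-trial signal-to-noise ratios is consensus clustering
applied twice: within each trial across a suite of base clustering methods,
and across trials within a subject/condition.

## Data model

Every epoch is an `n_time × n_electrodes` matrix in µV on a uniform time
axis. Time points are the clustering observations and electrodes the
features, so a cluster is a set of time points sharing a quasi-stable scalp
map, and a *segment* (maximal run of one label) is a candidate component
window. All latencies are reported at sample centres; windows are inclusive
on both ends.

## Similarity primitives

The spatial correlation between two maps u, v over F electrodes is the
uncentred cosine

    Corr(u, v) = Σᵢ uᵢvᵢ / (‖u‖‖v‖),

deliberately polarity-sensitive: an inverted map scores −1. (Classical
microstate analysis rectifies polarity, which conflates, e.g., a frontal
negativity with a frontal positivity.) A `centered=True` flag computes the
mean-subtracted (Pearson) variant; the default is the plain cosine, matching
the displayed formula rather than the word "Pearson". The *inner similarity*
of a window is the mean pairwise spatial correlation over its time points,
computed in closed form from the sum of unit-normalised rows; it is defined
only for ≥ 2 samples (callers enforce minimum durations).

## Base clustering and standardization

Nine base methods cluster each epoch at K clusters: k-means (KM), Ward
hierarchical (HC), fuzzy c-means (FCM, m = 2, hard labels by maximum
membership), a 1 × K batch self-organising map (SOM), spectral clustering on
a diffusion-map embedding (DSPC; Gaussian kernel, bandwidth = median pairwise
distance, 10 components scaled by their eigenvalues), polarity-respecting
modified k-means (MKM; cosine assignment, normalised-mean centroids — with
`polarity=False` it becomes the classical sign-blind variant with
eigenvector centroids), spectral clustering with a median-bandwidth RBF
affinity (SPC), alternating k-medoids (KMD), and a full-covariance Gaussian
mixture (GMM, labels by maximum responsibility). Every stochastic method
receives a seed derived by CRC from a master seed and its (subject,
condition, trial, method) context, so the entire study is reproducible from
one integer.

Before clustering, each time point's map is scaled to unit L2 norm
(`normalize_maps`, default on). This standardization step matters: on raw
voltages, Euclidean methods carve a large component such as a 5 µV P3 into
concentric *amplitude shells* — the same label reappears on the rising and
falling flank — and the cluster budget is spent on one component. On the
unit sphere, clusters are topographic directions (polarity preserved), which
is what a component is. Scores (inner similarity, correlation, amplitude)
are always computed on the raw data; normalization affects only the
clustering geometry.

## Consensus machinery

For an ensemble of labelings over one time axis, the co-association matrix
S holds the fraction of labelings placing two time points together. The CSPA
consensus partitions S into K clusters by deterministic average-linkage
agglomeration on 1 − S (equivalent to hypergraph partitioning on
block-structured S, without a METIS dependency). The selected consensus is
the argmax of mean normalized mutual information (NMI, arithmetic-mean
normalisation; a constant labeling has NMI 0 by convention) over the
candidate set {input labelings ∪ CSPA result}, with ties resolved toward
CSPA. Within-trial consensus runs every surviving base method on the epoch
and combines; methods that fail (non-convergence, collapse to one cluster)
are dropped. Across-trial consensus applies the same selection to the
per-trial consensus labelings.

## Pipeline

1. **Method screening.** Candidate methods are vetted per subject on the
   conditions' ERPs stacked along time: a method is kept when the window it
   recovers for the screening target passes inner similarity > 0.95 and
   duration > 50 ms in every condition (stochastic methods: majority of 10
   seeded repeats). If fewer than two survive, a replacement list screened
   identically on the group-average ERP is used (and if that also yields
   fewer than two, all candidates).
2. **Optimal K.** On the group-average ERP, K = 2..15 are scanned; for each
   K the target windows are determined against the templates and the profile
   records the worst target's inner similarity. The selected K is the
   smallest with profile ≥ 0.95 changing by ≤ 0.02 at K+1 (argmax with a
   warning when none qualifies). The scan must use the templates: the N2 and
   P3 search intervals overlap, and a template-free inner-similarity argmax
   happily returns the same P3 segment for both.
3. **Templates.** For simulated studies the generator's predefined component
   maps serve as templates (`ground_truth_template`); for real data
   `derive_template` clusters the group-average ERP and takes the mean map
   of the best window in the component's search interval. Default search
   intervals: N2 [150, 350] ms scored at Fz; P3 [250, 600] ms scored at Cz.
4. **Trial selection.** Each trial is consensus-clustered once
   (template-independent, shared across target components). A trial is kept
   when a window matching the template can be determined at the trial
   thresholds (inner similarity 0.90, correlation starting at 0.70). The
   correlation threshold decrements by 0.05 to 0.50 until ≥ 50 % of trials
   are retained; if the floor still retains fewer, the inner-similarity
   threshold relaxes the same way (both sensitivity parameters are
   adjustable when no map is found — at 1 µV channel noise a single-trial N2
   window's inner similarity is bounded far below 0.90, so the correlation
   criterion is the effective gate). Whatever is retained at the last rung
   proceeds, flagged.
5. **Window determination.** Candidate maps are segments (≥ 2 samples,
   after thin maps < 10 ms are absorbed into a neighbour correlating
   > 0.90) overlapping the search interval with inner similarity above
   threshold; among them those correlating with the template above threshold
   compete and the highest correlation wins, comparing correlations at 0.01
   resolution so that near-ties go to the longer, earlier map. The window is
   the union of the contiguous chain of qualifying maps around the winner —
   a component's rise, core, and decay are separate consensus maps sharing
   its topography — where chain members need template correlation at the
   accepted threshold and inner similarity ≥ min(threshold, 0.5) (keeping
   transition slivers between components out). Subject-level thresholds are
   0.95/0.90 with the same 0.05-step relaxation (floors 0.50 for
   correlation, 0.20 for inner similarity); "not identified" is a value,
   not an error.
6. **Scoring.** The subject window is determined on the subject's full
   condition ERP from the across-trial consensus labeling (the selected
   trials shape the labeling; every trial carries signal, so the full
   average is the better-resolved readout). A score row holds window start
   and end (ms), inner similarity, mean amplitude at the component's site,
   and spatial correlation of the window's mean map to the template. The
   same scoring applies per trial with the trial's own window.

## Synthetic study generator

The generator emulates a stimulus-locked two-condition ERP study: 20
subjects × 2 conditions × 70 trials at 32 standard 10-20/10-10 electrodes
(unit-disk projected), epochs −100..700 ms at 500 Hz (400 samples), white
Gaussian channel noise of 1 µV. Components are separable space-time
products: a spatial Gaussian bump with unit peak of the component's polarity
at its centre electrode, times a truncated (bi-)Gaussian pulse whose total
support equals the drawn duration, split `rise_frac` before the peak and the
rest after, with σ = flank/3.

Subject-level parameters are drawn uniformly per subject (shared across
conditions); each trial adds uniform jitter within the stated deviations;
the condition effect scales the target amplitudes in condition 2 (N2 × 0.64,
P3 × 0.49), back-solved from the ratio of the reported mean window
amplitudes. Defaults:

| comp | centre | spread | latency (ms) | duration (ms) | magnitude (µV) | jitter (ms, µV, ms) | rise |
|------|--------|-------:|--------------|---------------|----------------|---------------------|------|
| N1 | Oz | 0.50 | 85–105 | 40–80 | −2.5..−1.5 | 10, 1, 10 | 0.5 |
| P2 | FCz | 0.50 | 110–130 | 40–80 | 1.5..2.5 | 10, 1, 10 | 0.5 |
| N2 | Fz | 0.60 | 200–250 | 100–200 | −2.5..−1.5 | 50, 2, 50 | 0.5 |
| P3 | Pz | 0.60 | 250–450 | 350–500 | 4..6 | 100, 3, 100 | 0.10 |

Design rationale for the free choices (the N2/P3 rows' latency, duration,
magnitude, and jitter are the study conditions; the rest is ours):

* **P3 morphology.** The P3 uses a steep onset and slow decay
  (`rise_frac = 0.10`). With its long 350–500 ms durations and latencies
  down to 250 ms, a symmetric pulse would cover the entire N2 latency range
  with several µV for early-P3 subjects, and no frontal N2 could ever be
  recovered at its stated −2.5..−1.5 µV. With the steep onset the P3
  support never begins before 200 ms for any admissible draw, so every
  subject keeps an uncontaminated N2 flank. The recovered P3 windows are
  correspondingly right-skewed around the drawn latency.
* **Backgrounds early and compact.** N1 and P2 are finished before the N2
  latency range begins; a P2 peaking at ~180 ms would sit inside the N2
  window and cancel it frontally.
* **Distinct maps.** The P3 is centred at Pz (classic centro-parietal
  topography; Cz stays its amplitude-scoring site) so the N2/P3 maps have
  cosine ≈ −0.5 rather than being collinear midline bumps.

What the generator deliberately does **not** emulate: realistic head-model
lead fields (maps are parametric bumps), correlated or 1/f background EEG
(noise is white by design), artifacts, latency correlations between
components within a subject, and channel-count variation. Passing tests
therefore show that the *pipeline machinery* recovers known space-time
structure at realistic SNR — not that it is robust to structured real-EEG
noise or to overlapping components with correlated topographies.

## Reliability scoring

Analytical standard errors use the n−1 sample SD: SE = SD/√n over trials or
subjects. The Monte-Carlo test resamples a subject's pool of per-trial
consensus labelings with replacement (no re-clustering), reruns across-trial
consensus and window determination per iteration, scores the drawn trials,
and aggregates per-iteration SE_r = SD_r/√N into mcSE = √(mean SE_r²);
iterations with no identifiable window count as missing and the missing rate
is reported. Across subjects, MS(SE) is the mean squared subject SE, Var_par
the between-subject score variance, Var_all = Var_par + MS(SE) exactly (by
construction), and reliability = 1 − MS(SE)/Var_all. Cronbach's alpha takes
an explicit subjects × items matrix (the conditions of one score type by
default; the attribution of "items" is ambiguous in this design, so the
caller decides); SEM = SD·√(1−α). The two-level repeated-measures condition
test is computed from paired differences: F = t², df (1, n−1), partial
η² = F/(F+n−1); a zero-variance nonzero-mean difference reports an infinite
F with a `capped` flag.

## Numerical and degenerate-input conventions

Zero-norm maps make the cosine undefined and raise; window operations on
empty slices raise; `ms_to_idx` rounds half-up deterministically; constant
labelings have NMI 0; CSPA with m = 1 returns that partition; empty k-means
or k-medoids clusters are re-seeded from the worst-fit point; GMM uses a
1e-4 covariance regulariser. Relaxation ladders move in exact 0.05 steps
with a 1e-9 guard against float drift.

## Problem sizes

The reference run (`erpconsensus.reference.reference_study`) executes the
full default study — 20 subjects × 2 conditions × 70 trials, one repetition
— in roughly ten to fifteen minutes on one core; base-method restart counts
(k-means 2, modified k-means 2, GMM 1, k-means inside the diffusion
embedding 4) were chosen to keep a 2 800-trial study at that scale while
leaving planted-structure recovery exact in the test suite.
Unit tests run on planted partitions and miniature studies (2 subjects × 6
trials) in a few minutes.

## Known limitations

* At the stated noise level the N2's window inner similarity on 70-trial
  averages is bounded near 0.7 in this generator (weak flanks dominate the
  pairwise mean); the P3's sits near 0.95.
* The optimal-K stability scan on the grand average is marginal between 6
  and 8 clusters: the K at which the N2 map separates from the P3 onset
  region depends on the seed.
* Subjects whose drawn P3 latency nearly coincides with their N2 latency
  have only a narrow clean N2 flank; with unlucky draws the N2 is flagged
  not-identified rather than forced.
* The CSPA partitioner is average-linkage on 1 − S; on non-block-structured
  co-association matrices this is an approximation to graph partitioning.
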
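# Methods

This note documents the models, estimators and design choices behind
`neurogut`, in the order the pipeline runs.

## EEG preprocessing

Recordings are expected as channels × samples matrices in microvolts with
10–20 labels (modern temporal names T7/T8/P7/P8 are canonicalized to
T3/T4/T5/T6). All metrics are computed on **common-average-referenced**
signals. Spatial filters that depend on third-party artifact models
(surface Laplacian, artifact-subspace reconstruction, wavelet-ICA) are
deliberately out of scope: CAR keeps the package self-contained, and because
every statistic in the pipeline is a *paired within-subject contrast*, the
choice of reference shifts absolute connectivity levels but not the
pre/post inference. Absolute iCOH values from this package are therefore not
comparable to Laplacian-referenced values; their paired differences are.

Band-limiting uses zero-phase (forward–backward) FIR filters designed with a
Hamming window; the transition width is max(1 Hz, 10 % of the lower band
edge), giving > 50 dB one-pass stopband attenuation (doubled by
forward–backward application). Filtering happens at the native rate
(500 Hz in the reference setting) *before* any decimation so transition
bands are defined where the data were acquired.

For the nonlinear metrics, signals are low-passed at 80 Hz (0.8 × the target
Nyquist) and polyphase-resampled to 200 Hz, then cut into non-overlapping
8-s epochs of exactly 1600 samples; the trailing remainder is dropped.
Epochs whose peak absolute amplitude in any channel or band exceeds a
threshold (default 500 µV, configurable) are rejected and logged — a simple
amplitude screen standing where full artifact reconstruction is out of
scope. Connectivity is computed on the continuous cleaned signal at the
native rate, not on the 200 Hz epochs.

## Connectivity

Cross-spectra are Welch estimates: 1-s Hann-tapered segments with 50 %
shift, per-segment linear detrend, one-sided density scaling (verified
against `scipy.signal.csd`). Coherency is the normalized cross-spectrum
`C_ij(f) = S_ij/√(S_ii S_jj)`; the connectivity weight per band is the
arithmetic mean over in-band FFT bins of `|Im C_ij(f)|` (imaginary
coherence). The imaginary part vanishes for instantaneous (zero-lag) mixing,
which is what makes it robust to volume conduction; the package's tests pin
this property (x vs x+noise has high |C| but near-zero iCOH).

Two estimator facts matter when reading small iCOH values:

* With K segments, the null distribution of each of Re Ĉ and Im Ĉ is
  ≈ N(0, 1/(2K_eff)), so `|Im Ĉ|` has a **bias floor** of
  `√(1/(2K_eff))·√(2/π)` — about 0.055 for a 60-s recording at the default
  window settings. Independent channels do not read 0; they read the floor.
* The floor shrinks like 1/√duration; tests assert against the analytic
  floor rather than against zero.

The iCOH matrix is read as a weighted undirected graph (no thresholding —
every positive weight is an edge; edge length = 1/weight):

* **Global efficiency** — mean inverse shortest-path length over ordered
  node pairs (Dijkstra via `scipy.sparse.csgraph`); unreachable pairs
  contribute 0.
* **Local efficiency** — per node, the global efficiency of the subgraph
  induced by its neighbors; nodes with < 2 neighbors score 0.
* **Transitivity** — `trace((W^{1/3})³) / Σ k_i(k_i−1)` with k the count of
  nonzero weights: the geometric-mean triangle intensity over connected
  triples. Note that T (and LE) are *not* monotone under edge addition —
  a new edge can grow the degree denominator without closing a triangle —
  so only GE carries a monotonicity guarantee.

## Complexity metrics

All four metrics run per 1600-sample epoch, per channel, per band, and are
averaged over epochs (epochs flagged invalid for one metric are excluded
from that metric's average only).

* **Katz FD.** With unit abscissa spacing, L is the Euclidean curve length
  `Σ√(1+Δx²)` and d the maximal Euclidean distance from the first sample;
  `FD = log₁₀ n / (log₁₀ n + log₁₀ (d/L))` with n the number of steps.
  Katz's definition is ambiguous about abscissa scaling; unit spacing makes
  a straight line satisfy d = L exactly, hence FD = 1 (the boundary anchor),
  and affects absolute levels but not pre/post contrasts. Constant or
  single-step signals return 1 by convention. The often-quoted "EEG FD lies
  in [1, 1.5]" is descriptive of EEG-like signals, not an enforced bound.
* **QSE.** Sample entropy with m = 2, tolerance r = 0.2 × epoch SD
  (standard SampEn practice), Chebyshev distance, self-matches excluded,
  template sets of both lengths drawn from the first N−m positions.
  QSE = SampEn + ln(2·r·SD) uses the *absolute* tolerance so values are in
  nats of the signal's amplitude units and comparable across tolerance
  choices. Zero-variance epochs are flagged and excluded; epochs with no
  template matches return NaN and are excluded from the average.
* **Quantile graph.** Samples map to Q = 8 empirical amplitude quantiles
  (boundaries at k/Q; a sample equal to a boundary goes to the lower
  quantile, so the assignment is rank-based and affine-invariant).
  Consecutive-sample transitions form a weighted directed graph; the summary
  is the occupancy-weighted expected hop distance
  `Δ = Σ_ab π_a w_ab |a−b|`, with π the source-sample occupancy. Q is
  configurable; conclusions should be checked across Q ∈ {4, 8, 16} when it
  matters (the config exposes Q).
* **Visibility graph.** Natural (not horizontal) visibility with the
  *strict* line-of-sight criterion: collinear intermediate points block
  visibility, so a monotone ramp yields exactly the path graph. A small
  slope margin (1e-9 × signal scale) keeps float jitter in collinear runs
  from faking strict dominance. The summary is the graph index complexity
  `GIC = 4c(1−c)` where c rescales the largest adjacency eigenvalue between
  the path graph (c = 0) and the complete graph (c = 1); c is clipped to
  [0, 1] against eigenvalue round-off. The Lanczos solver used for long
  epochs is given a fixed start vector so results are bit-reproducible.

## Paired statistics

Wilcoxon signed-rank on d = pre − post: zero differences dropped (≥ 5
informative pairs required), midranks for ties, W⁺ = rank sum of positive
differences. The reported z is `(W⁺ − n(n+1)/4)/σ` with the tie-corrected
variance `n(n+1)(2n+1)/24 − Σ(t³−t)/48` and no continuity correction; the
sign convention makes increases after the intervention negative. For n ≤ 12
the p-value comes from full 2ⁿ sign enumeration (two-sided = twice the
smaller tail, capped at 1); above that the normal approximation is used —
at the n = 50 regime the package targets, the two agree at the 0.05
threshold in ≥ 95 % of random instances (tested).

BH correction is applied within each (metric, band) family of the four
nonlinear metrics (21 electrodes per family), with significance at
q < 0.10. iCOH pair tests are reported with raw p < 0.05 flags only, and
the global network metrics (GE, T) and LE are likewise uncorrected — their
multiplicity status is flagged as such in the output. A calibration fact
worth knowing: under a global null, BH makes at least one rejection with
probability ≈ q, so ~10 % of null cohorts will show some q < 0.10 finding;
this is a property of FDR control, not an implementation defect.

## Microbiome

Counts are never rarefied; all compositional statements use relative
abundances. Alpha diversity: bias-corrected Chao1
(`S_obs + F₁(F₁−1)/(2(F₂+1))`, robust when no doubletons exist), Shannon in
natural log (configurable base), Simpson as 1 − Σp². Beta diversity:
Bray–Curtis on proportions, Jaccard on presence/absence (the classic
unweighted form). PCoA double-centers the squared-distance Gower matrix and
reports negative eigenvalues rather than dropping them (scikit-bio backend).
Alpha comparisons use tie-corrected Kruskal–Wallis; beta comparisons use an
in-package permutation PERMANOVA (pseudo-F from the squared-distance
partition, p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), seeded and invariant
to sample order via canonical id ordering; cross-checked against
scikit-bio). Pre and post are treated as the two groups of the named
unpaired procedures; the within-subject pairing enters through the shift
report and correlation stages instead.

Shift reports collapse counts to each lineage rank and quote
`100 × (post − pre)/pre` on **condition-mean** relative abundances — the
convention that makes a 3.48× fold change on a 0.1 %-abundance taxon read
as ≈ +248 % — plus a per-taxon paired Wilcoxon p. Taxa absent before the
intervention are flagged "emergent" with no percentage.

## Gut–brain correlation

Per-subject deltas (post − pre) of every nonlinear EEG feature are screened
against per-subject taxa shifts with Kendall tau-b (tie-corrected — taxa
deltas tie at zero). For n ≤ 9 the p-value is exact by full n! enumeration
(valid under ties); above that the normal approximation is used, floored at
2/n! so no pair can report an unattainably small p at small cohort sizes.
The full grid is one BH family (family size audited in the output); pairs
with uncorrected p < 0.001 get a Spearman follow-up and only those pairs
do. Missing subjects are dropped listwise per pair with a minimum of 5
complete pairs.

## Synthetic cohorts

The EEG generator builds each channel as a sum of **narrowband stochastic
oscillations** — random-phase spectra confined to a configurable bandwidth
(default 2 Hz) around each component's center frequency — plus 1/f noise
synthesized by spectral shaping of white noise. Narrowband *stochastic*
components rather than deterministic sinusoids are essential: phase-locked
tones at a shared frequency are mutually coherent no matter what, whereas
independent narrowband processes give coherence at the estimator floor
unless a coupling explicitly injects a phase-lagged copy of the source
component into the target channel
(`target = √(1−s²)·own + s·shift_φ(source)`), which yields the analytic
coherency `s·e^{−iφ}` and iCOH `s·sin φ` at the component frequencies.
Defaults emulate resting adult EEG: components at 2, 6, 10 and 20 Hz with
alpha dominant (15 µV), 1/f noise exponent 1, 10 µV noise scale, 21-channel
montage at 500 Hz, log-normal per-subject amplitude jitter (σ = 0.2) shared
between a subject's pre and post recordings so paired tests see realistic
between-subject variance. The "post" condition multiplies selected coupling
strengths by the effect factor (clipped to [0, 1]). Everything is
byte-deterministic under the seed. What the generator does **not** emulate:
head-volume conduction (beyond what CAR reintroduces), blink/EMG artifacts,
non-stationarity, electrode drift — so passing recovery tests demonstrate
estimator correctness, not robustness to real-world artifacts.

The taxa generator draws per-subject compositions from a Dirichlet around a
base profile (concentration = overdispersion; ∞ disables subject
variation), applies per-taxon fold changes to the post composition with
renormalization, and samples multinomial counts at fixed depth (default
100 000 reads, 13 subjects, 40 taxa with clearly synthetic lineage strings).
It does not emulate sequencing error, variable depth, or compositional
zero-inflation beyond what the multinomial produces.

## Problem sizes used in the checks

Statistical checks run at deliberately chosen scales: type-I calibration on
1000 null cohorts of 50 subjects × 21 features; PERMANOVA null uniformity
on 200 runs × 199 permutations; coupling recovery on 10 replicates of
50-subject cohorts with 60-s six-channel recordings; fold-change recovery
on 13 subjects at 100 000 reads. Oracle-equivalence checks use exhaustive
enumeration at sizes where enumeration is exact (graphs ≤ 8 nodes, 200-sample
entropy epochs, 64-point visibility series, 2ⁿ sign assignments for n ≤ 12,
n! orderings for n ≤ 9).

## Known limitations

* CAR instead of Laplacian/ASR/wICA shifts absolute connectivity levels
  (documented above); only paired contrasts are reference-robust.
* iCOH's estimator bias floor means weak true couplings (s·sin φ below
  ~0.05 at 60 s) are not distinguishable from zero at single-recording
  level.
* The pairwise Kruskal–Wallis / PERMANOVA treat pre and post as independent
  groups, as the named procedures do; subject pairing is not exploited
  there.
* Band summarization of iCOH is an unweighted mean over FFT bins; a
  power-weighted mean would emphasize bins with actual signal content.
* Kendall p-values for 9 < n ≤ 13 use the normal approximation, which is
  mildly conservative in the extreme tail relative to the exact permutation
  distribution.
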
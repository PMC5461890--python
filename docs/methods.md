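# Methods

## Detection model

The detector treats burst / inter-burst segmentation of a single EEG
channel as per-sample binary classification on a 64 Hz grid. The signal
chain is:

1. **Rate handling.** The raw channel (µV, acquisition rate 256 Hz) is
   anti-alias filtered and decimated to 64 Hz for all features except the
   frequency-weighted energy operators, which are computed at the
   acquisition rate because their output depends on the sampling rate;
   their feature streams are then taken down to 64 Hz by plain stride-4
   subsampling, the preceding 1–1.5 s moving average serving as the
   anti-alias filter (this also keeps the envelope–derivative operator's
   stream exactly non-negative).
2. **Band filtering.** Zero-phase (forward–backward) 5th-order Butterworth
   band-passes into 0.5–3, 3–8, 8–15 and 15–30 Hz, plus the broadband
   0.5–30 Hz signal. The energy operators use a 1st-order Butterworth
   high-pass at 0.5 Hz with a 6th-order elliptic low-pass at 10 Hz
   (0.5 dB ripple, 50 dB attenuation; 1–20 Hz for the line-length
   baseline).
3. **Features.** 26 per-channel features: squared analytic envelope per
   band (1 s windows, median summary), relative band power, log–log
   spectral slope and r², periodic mean frequency, instantaneous frequency
   (2 s windows; median summary for the instantaneous frequency), Higuchi
   fractal dimension of the broadband signal (1 s windows, k_max = 8), and
   the envelope–derivative operator (EDO). Windows overlap 75%; each
   window's value is held over its central hop interval, with
   nearest-value fill at the record edges, so all columns share one 64 Hz
   grid.
4. **Normalisation.** Heavy-tailed features (EDO, envelope, relative
   power; NLEO and line length in the baselines) are natural-log
   transformed (floored at 1e-12), then all features are z-scored with
   parameters estimated on the training data only.
5. **Selection and fusion.** Training rows are thinned to every 500th
   sample per record (neighbouring samples are heavily correlated), then
   reduced 26 → 16 by a greedy mRMR filter (difference form; mutual
   information on 10 equal-frequency bins), then by a
   backwards-elimination wrapper scored with inner leave-one-record-out
   sample-wise AUC; the subset with the best inner AUC along the
   elimination path is kept (ties prefer the smaller subset, then
   lexicographic order). A linear SVM is trained on the selected columns.
6. **Post-processing.** The continuous SVM output is thresholded (static
   T = 0 by default; adaptive T = per-record mean as an infant-dependent
   operating point) and segments shorter than class-specific minimum
   durations are relabelled to the flanking class, shortest first, bursts
   before inter-bursts on ties; segments touching the record edges are
   exempt because they are truncated rather than complete. The operation
   is idempotent. The limits default to the 2.5th percentile
   (linear-interpolation percentile) of complete annotated segment
   durations, pooled over the training records.

Assumptions: channels are processed independently (bursts can be focal or
asynchronous across hemispheres); annotations and signal share a time
origin; training labels are a consensus — samples where two reviewers
disagree are excluded from both training and sample-based evaluation.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| feature grid | 64 | Hz | uniform rate for all features; resolves the 0.5 Hz band edge in 2 s windows |
| windows | 1 / 2 | s | 1 s for amplitude and fractal dimension (non-stationarity), 2 s for spectra (0.5 Hz resolution) |
| overlap | 75 | % | smooth per-sample expansion |
| mRMR shortlist | 16 | features | keeps the wrapper affordable while exceeding typical selected-set sizes (~9) |
| SVM | C = 1, tol = 1e-4 | — | class-balanced linear SVM; primal squared-hinge solver (fast, deterministic) |
| subsampling | 500 | samples | ~77 training rows per 10 min record; applied per record so results do not depend on record order |
| duration limits | 2.5th | percentile | removes implausibly short segments without erasing genuine short events |
| Higuchi k_max | 8 | scales | largest scale with ≥ 8 points per curve-length estimate in a 64-sample window |

## Numerical conventions

* The periodic mean frequency maps the half spectrum k = 0 … N/2−1 onto
  the full unit circle (weight e^{j4πk/N}) so that the estimate spans
  [0, fs/2) and a pure tone is recovered exactly; the circular form avoids
  edge bias for spectra concentrated near 0 or Nyquist.
* The EDO is computed as ¼|z(n+1) − z(n−1)|² (sum of squared central
  differences of the analytic signal), which vanishes at DC and is
  exactly non-negative in floating point; an alternative sign convention
  for the cross terms (maximal at DC) is available behind a compatibility
  flag.
* Spectral features use the raw (rectangular-window) periodogram of each
  2 s analysis window, no zero padding, bin frequencies f_k = k·fs/N, and
  half-open band membership low ≤ f_k < high so the four bands tile
  0.5–30 Hz without double-counting; the separate Welch utility (2 s
  Hamming windows) is for cohort spectra, not features.
* Degenerate windows: an all-zero window yields relative power 0 and an
  undefined (NaN) mean frequency; a constant window has undefined fractal
  dimension; a flat in-band spectrum has r² = 1 (a constant line is a
  perfect fit). NaNs from degenerate windows are filled from the nearest
  valid window before classification, and such windows are warned about.
* AUC uses the midrank convention for ties. Cohen's κ is reported with
  the bias index |b−c|/n and prevalence index |a−d|/n from the 2×2 table.
  Event-based coverage pools fragmented detections within one reference
  event and uses a strict inequality (> 75%).
* IBI statistics use complete (non-edge) inter-burst segments only; edge
  segments still count towards the burst-to-inter-burst time ratio.
* Agreement between two binary annotations is summarised as the average
  of the two directed AUCs (each annotation in turn scored against the
  other); this is a convention, as a binary "score" has a single
  operating point.
* Bootstrap CIs are percentile CIs over 1000 resamples with a caller-
  supplied seed; Wilcoxon signed-rank is used for paired comparisons, with
  p = 1 by convention when all differences are zero.

## Synthetic data: what it does and does not model

The generator emulates the statistical structure the detector exploits:

* alternating segments with log-normal durations (median burst 5.7 s,
  median inter-burst 4.1 s, log-space SD 0.75 — right-skewed, strictly
  positive);
* inter-bursts as low-amplitude (10 µV RMS) coloured noise with log–log
  spectral slope −2 (near-linear log–log spectrum);
* bursts as slow activity transients: broadband coloured noise at
  `burst_gain` (default 3×) the floor amplitude, dominated by a delta-band
  (0.5–3 Hz) slow wave (RMS = 1.5 × (gain − 1) × floor) and carrying a
  small nested 3–15 Hz component (10% of the broadband RMS) that bends
  the log–log spectral shape;
* independent per-segment amplitude scaling (log-space SD 0.4) — real
  burst amplitudes vary several-fold, so quiet bursts overlap loud
  inter-bursts and no single amplitude feature is sufficient;
* state-independent broadband sensor/EMG noise (5 µV RMS), which keeps
  the high-band burst contrast modest as in real recordings;
* 0.25 s cross-fades at segment boundaries so discontinuities do not
  trivially cue the detector.

These choices were calibrated once against the qualitative structure of
real preterm cohorts — the 0.5–3 Hz envelope as the best single feature,
frequency-weighted energy second, selected subsets of around 9 features —
and then frozen. Setting `burst_gain = 1` and `burst_bump = 0` disables
every class difference (the slow wave scales with gain − 1), giving a null
construction on which detection must be at chance.

Not modelled: delta brushes and other microstructural graphoelements,
inter-hemispheric asynchrony (the generator is single-channel),
artifacts (movement, electrode pops, ECG), amplitude drift over hours,
and gestational-age dependence. Passing the synthetic experiments
therefore demonstrates that the pipeline recovers the burst structure it
was designed for — not clinical-grade performance on real EEG, which
requires validation against expert annotations.

## Validation experiment sizes

The packaged experiments use a 20-record × 600 s cohort (seeds 0–19) for
the nested cross-validation recovery test and its null counterpart, and a
10-record × 600 s cohort in the results-reproduction script; these sizes
give stable medians while keeping a full run in the minutes range on one
CPU. Simulated annotator pairs (boundary jitter, segment flips) support
the consensus and agreement machinery.

## Known limitations

* The EDF writer emits minimal 16-bit EDF (one 1 s data record per second,
  integer sampling rates, no clinical metadata); reading uses mne.
* The adaptive threshold needs the whole record before deciding, so it is
  unsuitable for streaming use, and it fails by construction on fully
  continuous or fully inactive EEG.
* Inner-loop wrapper selection refits the SVM O(n_filter² × records)
  times; with much larger cohorts the filter stage size or the thinning
  step should be adjusted.
* The mutual-information estimator (equal-frequency binning, 10 bins) is
  biased for very small training sets; with fewer than ~100 thinned rows
  per class the mRMR ranking becomes noisy.
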
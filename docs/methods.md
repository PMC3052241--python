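# Methods

## The analysis in brief

A total-saponin injection is characterized by an HPLC-UV fingerprint at
203 nm containing 27 characteristic peaks between 28 and 75 min. The
package implements the four analytical stages of that workflow —
peak detection, cross-batch common-peak matching with similarity scoring,
calibration-based quantification with substitutive standards, and
ESI-MS^n neutral-loss annotation — together with a synthetic-data
generator that reproduces the statistical structure the stages assume, so
the whole pipeline is testable without instrument data.

## Packaged domain knowledge

The library resource carries the 27 saponins (identity, nominal [M−H]⁻,
retention time, glycan-loss composition, aglycone class) and the ten
linear calibration curves (slope, intercept, linear range, R², LOD) with
the printed peak→curve assignment. All masses are nominal integer Da;
printed fragment tables round inconsistently by ±1 Da, so every mass
comparison uses a ±2 Da tolerance. Two pairs of peaks (m/z 752 at
61.7/62.4 min and m/z 765 at 62.1/62.8 min) are stored as
`unknown-752`/`unknown-765` with no aglycone: their identity is not
resolvable from mass and losses alone, and the package deliberately
preserves that ambiguity, separating the members only by retention order.

Substitutive-standard assignment picks, for an analyte without its own
reference standard, the calibration curve whose standard is nearest in
molecular weight. This rests on the strong negative correlation
(Pearson r ≈ −0.963 over the ten curves) between slope and standard MW:
at 203 nm only the aglycone chromophore absorbs, so the mass response
falls roughly inversely with glycosylation. Exact ties — which occur,
because three standards share MW 783 and two share 945 — are broken by
(1) matching aglycone class when the analyte's aglycone is known,
(2) the lower-MW standard, (3) a packaged surrogate-preference rank that
encodes the published choice of 20(S)-Rg3 as the surrogate of the 783
group. This chain reproduces the printed assignment for all 27 peaks.

## Synthetic chromatograms

Peaks are exponentially modified Gaussians (EMG), the standard model of
tailing reversed-phase peaks; `emg_tau = 0` degenerates to a pure
Gaussian. The profile is parameterized by area and *apex* position (the
mode offset of the EMG is solved numerically once per shape), so detector
tests can assert apex recovery to one sampling interval.

Default study conditions, chosen once as the conditions the analysis
assumes:

| parameter | default | rationale |
|---|---|---|
| contents | per-peak means of the packaged batch table | realistic composition (Rb1 ≈ 28%, Rg1 ≈ 23%, …) |
| nominal_total / dilution_to | 50 / 0.5 mg/ml | label concentration and assay dilution |
| peak σ / τ | 0.04 / 0.03 min | narrowest printed pair is 0.17 min apart and is resolved ("good resolution"); σ = 0.08 would merge it into a shoulder |
| rt_jitter_sd | 0.05 min | shared per-batch retention shift |
| rt_jitter_peak_sd | 0.005 min | independent per-peak scatter; retention drift on one instrument is strongly correlated across peaks, so the shared term dominates |
| area_cv | 0.05 | log-normal between-batch area multiplier |
| noise_sd / baseline_amplitude / solvent_front | 0.5 / 5 / 60 | smallest real peak (height ≈ 33) sits ≈ 22 noise SDs above the floor; the 0–28 min disturbance exercises the window exclusion |
| sampling_interval | 0.01 min | ≈ 4 points per σ; integration error ≪ area_cv |

Noiseless areas are generated by *inverting the calibration lines* at the
configured content levels, which makes end-to-end parameter recovery
exact up to integration error. Four peaks (R4, Rf, Fa, Fc) have printed
content levels that imply *negative* areas on their assigned curves
(large negative intercepts) — an internal inconsistency of the published
tables. The generator clips such areas to a small positive floor
(`area_floor`, default 5 area units, comparable to the smallest real
peak) and records the post-clip area and concentration in the ground
truth, so the truth table always describes the trace actually produced;
`on_nonpositive_area="error"` turns the clip into a hard error naming the
peak. One root seed streams per-batch generators; identical
(config, seed) pairs give bit-identical output.

What the generator does **not** emulate: real mAU magnitudes, gradient-
dependent peak-width evolution, PDA spectra, co-eluting non-saponin
matrix, detector saturation, or retention drift that varies nonlinearly
along the run. Passing tests therefore demonstrate correctness of the
analysis logic under the stated statistical model, not instrument-grade
robustness.

The printed gradient program is carried as metadata
(`gradient_percent_b`), piecewise linear over the printed nodes with
re-equilibration at 19% B after 75 min; it does not drive retention.

## Peak detection

Baseline: grey opening (rolling minimum then maximum) over a 2 min
window, smoothed by a moving average of the same width, then re-centered
by the median residual — the opening rides the noise *floor*, about one
SD below the noise mean, and without re-centering the offset inflates
noise maxima into spurious peaks. Apexes are local maxima of the
baseline-subtracted trace with height and prominence above
`min_height` (default 3 × the robust noise SD, estimated from the median
absolute deviation of first differences) and full width at half
prominence above `min_width` (default 0.03 min — detector noise maxima
are one to a few samples wide). Peak bounds are the valley minima toward
neighbouring apexes (perpendicular drop; no curve deconvolution), or the
decay to the noise floor for outermost peaks; areas are trapezoidal above
baseline, filtered by `min_area`. A peak belongs to the 28–75 min
analysis window iff its apex does.

## Fingerprinting

Common-peak matching chains peak lists across batches: batches are
processed in sorted-id order (permutation invariance); each batch is
first anchored by removing the median retention offset of its peaks
against current cluster centers, then assigned greedily nearest-first
within `rt_tolerance` (default 0.3 min, below half the closest
characteristic-peak spacing after jitter), one peak per batch per
cluster. A cluster is a common peak iff it holds exactly one peak from
every batch; common peaks are numbered by ascending median retention
time.

The reference fingerprint is the pointwise mean (optionally median) of
the resampled traces. Similarity is the congruence (cosine) coefficient
on the raw baseline-subtracted vectors, clipped to [0, 1];
Pearson-on-centered-vectors is available via `metric="pearson"`. Before
averaging and before scoring, each trace may be rigidly shifted by an
integer number of samples (cross-correlation, ≤ 0.3 min) onto the
reference: this removes the shared per-batch retention drift — which
alone would dominate the cosine for peaks this narrow — while remaining
far short of time warping (COW/DTW are out of scope by design). With
alignment disabled the same functions compute the textbook unaligned
cosine.

## Quantification

`concentration_from_area` inverts the calibration line exactly; negative
estimates clip to zero and are flagged, and estimates outside the printed
linear range are flagged rather than censored (the published tables print
contents below some LODs' implied concentrations, so censoring would
discard published behaviour). Content percent uses the *nominal* assay
total (0.5 mg/ml) as denominator — hence batch sums need not equal 100%.
Matched common peaks are mapped to library peak numbers by nearest
retention time after removing the median offset. The summary reports
per-peak ranges across batches and the two published aggregate sums: the
five major saponins (peaks 1, 2, 3, 9, 15) and the ten standard-bearing
saponins (1, 2, 3, 9, 11, 12, 13, 15, 23, 24). LOD *estimation* is not
implemented (no method is published); printed LODs are metadata.

## MS^n annotation

`explain_fragments` enumerates loss ladders depth-first over the residue
alphabet {Hex 162, dHex 146, Pen 132, C5H10 68, H2O 18}, length ≤
`max_losses` (default 6, deep enough for the penta-glycosides), at most
one water loss per ladder (water is a chemically ubiquitous adjunct; more
would explode the search). A ladder is reported when its final prefix sum
matches an observed fragment within tolerance; unmatched intermediate
steps are allowed. Ranking: fragments explained (desc), total |Δm| (asc),
ladder length (asc — parsimony guards against H2O+dHex ≈ Hex mimicry
within the ±2 Da tolerance), then lexicographic for determinism. The
search is provably equivalent to brute-force enumeration on small
instances (oracle test). Library matching requires precursor agreement
within tolerance and containment of the best ladder's residue multiset
(water excluded) in the candidate's glycan composition; isobaric
candidates are ordered by retention proximity when a retention time is
supplied, never by mass.

## Numerical choices and degenerate inputs

- Mass tolerance ±2 Da everywhere (nominal-mass arithmetic).
- Flat traces yield a constant baseline and no peaks; all-zero traces are
  valid input to the baseline but raise on similarity (zero norm).
- `find_peaks` ties at plateau maxima resolve to the left sample.
- Calibration fitting requires ≥ 3 distinct concentrations and a positive
  slope; degenerate designs raise.
- Summaries require a complete 27 × batches matrix and list every missing
  cell in the error.

## Known limitations

- Perpendicular-drop integration biases areas of strongly overlapped
  pairs (the 52.2–52.6 min triplet) by a few percent toward the larger
  peak; deconvolution is out of scope.
- The rigid-shift similarity correction cannot compensate differential
  (peak-dependent) retention drift.
- Semi-quantified contents inherit the surrogate curve's response error;
  the published tables themselves show this can exceed the calibration
  error (four peaks' printed contents are unreachable through their
  assigned curves, see the generator section).
- Annotation assumes [M−H]⁻ precursors only; adducts, isotope patterns
  and linkage positions are out of scope.
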
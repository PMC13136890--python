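# Methods

## Scope and data model

`poremod` operates downstream of basecalling, alignment, and
signal-to-reference alignment. Its inputs are plain tables: per-position
basecall pileup counts (CSV), per-read per-position signal features (TSV:
dwell time, current mean, current SD), modification-call pileups (a minimal
bedMethyl-like dialect), a reference FASTA, and a truth BED of modified
positions. All user-facing coordinates are 1-based inclusive; BED files are
0-based half-open and converted at the boundary. Raw waveform processing,
basecalling, and signal-to-reference alignment themselves are out of scope;
their outputs are the package's inputs.

## Total variation

For a position with base-call counts (A, C, G, U), deletion calls D and
insertion events I, the total variation percentage is
100·(mismatches + D + I) / (A + C + G + U + D + I), where mismatches are all
base calls other than the reference base. Conventions:

* References and calls are normalized to the RNA alphabet (T→U) on ingestion.
* An insertion of any length is one event, anchored to the reference
  position it follows, at most one per read per position. Reported depth
  excludes insertion events (they own no reference position), but the
  denominator includes them, as the formula requires.
* A zero denominator makes the position *undefined* (NaN), never 0%, so
  coverage gaps cannot deflate averages. Undefinedness propagates through
  modified−control deltas and is excluded from every metric.
* The per-type breakdown (four mismatch channels, deletion, insertion)
  shares the denominator, so components sum to the total to ~1e-9.

The BAM/SAM adapter counts via a CIGAR walk, keeping only primary,
mapped alignments with mapping quality ≥ 20 (configurable). A leading
insertion with no preceding aligned reference position has no left anchor
and is not counted.

## Signal preprocessing and energy distance

Reads must cover ≥ 90% of the reference (configurable; the boundary is
inclusive). Dwell is log-transformed (natural log — any base is a uniform
channel rescale). Each channel is then robustly scaled per position:
(x − median)/(1.4826·MAD), with median and MAD pooled over the modified and
control samples *jointly*. Pooling is deliberate: scaling each sample to its
own center would erase exactly the between-sample location shifts the method
is trying to detect. A zero MAD falls back to centering alone and is
reported as a warning flag.

Per center position c (2 ≤ c ≤ L−1), each read covering c−1, c, c+1
contributes the 9-vector (log-dwell, mean, sd) at those three positions; a
read missing any of the three (deletion) is dropped from that window only —
nothing is imputed. The two-sample energy distance

E(X,Y) = 2/(nm)ΣΣ‖xᵢ−yⱼ‖ − 1/n²ΣΣ‖xᵢ−xⱼ‖ − 1/m²ΣΣ‖yᵢ−yⱼ‖

is computed per window as a V-statistic (self-distances included, hence
exactly 0 on identical multisets). It is used as a raw score, not as a
permutation test. Windows with fewer than `min_vectors` (default 10)
vectors on either side are undefined; windows larger than `max_vectors`
(default 1000) are subsampled uniformly without replacement with a
per-position seeded generator, since the computation is quadratic in depth.

A V-statistic subtlety matters for calibration work: under the null its
mean scales as (1/n + 1/m)·E‖X−X′‖, so profiles computed at different
window depths are not distribution-identical even with no effect. The null
calibration test therefore fixes `min_vectors = max_vectors = 70` for both
the modified-vs-control profile and the control split-half profile, making
every defined window exactly 70-vs-70.

## Detection metrics

Truth labels are the exact modified positions; neighbors are negatives.
AUROC uses the mid-rank Mann–Whitney formulation, P(s⁺>s⁻)+½P(tie), which
equals trapezoidal integration of the ROC sweep exactly. AUPRC is step-wise
average precision over distinct score thresholds (no interpolation, which
is known to over-estimate). Confusion matrices use an inclusive threshold
(score ≥ t predicts modified). Because error and signal perturbations smear
over the pore's k-mer footprint, false positives concentrate near true
sites; `proximity_attribution` reports how many false positives lie within
a two-sided window (default ±7 nt) of any true site. This is a post-hoc
explanation device, not label smoothing.

## Modification-call summarization

percent_modified = 100·n_mod/(n_mod + n_canonical): only reads basecalled
as the relevant canonical base enter the ratio; miscalled, deleted, or
filtered reads (n_other) affect neither numerator nor denominator. This is
the single most consequential quantification convention — at error-prone
modified sites the reported percentage describes a minority of reads — and
it is asserted by construction tests. Cumulative curves are running sums of
percent_modified over ascending positions (undefined positions contribute
0), so they are non-decreasing; a near-flat curve is the signature of an
unmodified control.

## Synthetic data generator

The generator emulates the phenomenology the analyses rely on, not the
physics that produces it:

* **Coverage.** Reads are 3′-anchored (sequencing proceeds 3′→5′) and a
  fraction `five_prime_dropout` (default 0.3) is truncated before reaching
  the 5′ end, with geometric truncation depth (mean 15 nt), reproducing the
  5′ coverage decay of real runs. There are no internal gaps other than
  deletions.
* **Errors.** Each covered position draws {correct, mismatch (uniform over
  the three alternatives), deletion} plus an independent insertion event.
  Defaults: background (mismatch .02, deletion .01, insertion .005; total
  ≈3.5%, under the <5% observed background) versus modified sites
  (mismatch .05, deletion .15, insertion .02; total >20%,
  deletion-dominant). Elevation decays linearly to baseline over
  `neighbor_halfwidth` = 3 nt — real data show elevated errors at proximal
  bases without a documented functional form, so the linear ramp is a free
  modeling choice.
* **Signal.** Non-deleted positions emit current mean ~
  Normal(base level + shift·[site], noise_sd), current SD as a positive
  |Normal| draw inflated ×1.5 at sites (only the inflation ratio matters
  downstream, so a Gamma model would be needless complexity), and
  log-normal dwell. The dwell perturbation is applied at site + 10 in
  reference coordinates (clipped at the reference end), reflecting the motor-protein/pore separation; its default magnitude is
  log 2 (a twofold slowdown) — real data show a pronounced dwell peak ~10 nt
  from ribose-modified sites but no published magnitude.
* **Modification calls** derive only from correctly basecalled reads:
  at a true site each such read is called modified with `mod_call_rate`
  (default 0.8, emulating sub-stoichiometric detection), elsewhere with
  `false_mod_rate` (default 0.01).
* **Defaults** otherwise: 120-nt reference (random over {A,C,G,U} from the
  seed unless given explicitly), nine modified sites in three clusters
  (33/35/37, 70/72/74, 107/109/111), 500 reads per sample — a desk-scale
  stand-in for real depths, chosen so the full test suite runs in seconds;
  mean shift 0.75 = 3× the 0.25 noise SD. One integer seed determines every
  draw; identical configurations produce byte-identical fixture files.

What passing tests on this generator do **not** show: robustness to
signal-to-reference misalignment, k-mer-dependent (sequence-context) error
and current structure, correlated errors along a read, carrier/adapter
artifacts, or stoichiometry mixtures — none of these are modeled. Results
on synthetic data certify the statistical machinery, not performance on
any particular chemistry.

## Numerical and design choices

* Energy distances are computed with vectorized pairwise-distance kernels;
  agreement with an explicit double-loop oracle is held to 1e-10.
* Degenerate inputs: single-class truth labels raise an undefined-metric
  error rather than returning 0.5; edge window centers, low-coverage
  windows, and zero-denominator positions carry explicit undefined markers.
* The error-rate triple may sum to exactly 1 (the correct-call remainder is
  then 0), permitting degenerate configurations such as a certain deletion.
* Subsampling, simulation, and profile computation all derive their
  generators from explicit integer seeds; nothing reads global RNG state.
* The pipeline runner writes a manifest with the package version, full
  configuration, and SHA-256 digests of all inputs; plots (depth, ΔTV,
  energy profile, per-channel median ± IQR bands) are artifacts for visual
  inspection, while the CSV/JSON outputs are the tested surfaces.

## Acceptance script problem sizes

`scripts/acceptance.py` uses five replicate simulations at the default
500-read scale for recovery metrics, five 200-read zero-effect replicates
for the null AUROC, one 300-read dwell-only run for the peak-offset
measurement, and one full-U-substitution run (30 modified positions on a
fixed-composition 120-nt reference) for quantification — sizes chosen to
keep the whole script in the seconds range while leaving each estimate's
sampling error well inside the margins it is read against.
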
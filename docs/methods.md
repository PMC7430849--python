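# Methods

This note documents the models and procedures implemented in
`squigalign`, their assumptions, the defaults that matter, and what the
synthetic-data tests do and do not establish.

## Signal model

A nanopore read is a current time series x(t) (pA). While one k-mer
occupies the pore, samples fluctuate around a k-mer-specific level; the
pore model records that level's mean μ(K) and spread σ(K) per k-mer K.
Three distortions separate an observed read from the model:

* **time warp** — the strand translocates at varying speed, so a k-mer
  may emit several events (*stays*) or none (*skips*);
* **per-read affine distortion** — amplifier offset and gain shift and
  scale the whole read's current;
* **noise** — per-event and per-sample Gaussian fluctuation.

All components below are phrased against this generative picture, and
the simulator draws from exactly it, so the aligner is well-specified
for the recovery tests.

## Event detection

Boundaries between events are abrupt level changes. For every boundary
position i the detector computes a two-sample Welch t-statistic between
the w samples left and right of i:

    t(i) = |m_L − m_R| / sqrt(v_L/w + v_R/w)

with *population* (biased) window variances, floored at 1e−9, computed
with prefix sums. Two detectors run in parallel — short window w=3 at
threshold 1.4 (brief events) and long window w=6 at threshold 9.0
(noise robustness). A detector arms when t rises above its threshold,
tracks the running maximum, and emits that maximum's position when t
falls back below threshold; accepted peaks from either detector must be
at least 3 samples apart. Boundaries plus the trace ends partition the
signal; each segment becomes an Event(start, length, mean, stdv).

Notes and limitations:

* The defaults favour recall: at 1 pA sample noise the short detector
  over-segments (≈2–3 detected events per true event is normal).
  Over-segmentation is benign downstream — the DP absorbs extra events
  as stays — whereas a missed boundary merges two pore states.
* A boundary between two *stay* events of the same k-mer is not a level
  change; no change-point method can recover it except through noise.
  The detection benchmarks therefore use stay-free simulations: the
  ground truth of a segmentation test must be identifiable.
* Adding a constant to all samples leaves boundaries unchanged
  (the statistic depends only on differences and variances).

## k-mer encoding and pore models

k-mers are ranked base-4 big-endian (A=0, C=1, G=2, T=3), a bijection
onto [0, 4^k). Models are stored as rank-indexed arrays; k is inferred
from the first table row, duplicate k-mers, mixed lengths and
non-positive stdvs are rejected. k=6 is the supported default (the
R9-class pore reads 5–6 bases at a time); toy models with smaller k are
allowed and used heavily in tests.

The packaged synthetic model (`synthetic_pore_model`) draws level means
uniformly on [60, 130] pA and stdvs on [0.8, 1.4] pA — the span and
per-k-mer spread of real DNA pore tables — deterministically from a
seed. It is a stand-in, not a measured chemistry table: adjacent k-mer
levels are independent, whereas real pore chemistry correlates k-mers
sharing a context. Recovery percentages measured on it do not transfer
verbatim to real data.

## Per-read calibration

`estimate_scalings` matches first and second moments of the observed
event means against the model levels along the read:

    scale = sd(event means) / sd(model levels)
    shift = mean(event means) − scale · mean(model levels)

It is exact on noiseless affinely-transformed data. On noisy data the
scale is inflated by a factor ≈ (1 + σ_n²/(2·scale²·Var(μ))) because
event noise adds variance to the numerator; with ~1 pA noise and this
model's ≈ 450 pA² level variance that is ≈ +0.15%, which propagates to
a shift bias of ≈ −0.15 pA (the mean level is ≈ 95 pA). Drift (pA/s) is
carried in `ScalingParams` for the emission hook but defaults to 0 and
is not estimated; `var` is fixed at 1.

## Emission score

The data term of every DP cell is the Gaussian log density

    ln N(x_i; scale·μ(K_j) + shift [+ drift·t_i], var·σ(K_j))

in natural log. All DP arithmetic is float64 (scores are log-space
sums), regardless of how bands might be stored elsewhere, so banded and
unbanded runs are bit-comparable.

## The banded dynamic program

Cell (i, j) = best log-probability of aligning events 0..i to k-mers
0..j, with moves step (diag, +event +k-mer), stay (up, +event) and skip
(left, +k-mer); skips carry no emission. A virtual origin (−1, −1)
scores 0; virtual trim cells (e, −1) score (e+1)·ln 0.01, so leading
events can be discarded at fixed cost. Ties in the 3-way max break
DIAG > UP > LEFT (prefer progress on both axes); the oracle uses the
same rule so trace-backs are comparable.

Only anti-diagonal bands of width W (default 100) are computed. The
band for anti-diagonal n depends only on bands n−1 and n−2 — a
dependency contract that makes every cell within a band independent;
the implementation vectorises the per-band loop with NumPy. Movement
follows the Suzuki–Kasahara rule: compare the previous band's two end
cells and move toward the better one (RIGHT iff the upper-right end
strictly wins; ties move DOWN; with both ends outside the table the
band alternates by band-index parity, staying near the main diagonal).
Two seed bands place the origin and the first trim cell; a table of
n_events × n_kmers is then covered by n_events + n_kmers − 1
table-proper bands (13 × 6 → b0…b17), n_events + n_kmers + 2 bands in
total including the seeds and the band past the corner.

Trace-back starts at the event row maximising the score in the last
k-mer column over all bands containing that column (earliest row on
exact ties), recording a pair at every visited cell until either index
drops below 0. Starting at the best row rather than strictly at the
bottom-right corner tolerates trailing events (adapter/stall residue)
without forcing them into the alignment; candidate rows are compared on
their raw cell scores, with no extra weighting of the unaligned tail.

Transition defaults derive from the event/k-mer ratio r: p_stay =
1 − 1/(r+1) (so expected events per k-mer matches r), p_skip = 1e−10,
p_step the remainder, trim ln 0.01. All are overridable via
`TransitionParams`.

### QC

An alignment passes QC when the mean emission log density over
event-carrying pairs (reached by step/stay) is ≥ −5.0 and the pair list
spans k-mer 0 through the last k-mer. Misassigned reads fail on the
first condition (a wrong sequence costs several nats per event);
truncated band escapes fail on the second.

## The unbanded oracle

`full_dp_align` materialises the full padded table with the identical
recurrence, penalties and tie-breaks, written independently (scalar
loops, its own inline emission code, no shared inner-loop code with the
banded implementation). Two properties anchor verification:

* **restriction**: banded score ≤ oracle score for every instance and
  any W (the band can only remove paths);
* **equality**: W ≥ n_events + n_kmers ⇒ identical score *and*
  identical pair list.

A guard refuses tables above 10^6 cells — the oracle is a verification
tool, not a production aligner.

## Simulator

`simulate_events` walks the read's k-mers: each is skipped
independently with `skip_prob`; otherwise it emits
G ~ 1 + Geometric(stay_prob) events (mean 1/(1−stay_prob)) with means
drawn N(scale·μ + shift, noise_mult·var·σ). `simulate_raw` expands each
event into max(4, Poisson(samples_per_event_mean)) samples at
N(event mean, sample_noise). Ground truth records every (event, k-mer)
pair, the sample boundaries and the scaling used. All randomness comes
from one integer seed through NumPy's PCG64 generator
(`default_rng`), fixing cross-platform reproducibility.

Defaults state a typical DNA regime: stay_prob 0.5 and skip_prob 0.05
(≈1.9 events per base, matching the ≈2.0 planning heuristic below),
noise_mult 1.0 (≈1 pA event noise under the synthetic model), 15
samples per event, 1 pA sample noise. What the simulator deliberately
omits: realistic pore-noise spectra and autocorrelation, slow current
drift, adapter/stall artefacts, and run-length-correlated skips. A
green recovery test therefore establishes that the aligner inverts the
*stated* generative model, not that it matches field accuracy on real
flowcell data.

## Batch scheduling

Read lengths in nanopore data are heavily skewed; policies here keep
batch processing regular without any hardware assumption:

* **classification** — reads above 30 kb are *very long*, above 100 kb
  *ultra long* (strict inequalities). The 100 kb cut follows the usual
  ultra-long convention; 30 kb is this package's default and both are
  configurable.
* **batch planning** — admit reads in input order while estimated
  band-chain bytes (W · count_bands(ceil(2.0·L), L−k+1) · 9 bytes/cell:
  float64 score + trace tag) fit the budget; a single read exceeding
  the whole budget is admitted alone to the overflow lane. The events
  term uses the average events-per-base heuristic (default 2.0).
* **execution** — `run_batch` aligns each admitted read exactly once,
  records per-read failures without aborting the batch, and guarantees
  results are independent of lane assignment; lanes are a placement
  hint for executors (threads, accelerators), not semantics. The
  bundled executor is sequential.

## Numerical choices

* float64 scores; −inf marks out-of-band/out-of-table cells; variance
  floor 1e−9 in the t-statistic.
* Band-end comparison uses strict `<` so a tie moves DOWN.
* Trace-back row selection uses strict `>` scanning rows upward, so the
  earliest best row wins — identically in both aligners.
* Eventalign TSV floats carry 6 significant digits; coordinates are
  0-based, intervals half-open.

## Known limitations

* Template/forward strand only; reverse-complement handling is the
  caller's job.
* One read per `align`/`simulate` CLI invocation; multi-read batches
  are a library-level feature (`plan_batch`/`run_batch`).
* Event detection parameters are stand-ins tuned for ~15 samples/event
  DNA; RNA and very fast translocation regimes need different windows.
* The moment-matching calibration ignores the known event-noise
  inflation (see above); a de-biased or robust estimator is a possible
  extension but is deliberately kept out of the core contract.
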
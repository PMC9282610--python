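# Methods

This note documents the models, estimators, and numerical conventions
implemented in `phrasal`, the defaults they ship with, and what the
synthetic-data experiments do and do not establish.

## Time-based binding simulation (`phrasal.binding`)

**Model.** Linguistic constituents are represented by the relative timing of
unit activity in a layered network. Four syllable input units (S) fire in
staggered 250-ms windows within every second of a 12-s drive; each second
holds one burst per unit, of duration drawn uniformly from 140–230 ms
(roughly the 4–7 Hz syllable rhythm) at a random onset inside the window.
Firing is binary, Gaussian white noise (SD 0.2 of the burst amplitude, a
configurable calibration) is added, and each sequence is peak-normalized.

Each non-input node applies three steps to the summed activation of its
children, in topological order:

1. *binding* — a causal moving average, y[n] = L⁻¹ Σ_{m=n−L+1}^{n} x[m]
   with zeros before the signal start, window L = 30 ms for a single-child
   (relay) node and 250 ms for a two-child (binding) node. Scaling the
   boxcar by L instead of 1/L only rescales the signal and is equivalent
   after the final normalization;
2. *SNR refinement* — a zero-phase windowed-sinc FIR low-pass
   (order 3·fs/cutoff, applied forward–backward) at 50 / 35 / 20 Hz for
   PO / RB / P nodes;
3. *amplitude normalization* — pointwise division by the sequence maximum
   (skipped for all-zero signals).

**Structures.** The phrase template has one PO binding two syllables
(the disyllabic inflected adjective) and tops out in P(DP); the sentence
template gives every syllable its own PO and embeds P(DP) under the
top-level P(s). The sentence therefore contains more bound (non-input)
units (8 vs. 6). Templates are plain data (JSON-serializable), so
alternative wirings can be swapped in without code changes.

**Readouts** (each per drive pair or randomization, phrase vs. sentence,
paired t with df = n−1):

* *power* — DFT power of each PO unit summed over frequencies in
  (0, 13.5) Hz and over PO units: total network power. Summation (rather
  than averaging) over units is what expresses the model's prediction that
  more active units yield more power; the per-unit average is empirically
  flat between conditions.
* *phase coherence* — per DFT frequency below 13.5 Hz, the resultant
  length across 30 randomly drawn sequences of the unit-normalized
  spectral phasors of a PO unit, averaged over PO units and frequencies;
  100 randomizations per condition. A time-domain variant (resultant of
  pointwise unit-normalized analytic signals across pooled PO sequences)
  was evaluated and rejected: the sentence's four PO timing classes are
  spread evenly over the 1-s cycle, so their instantaneous phases cancel
  and the contrast reverses; the frequency-resolved form measures the
  across-sequence reliability of each unit's spectral phase, which is what
  increases when structures are bound from stereotyped single-syllable
  units.
* *power coupling* — Spearman rank correlation between the PO-layer and
  S-layer band-limited power time-courses (squared Hilbert envelopes in six
  bands below 48 Hz, decimated to ~100 Hz before ranking), averaged over
  bands.
* *phase coupling* — the resultant length over time of the unit-normalized
  PO × child-S cross-spectral density (a phase-locking value), averaged
  over parent–child pairs.

**Expected magnitudes.** With shared drives and the default noise, the
power and coupling contrasts are almost deterministic (the unit-count
difference dominates), so their t statistics are very large (order 10²);
the phase-coherence t is order 10¹. Raising the drive noise SD lowers all
of them roughly in proportion; the direction (sentence > phrase) is stable
in every seed tested for all four readouts.

## Synthetic trial data (`phrasal.synth`)

`gen_trials` plants, per the `GroundTruth` parameters: a stimulus-locked
oscillation whose intertrial phase concentration equals the requested ITPC
(von Mises phases with concentration solved from the target resultant
length via Fisher's piecewise approximation); a post-onset alpha amplitude
change in dB; an amplitude at the PAC carrier frequency modulated by
(1 + m·cos φ_slow); a response equal to a known (channel × band × lag)
kernel convolved with 16-band burst-train stimulus features; per-channel
phase lags on the locked component; and white (optionally 1/f) noise. The
default sampling rate is 256 Hz and the default epoch −1…+2 s around onset
(≥ 800 ms pre-onset baseline is enforced).

`gen_envelopes` emulates syllable-rate speech envelopes: Hann bursts of
140–230 ms, one per syllable window, at 400 Hz, RMS-normalized to −16 dB
full scale. A phrase/sentence pair shares burst onsets, durations, and
amplitudes up to a ±5% jitter, plus a shared smooth (~30 ms) random
amplitude modulation that gives each item bin-level fine structure — without
it, envelope bins within a burst are perfectly correlated across time and
the time-shuffle permutation null degenerates.

What the generators do **not** emulate: eye/muscle artifacts, line noise,
volume conduction, channel covariance structure, spectral tilt of real EEG,
or the phonetic content of real speech. Passing tests on these data show
that the estimators recover what they are defined to measure, not that the
scientific conclusions transfer to any particular recording.

## Time–frequency analysis (`phrasal.tfr`)

Morlet wavelets are evaluated in the frequency domain; each wavelet's
spectrum is peak-normalized so a unit-amplitude sinusoid at a center
frequency yields magnitude 1, making magnitudes comparable across the
bank. Samples within 3 temporal SDs of an epoch edge are flagged invalid
per frequency rather than dropped. ITPC bins where any trial has a
zero-magnitude coefficient are NaN (missing), never 0. Induced power uses
10·log10(power/baseline) per channel and frequency with the −800…−200 ms
baseline; the 10·log10 convention (power ratio) was chosen where the
convention was ambiguous. Frequency tagging concatenates 1-s post-onset
responses into 15-s trials and t-tests the 1 Hz and 4 Hz bins against five
flanking bins per side; epochs are partitioned across long trials when
enough are available, because reusing an epoch inflates integer-Hz bins
(within a trial) and the test statistic (across trials).

## Connectivity (`phrasal.connectivity`)

ISPC is the trial-resultant of unit-normalized cross-spectral phasors;
power connectivity is Spearman across trials with average ranks for ties
(NaN where a channel's power is constant). Thresholding pools BOTH
conditions' pair values per time–frequency bin, takes median + 0.5·SD
(population SD), binarizes at strictly-greater-than (ties fall below), and
reports both global and per-channel degree; percent change uses
100·(x−b)/b with the baseline-mean b (bins with b = 0 are NaN). Degree is
exported both globally and per channel, since either convention may be
wanted for topographies.

## PAC (`phrasal.pac`)

Raw PAC is the mean vector length |⟨a(t)e^{iφ(t)}⟩|; the null circularly
shifts the amplitude series by a uniform random offset ≥ 1 sample
(preserving its distribution exactly) and PAC-Z is the z-score of the
observed value in 1000 such nulls. The threshold is one-tailed
(z = Φ⁻¹(1 − α/n) = 3.73 at α = 0.05 over 11 × 12 × 4 tests). A perfectly
periodic phase series makes every shift reproduce the same coupling; the
degenerate null (SD ≈ 0) is reported as NaN rather than an arbitrary z.
Grid series are taken from the wavelet bank at the nearest center
frequencies over −50…+1500 ms and concatenated across trials.

## STRF (`phrasal.strf`)

Features are 16 log-spaced bands (0.05–8 kHz; 4th-order zero-phase
Butterworth + Hilbert magnitude, polyphase-resampled to the neural rate).
Training pairs are bootstrap concatenations of ten 1-s pairs from a random
80% stimulus split; test pairs concatenate four 1-s pairs from the held-out
20%; responses get 10% linear edge ramps. Ridge regression standardizes
features per band and centers responses per channel on training statistics;
leave-one-pair-out CV over the λ grid uses one eigendecomposition of the
fold's normal matrix so all λ values share it; performance is Pearson r
averaged over channels, then folds. The null pairs a test stimulus with
responses re-concatenated from randomly drawn 1-s responses; above-chance
means exceeding the null's 97.5th percentile. TRF/SRF average the kernel
over 0.1–0.8 kHz bands / 0–400 ms lags (reading the two typographic
impossibilities in the source ranges as 0.8 kHz and 400 ms); peak latencies
are argmax |TRF| in 50–150 and 250–350 ms windows with magnitudes averaged
over ±5 ms; flat windows are flagged degenerate with the tie broken to the
earliest sample. Default lag window 0–500 ms.

## Stimulus statistics (`phrasal.stimstats`)

Envelope similarity compares the two conditions' item vectors per time bin
(cosine, after 50-ms moving-average smoothing); the null shuffles each
condition-B envelope in time independently *before* smoothing and takes the
largest similarity across bins per permutation (max-statistic familywise
control; threshold = 95th percentile). Shuffling after smoothing, or with
one shared permutation, leaves near-identity bins and drives the threshold
to the matched-pair level. The RSM applies the same construction to whole
envelopes.

The spectrum comparison is a BEST-style two-group model per frequency bin
(> 1 Hz) on per-item dB intensities (referenced to the pair maximum):
Student-t likelihood with fixed ν = 30, gamma priors on the condition means
(prior mean = pooled mean, prior SD = 5 × pooled SD, shifted when the pool
extends below zero), 1/σ scale priors, sampled by a vectorized
Metropolis-within-Gibbs (two chains; split-chain R̂ reported; default
10 000 + 2 000 warm-up iterations). The ROPE (±0.1) applies to the
*standardized* mean difference. Note the decision geometry: with n = 50
items per group the posterior SD of the standardized difference is ≈ 0.2,
so a 95% HDI can never fit inside ±0.1 — "equivalence" is reachable only at
much larger n, and matched conditions at realistic n yield "undecided"
(crucially, never "difference"). The tests assert exactly that attainable
behavior.

## Cluster permutation test (`phrasal.cluster`)

Per-bin paired t; entry threshold two-sided p < 0.05; clusters are
sign-split connected components under a combined adjacency (consecutive
time and frequency bins; channel neighbors from a symmetric k-NN graph of
montage positions, default k = 4); cluster mass is the sum of t values; the
null is the maximum |mass| over within-subject condition exchanges (sign
flips); p = (count + 1)/(n_perm + 1), so the attainable floor is
1/(n_perm+1). A constant nonzero difference (SD = 0) is assigned a large
finite t so degenerate-but-real effects still cluster; a constant zero
difference gets t = 0.

## Pipeline (`phrasal.pipeline`)

TOML config with unknown-key rejection; every run writes a provenance
record (config SHA-256 digest, seed, package version). All randomness
derives from one seed via `numpy.random.SeedSequence` spawning one child
stream per stage, so identical config + seed gives byte-identical CSVs.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script run
comfortably on a single CPU: binding contrasts use the full 100-pair /
12-s / 1 kHz configuration (and 20 seeds in the acceptance suite); null
calibrations use 500 replicates with 200–1000 permutations each; the
band-profile STRF experiment uses 30 one-second stimuli at 128 Hz with ten
10-s training pairs. Larger runs only tighten the same estimates.

## Known limitations

* The exact node wiring of the reference phrase/sentence structures is a
  modeling choice; only the relative unit counts are constrained.
* The drive-noise SD is a calibration, not a measured quantity; t-statistic
  magnitudes (not directions) of the binding contrasts scale with it.
* PAC uses the mean-vector-length estimator only; no Tort modulation index
  or GLM-PAC.
* The cluster test assumes exchangeability of paired conditions within
  subject; no TFCE or cluster-size statistics.
* Power connectivity is computed across trials per bin; sliding-window
  within-trial covariation is not implemented.
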
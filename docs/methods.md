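# Methods

This note documents the model and procedure implemented by
`polysorter`, the parameters that matter, the numerical choices made
where the design was genuinely open, what the synthetic generator does
and does not emulate, and the known limitations.

## Signal model and preprocessing

The input is a `channels x samples` voltage matrix in microvolts,
assumed already band-passed to the spike band (0.5-6 kHz) and sampled
at 25 kHz (40 us). Probe geometry (site positions in um, dead-channel
mask) rides along as metadata; the immediate-neighbor set `Z_n` of a
channel contains all live channels within a configurable radius
(default 100 um, which spans adjacent sites including diagonals at
50-75 um pitch). Masked channels are stored as zeros and excluded from
every statistic.

Optional preprocessing: common-average reference (subtracting the
across-channel mean per sample; removes externally coupled noise
common to all channels), temporal smoothing with the (0.25, 0.5, 0.25)
kernel (repetition approximates a Gaussian low-pass), spatial
smoothing with distance-Gaussian weights, and sample-and-hold
correction for the per-channel acquisition delays of multiplexed A-D
boards (up to 31 us across 2 x 32 sequentially sampled channels with
1 us holds). Two choices here were open:

* *Spatial-smoothing normalization.* The distance-Gaussian weights are
  normalized to sum to one over live channels so that a spatially
  uniform signal passes through unchanged; without normalization the
  output scale would depend on local site density.
* *Edges.* Convolution endpoints replicate the first/last sample.
  Zero-padding would synthesize voltage steps at the record ends that
  the detector would then register as events.

Channel noise is estimated per channel as `median(|V|) / 0.6745`
(0.6745 is the 0.75 standard-normal quantile). Unlike the RMS, this is
insensitive to spikes occupying a small fraction of samples: tests
verify < 10% bias with spikes on 1% of samples while the RMS inflates
by > 50%.

## Event detection

A proto-event at `(n, t)` requires `V(n, t)` to strictly exceed
`V(n, t-1)`, `V(n, t+1)` and `V(m, t)` for all `m` in `Z_n`, and to
exceed `theta_e` times the channel noise (mirror rule for minima).
The default `theta_e = 5.0` (typical working range 5-6). Strict
inequalities make exact ties fire at most once; remaining ties are
ordered by time then channel for determinism.

One spike typically yields several proto-events on adjacent channels.
They are coalesced by running the gradient-ascent clusterer on
proto-event coordinates `(x, y, t)`, with the time axis scaled so that
one time scale (default 0.25 ms, about one spike width) equals one
space scale (default 60 um, about one site spacing); the kernel width
equals the space scale. These two scales are package defaults, not
literature values; they are configurable (`det_space_scale_um`,
`det_time_scale_us`). Proto-events separated in time by more than ten
kernel widths are clustered independently — the Gaussian weight across
such a gap is below e^-50, so the partition cannot change, and the
cost drops from quadratic in the night's events to quadratic in a
burst's.

Each resulting cluster becomes one event, taking the time of its
largest-|amplitude| proto-event and the channel nearest the converged
scout position. Events are then aligned to the most negative
interpolated point within +/-0.5 ms on their channel (all-positive
waveforms take the least-positive point and are flagged), and events
whose template window would leave the record are dropped.

## Interpolation and event-time bookkeeping

Sub-sample values are computed by windowed-sinc interpolation over
+/-6 sample points on a 1/10-sample grid (4 us). A Blackman window
with normalized weights suppresses the truncation ripple of the bare
sinc: on a 1 kHz sinusoid sampled at 25 kHz the interpolation error is
~0.01% of amplitude (bare truncated sinc: ~5%). Event times are kept
as an integer sample index plus a fractional offset in [0, 1), so the
reconstruction `t_i + delta_i` is exact at any recording length and
survives arbitrarily many realignments.

## Templates, channel assignment, alignment

A cluster's template is the mean interpolated waveform of its events
over `tau` in [-10, +15] samples (-0.4 to +0.6 ms; 26 samples per
channel), with per-sample SD computed alongside; clusters above 1000
events use a seeded 1000-event subsample. The center channel carries
the largest peak-to-peak voltage `V_pp`; a candidate channel (center or
immediate neighbor) is assigned if its `V_pp` is at least 0.2 times the
center's and exceeds twice the center-channel template SD (the
per-sample SD averaged over `tau` — the scalar "template SD on the
center channel"). The template's spatial center is the V_pp-weighted
mean site position.

Three alignments are used:

* *Event-based* (after detection): to the negative trough, as above.
* *Least-squares to the template*: each event's offset `tau_min` in
  [-5, +5] samples (0.1-sample grid, matching the interpolation
  resolution) minimizes the squared difference to the template over
  the assigned channels; `tau_min` is **added** to the event time.
  Offsets at the search-range extremes flag the event as noisy or
  spuriously shaped (they are kept by default; `remove_flagged=True`
  drops them). Two realignment rounds are run per template update;
  further rounds change alignments negligibly.
* *Template-mean*: all of a cluster's event times are shifted by the
  second-derivative-weighted mean time of the template,
  `tau_bar = sum(tau |d2T|) / sum(|d2T|)`, computed over the full
  +/-1.5 ms window (tau_0 = 38 samples). This measure moves linearly
  with small waveform shifts, unlike alignment to a peak or trough,
  which can jump between two near-equal lobes and split one unit into
  two differently-aligned clusters.

Three numerical refinements to the template-mean alignment were
necessary and are deliberate design choices:

1. The wide-window template is evaluated *directly from the events*
   rather than by zero-padding the stored 26-sample template: padding
   creates large artificial curvature at the junction whenever the
   waveform has not decayed at the window edge, and mass outside the
   stored window is invisible, so the alignment never converges.
2. The second difference (one-sample lag) is evaluated on the
   interpolated 0.2-sample grid. Sampled only at integers, the
   curvature weight of a trough 2-3 samples wide aliases with its grid
   phase and the fixed point becomes bistable (clusters oscillate
   between two centers half a sample apart).
3. Weights are soft-thresholded at three times the template noise
   floor (estimated from the median |d2T|, since the spike occupies a
   minority of the window). The noise floor otherwise carries 30-40%
   of the total weight with a random centroid, shifting each cluster's
   center by up to a sample in a cluster-specific direction.
   The shift is iterated to its fixed point (|tau_bar| < 0.02, at most
   12 rounds) because each single estimate is still diluted by
   residual noise weight.

## Features

For each event a data vector is built from the voltages at up to
M = 100 (channel, tau) coordinates, chosen by ranking the across-event
variance at every coordinate on the assigned channels (ties break
lexicographically; degenerate all-identical input falls back to all
coordinates). Vectors are mean-centered, the M x M covariance is
eigendecomposed, and scores are projections on the top eigenvectors
(2 components for pair-overlap tests, 3 for splitting). Centering is a
deliberate choice — the projections are taken about the cloud's mean —
and eigenvector signs are fixed by making each column's
largest-magnitude loading positive, so runs are exactly reproducible.
Because the vectors are raw voltages, scores carry the microvolt
scale, which is what makes the clustering kernel width meaningful in
microvolts.

## Gradient-ascent clustering

Every data point spawns a scout at its own position. Each iteration
moves every scout up the kernel density gradient of the *fixed* data
cloud (the mean-shift update), then merges any scout pair within
`eps = sigma_m` of each other, deleting the higher-indexed scout and
transferring its labels (merge scans run in ascending index order for
determinism). A scout is stationary once it has moved less than 0.001
(microvolts, the units of feature space) for 25 successive iterations;
the run ends when all scouts are stationary. Scouts that have already
satisfied the criterion are frozen — the density field is fixed, so
they cannot un-converge — which cuts the cost of the long convergence
tail. For N above 5000 the density sum uses every m-th point
(`m = N // 5000 + 1`); scouts always start from every point.

The bandwidth sweep runs the clusterer at `sigma_1 = 5 uV` growing 10%
per step until a single cluster remains. Sub-clusters are tracked
across consecutive widths: same sub-cluster if the size changed by
less than `theta_N = 5%` and the position (member mean) moved by less
than `0.14 sigma_m`; ambiguous matches resolve to the nearest
position. The stability score `S` of a sub-cluster is the number of
sweep rows its track spans. If no track of a sub-cluster at least
`N_min = 50` strong reaches `theta_c = 8`, the cluster is
unsplittable. (Restricting candidates to `N_min`-sized sub-clusters is
load-bearing: an isolated outlier point is trivially "stable" — size 1
and position fixed — and would otherwise outscore every real
sub-cluster.) Otherwise the highest-S track (ties to the larger
sub-cluster) is split off using the partition at the midpoint row of
its stable range, and sub-clusters below `N_min` at that row have
their events deleted. Splitting strategy alternatives
(max-summed-score, max-count) are accepted in configuration but not
implemented.

Channel-cluster splitting then recurses: features -> sweep -> decide ->
split -> re-template, realign and re-derive features on both fragments
-> repeat until every surviving cluster is unsplittable. Removing a
dominant sub-cluster often reveals new structure in the fresh
projection of the remainder. Two open details were decided here:
scouts merge after each movement step (not before the stationarity
check), and a split whose "fragment" is the entire cluster is treated
as unsplittable to guarantee termination.

## Pairwise stage

Templates are compared only for spatially overlapping pairs: at least
half of either template's channel set must be shared (a two-channel
template overlaps anything sharing one channel; a three-channel
template does not overlap on one shared channel of three).

`q` is the RMS voltage difference over the union channel set, with
channels absent from one template contributing zeros (an absent
channel means sub-threshold signal there). The overlap index `o`
temporarily merges the pair, recomputes a joint template, least-squares
realigns all events to it, projects onto the first two common PCs, and
counts, for the smaller cluster, the fraction `p_k` of its points
whose nearest neighbor (self excluded, Euclidean) is a same-origin
point: `o = (1 - p_k) / (1 - e)`, `e = N_k / (N_k + N_l)` computed on
the subsampled counts. Pairs larger than 2000 points are subsampled in
equal fractions (minimum 2 per cluster) with the pipeline seed.

A pair is *distinct* — test DT — if any of: channel sets barely
overlap; `q > 25 uV`; `o < 0.05`; or the user declared it distinct. A
cluster is distinct only if DT holds against all other clusters.

The automated merge stage iterates three rules until quiescent,
refreshing every measure involving a changed cluster:

1. *Merge*: aligned RMS difference `< 5 uV` and `o > 0.9`. The RMS for
   this rule (`q_aligned`) is computed between the pair's mean
   waveforms *after* the common realignment performed for `o`, because
   each cluster's own template-mean alignment retains an independent
   ~0.1-sample registration offset whose RMS cost alone approaches
   5 uV for sharp, large spikes; `q` proper (own alignment) still
   drives DT rule 2.
2. *Recombine-split* for `0.05 <= o < 0.15`: the combined events get
   the stability split test; if splittable, events are reassigned
   between the two original ids (points in below-minimum sub-clusters
   are deleted — this is the outlier rejection); if unclusterable, the
   originals are restored and the pair stays ambiguous. Each pair is
   tested at most once per outer loop, guaranteeing termination.
3. *Over-divided unit*: a pair still ambiguous with `o >= 0.15` and
   `q_aligned < 5 uV` gets the same combined test, but an unclusterable
   combination now means one over-divided unit and the pair is merged.
   This automates the judgment an interactive reviewer would otherwise
   make from the combined cPC plot; the interactive stage itself is
   replaced by a declarative decision file (actions `merge`,
   `merge-and-split`, `declare-distinct`, `leave` per pair).

Clusters still below `N_min` after merging are deleted. The final
report gives detected events, cluster counts before and after the
pairwise stage, pairs examined (`n(n-1)/2`; 4950 for 100 clusters) and
the percentage of detected events carrying a final label.

## Synthetic recordings

The generator emulates the recording regime the sorter targets: 25 kHz
sampling, linear / 2-column / 3-column probes at 50-75 um pitch, spike
waveforms as smooth Gaussian-lobe sums classified by extremum sign
order ([-, +], [+, -], [+, -, +], [-, +, -], [-], [+]; archetypes
A-F), Gaussian spatial amplitude decay (default length 50 um, which
reproduces the typical 3-8 assigned channels per template), Poisson
firing with a 2 ms refractory period, white Gaussian noise (default
15 uV; an optional common-mode component exercises the common-average
reference), and optional smooth or step amplitude drift. Waveforms are
continuous functions, so spikes are planted at fractional sample times
and the exact per-channel template is known. Same seed, same
recording, bit for bit.

Defaults were chosen once as realistic study conditions: 4 Hz mean
rates (20 Hz is high for cortex), amplitudes 150-300 uV over 15 uV
noise (SNR 10-20). The standard parameter-recovery benchmark places
K in {2, 5, 10} units evenly along a 16-site linear shank (pairwise
separations >= 100 um) for 120 s — problem sizes picked so the full
pipeline runs in minutes on one core while every stage (fragmentation
across channels, splitting, merging) is exercised.

What the generator does **not** emulate: bursting amplitude
attenuation, electrode drift in space (only amplitude drift),
correlated firing, biophysically detailed waveform diversity within a
unit, and temporally overlapping spikes beyond what independent
Poisson trains produce. Passing the recovery tests therefore shows the
pipeline's machinery is correct under its own assumptions, not that it
will match curated performance on real tissue.

Expected coincidence losses are provided analytically (fraction =
rate x window; 2% for 20 Hz and 1 ms) and by Monte-Carlo with two
independent Poisson trains, including the central-correlogram-bin
variant (window / bin; 10% for 1 ms in 10 ms).

## Limitations

* Temporally overlapping spikes (< ~1 ms apart, < ~100 um) are not
  resolved; they typically end up as outliers and are deleted.
* The event detector's space-time kernel scales are package defaults;
  quantitative detector benchmarking is out of scope.
* Only the best-score split strategy is implemented.
* The sorter processes one continuous record; multi-file recordings
  are out of scope.
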
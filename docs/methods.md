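# Methods

`spatiodyn` analyses the spatiotemporal dynamics of resting-state brain
activity summarised as intrinsic connectivity network (ICN) time courses:
a `T x N` matrix (timepoints x networks, sampling interval TR, here 3 s)
per cohort, with an atlas assigning each of the 105 ICNs to one of 14
subdomains and 7 functional domains (cerebellar CB, visual VI, paralimbic
PL, subcortical SC, sensorimotor SM, higher cognition HC, triple network
TN). Because the source cohort data are access-controlled, the package
ships a synthetic generator with planted ground truth; everything
downstream is validated against what was planted.

## Preprocessing

The canonical chain is band-pass -> global signal regression (GSR) ->
z-scoring, each step recording a flag on the series (re-running a flagged
step is a warned no-op).

- **Band-pass** 0.01–0.15 Hz, zero-phase (forward–backward Butterworth,
  order 2 per pass). Zero-phase filtering matters: a causal filter would
  imprint its own phase gradient on the cPCA phase-delay maps.
- **GSR** removes the demeaned across-ICN mean signal from each column by
  least squares; column means are preserved so an input already orthogonal
  to its global mean passes through unchanged. Note that GSR output has an
  identically zero global mean (the mean regression coefficient is 1), so
  re-regressing is a warned no-op, not an error.
- **z-scoring** standardises columns to mean 0, sample SD 1 (ddof = 1).

The ordering of band-pass vs GSR is a package decision (the two nearly
commute on band-limited data); it is applied consistently everywhere.

## Synthetic data

`generate_background` draws independent Gaussian noise per ICN, band-passes
it to the infraslow range, rescales to unit SD, and adds a shared
band-limited global signal: `x = noise_sd * n_i(t) + global_signal_weight *
g(t)`. `plant_qpp` adds copies of an `N x W` template at quasi-periodic
starts (renewal process: gap = `mean_interval_tr` ± uniform jitter, floored
at `W`), each ICN row scaled by a non-negative `amplitude_map`. Injection
is purely additive, so `output − input` equals the scheduled copies
exactly, and the `PlantedGroundTruth` records template, starts, amplitudes
and lags. `make_traveling_wave` produces `cos(2π f t − m·Δ)` per ICN `m`, a
linear phase gradient for validating phase-delay estimation.

The planted *domain template* used in cohort experiments gives every ICN of
a domain a shared one-cycle cosine waveform under a Hann envelope, with the
domain phase traveling across domains (2πd/7) and a small idiosyncratic
per-ICN component (SD 0.15 before row standardisation). The envelope makes
the pattern a transient event with an onset and an offset, as empirical
recurrent patterns are; a pure cosine cycle is circularly symmetric (a
half-cycle shift equals its own negation), which leaves the detected
temporal phase unidentifiable and invites degenerate period-halved
solutions.

What the generator does **not** emulate: hemodynamic response shapes, 1/f
background spectra, spatial (voxel-level) structure, motion or
physiological artifacts, subject-level heterogeneity (each cohort is one
long session-concatenated series). Passing tests therefore demonstrate the
correctness and calibration of the *algorithms* under controlled
conditions, not performance on empirical fMRI.

## QPP detection

The quasi-periodic pattern (QPP) is extracted by a seed-free iterative
sliding-template algorithm. The template spans a 24 s window (`W = 8`
frames at TR = 3 s), roughly one infraslow cycle. From a randomly chosen
data segment, the algorithm alternates:

1. **Sliding correlation**: flattened `N·W` Pearson correlation of the
   template with every window of the series (the template is treated as a
   single spatiotemporal object). Zero-variance windows yield 0, not NaN.
2. **Peak picking**: local maxima strictly above a threshold (0.1 for the
   first three iterations, 0.2 after — the conventional values), kept
   greedily in descending height with a minimum separation of one full
   window `W`. Separation below `W` admits the shoulder maxima of a single
   event's correlation bump as duplicate occurrences.
3. **Refinement**: the template becomes the element-wise mean of the data
   segments at the kept peaks.

Iteration stops when successive correlation traces correlate above
`1 − 1e-4` (or after 20 iterations). Twenty random starts are tried; the
winner maximises the *match energy* (sum of squared suprathreshold peak
heights). Energy rather than a plain sum is essential: a period-halved
degenerate solution — the true template diluted 1:1 with background, which
matches both at the true occurrences and midway between them — doubles its
peak count at just over half the peak height and would win a linear-sum
contest.

A final **phase refinement** scans all `2W−1` offsets of the winning
occurrence set, re-extracts the template at each, and keeps the offset
with maximal match energy. The iteration itself is stable at whatever
window offset the initial segment happened to have (an offset template
matches itself at the offset position at every occurrence), so without
this step roughly half of all runs return a template one frame off the
event start, with the offset frame holding averaged background.

The returned pattern is always the mean of the data segments at the
reported occurrences. Detection operates per cohort on concatenated
sessions; windows straddling a session boundary can be excluded via
`session_boundaries`.

## Complex PCA

Each (zero-mean) ICN time course is lifted to its analytic signal
`z(t) = x(t) + i·H(x(t))`; the complex correlation matrix
`R_ij = (1/T) Σ_t z_i(t) conj(z_j(t))` is Hermitian positive semidefinite.
Its eigendecomposition gives complex loadings `u_k` (unit norm, descending
eigenvalue) and component time courses `a_k(t) = u_k^H z(t)`. The leading
component's modulus `|u_1|` is the amplitude map and `arg(u_1)` the phase
map.

Conventions, fixed and tested:

- **Global phase** of each eigenvector is arbitrary; it is fixed by
  rotating so the amplitude-weighted circular mean phase is zero
  (`φ* = arg Σ_m u_m`).
- **Phase sign**: with `a_k = u_k^H z` and positive-frequency analytic
  signals, rank-1 data evolve as `Re(u·e^{iωt})`; an ICN that peaks later
  (lags) carries a more *negative* `arg(u_1)`. The phase-*delay* map is
  `−arg(u_1)`. On a traveling wave with step Δ, the unwrapped phase map is
  linear with slope `−Δ`.
- **Reconstruction**: `reconstruct_pattern` renders one forward cycle,
  column `w = Re(u_1 · e^{+i·2πw/W})`, directly comparable to a QPP
  template; a loading phase of +π/2 peaks a quarter-cycle earlier.
- **Edge exclusion**: the first and last 8 frames (one window) are dropped
  from R's time average by default to suppress Hilbert-transform ringing.
- **Normalisation**: reported R matrices are coherence-scaled (unit
  diagonal), making `|R_ij|` interpretable in [0, 1]. On z-scored inputs
  this is a small correction. Amplitude-faithful loadings (e.g. for
  reconstructing a rank-1 signal with heterogeneous amplitudes) use
  `normalize=False`.

## Template integrity and engagement

For cohort templates `Q_i` (`N x W`), `C_ii` and `C_ij` hold the Pearson
correlations between ICN time courses within the template window (rows of
`Q_i` vs rows of `Q_j`). The integrity delta `ΔC_ij = C_ii − C_ij`
measures departure from the reference cohort's pattern; degraded networks
show predominantly positive deltas. No Fisher z-transform is applied (a
`z`-mode exists but is off by default; note the rank-based group tests are
invariant to it anyway).

Templates are defined only up to circular shift and sign.
`align_templates` finds the best `(shift, sign)` by exhaustive search
under flattened Pearson correlation (ties: smallest shift, then positive
sign). For *cross-cohort* matrices the pipeline goes one step further:
rolling an 8-frame window wraps junk frames (one wrapped frame costs about
0.1 in 8-point row correlations), so the comparison template is
re-extracted from its own data at the shift-corrected occurrence starts
(`phase_locked_template`), keeping every frame a genuine sample.

cPCA engagement indices are `l = |u_1|` per ICN, averaged within each
atlas domain (`L(d)`). The cPCA route to correlation matrices reuses
`template_corr` on `reconstruct_pattern` output, so QPP- and cPCA-derived
patterns enter the statistics through one code path.

## Group statistics

Inference is at the network level: for each functional domain, the
within-domain ICN-pair values (upper triangle, `k(k−1)/2` observations)
of each cohort's **own** template correlation matrix form one group.
Self-correlation values are invariant to the template's arbitrary phase,
which makes the groups directly comparable; pairing a self matrix against
a cross matrix instead would bake in an optimistic bias for the reference
(its template shares occurrence-timing noise with itself).

Per domain, a tie-corrected Kruskal–Wallis omnibus test (χ²
approximation, df = groups − 1; the all-values-identical case is defined
as H = 0, p = 1) is followed — only where the omnibus is significant at
α = 0.05 — by Dunn's pairwise z tests on the pooled tie-corrected ranks
with Bonferroni correction. The Bonferroni family is the pairs within one
domain by default; a global (pairs × domains) family is available, since
the correction scope is a genuine modelling choice. Two-sided tests
throughout. For two groups, Dunn's z is algebraically identical to the
tie-corrected rank-sum normal approximation, which the tests exploit as
an independent oracle.

**Known limitation**: ICN pairs within a domain share rows, so they are
not independent observations; the Kruskal–Wallis test is therefore mildly
anticonservative at the domain level (in the 50%-attenuation experiment,
unperturbed domains flag at roughly 2–3× the nominal α). This is intrinsic
to network-level pair-as-observation inference, not an implementation
artifact; domain-level flags should be read with that in mind.

## The degradation experiment

The canned experiment (`spatiodyn.experiments.attenuation_experiment`)
plants the same domain template in two cohorts (T = 800 TRs, TR = 3 s,
background noise SD 1.0 — pattern amplitude comparable to background —
mean interval 26 TRs, jitter 3), halves the planted amplitude of one
domain's ICNs (default PL) in the comparison cohort, z-scores, detects one
template per cohort (10 random starts), and compares within-domain
self-correlation values per domain. A 50% amplitude loss is visible in the
template correlations through the doubled residual noise-to-signal ratio
of the attenuated rows (the detected template averages ~30 occurrences;
in the infinite-data limit a pure rescaling would be invisible to
correlations). Across seeds 0–19 the perturbed domain is flagged in 18/20
runs and its mean within-domain delta exceeds the unperturbed domains' in
19/20 (one-sided sign test p < 0.05). Problem sizes here (T = 800, 10
starts, 20 seeds) were chosen to keep the full validation suite fast
while leaving the planted effect several times its estimation noise.

## Cohort accounting

`cohort_scan_hours` derives total scan time as `timepoints × TR / 3600`,
reported at full precision and rounded to 2 decimals. For the published
per-cohort TR counts at TR = 3 s this reproduces the printed scan-hour
figures (e.g. 140 114 TRs -> 116.76 h); the one published row that implies
4.68 h where uniform TR = 3 s gives 4.69 h is reported as computed, not
reconciled.

## Bundled atlas

The exact ICN-to-subdomain assignment of the 105-ICN parcellation is not
published as a table; the bundled default atlas is a synthetic stand-in
using contiguous index ranges consistent with the published counts (105
ICNs, 14 subdomains, 7 domains) and with the ICN numbering used in the
associated result tables. Any real assignment can be supplied as a
three-column TSV (`icn_id`, `subdomain`, `domain`).

## Numerical choices

- Correlations are clipped to [−1, 1] after computation; zero-variance
  rows/windows produce 0 entries with a logged warning.
- Eigendecomposition uses `scipy.linalg.eigh` on the explicitly
  Hermitian-symmetrised R; eigenvalues are floored at 0.
- All stochastic operations take an explicit integer seed; pipeline
  sub-seeds derive from a `SeedSequence` spawn of the master seed. Reruns
  with the same config and seed are byte-identical, verified per output
  file by SHA-256 in the results manifest.
- TSV is the only on-disk format (1-based ICN ids in headers; 0-based
  timepoint indices in occurrence files, stated in their headers).
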
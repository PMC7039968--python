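# Methods

## Stereotypy metrics

Both metrics operate on a `ResponseTable`: a finite real matrix of
trial-averaged responses, rows = individuals, columns = odors, at least
2 × 2 for any pairwise analysis.

**PRED.** For one pair of individuals (responses *a*, *b*) and one pair
of odors (1, 2), D1 sums the two same-odor squared differences and D2 the
two cross-odor ones; PRED = (D2 − D1)/(D2 + D1). D1 and D2 each sum over
both of their squared differences (the ratio is identical under averaging
instead of summing). Algebraically D2 − D1 = 2(a1 − a2)(b1 − b2), so the
sign of PRED is the sign of the product of the two individuals' odor
contrasts, and PRED is invariant to adding a common constant to all four
responses and to scaling all four by a nonzero constant. When D1 + D2 = 0
(all four responses equal) PRED is defined as 0; numerically the
denominator is treated as zero when it falls below 1e−12 times the
largest squared term, to avoid 0/0 from rounding. Table-level PRED is
the plain mean over all C(I,2)·C(O,2) pair values.

**Correlation.** Pearson r between two individuals' odor response
vectors, averaged over individual pairs. A pair in which either vector is
constant has an undefined correlation; such pairs are excluded from the
mean and counted, never coerced to 0. A table whose pairs are all
undefined reports NaN with a flag.

**Grouping.** `grouped_pred` splits the PRED pair values by whether the
two odors share a user-supplied group label (e.g. a concentration level)
and reports within-/across-group means with counts. Groups contributing
no within pairs simply yield empty within sets, not errors.

**Significance.** Means are compared to the chance level 0 with a
two-tailed one-sample t-test; a zero-variance input is an error that
points the user to the permutation test. `permutation_null` builds a null
by independently permuting each individual's odor labels (permutations
resampled with replacement) and recomputing the mean PRED; the one-sided
p-value uses the +1 small-sample correction, p = (1 + #{null ≥
observed})/(n + 1). The resampling scheme is a documented design choice;
with few odors the null has atoms (including the perfect realignment), so
small tables cannot reach arbitrarily small p.

## Circuit model

Defaults (the reference conditions): 50 PNs, 2000 KCs, PN-KC connection
probability 0.14 (i.i.d. Bernoulli per entry, not fixed in-degree; mean
KC in-degree 7), KC threshold t = 119, MBON connected to the first 1000
KCs (identical across individuals), PN response probability 0.5 per odor,
responder spike counts uniform **integers** on [10, 30] inclusive (mean
20, matching the stated mean of the 10–30 range), non-responders exactly
0. PN response matrices vary with odor but are shared across individuals;
connection matrices vary with the individual but not the odor.

KC input is the summed spike count of connected PNs; responses use the
rectifier f(k) = max(0, k − t). The MBON applies the same rectifier to
the sum of its connected KCs' responses, with its threshold defaulting to
the KC threshold (`mbon_threshold` overrides it; 0 gives a plain-sum
readout). At default convergence the MBON input (~10⁴) is far above
threshold, so the readout is a constant shift and — because PRED and
Pearson r are shift-invariant — default-network stereotypy is unchanged
by the choice; the threshold matters at low convergence, where small MBON
inputs are clipped to zero and stereotypy drops, which is what gives the
convergence × randomness grid its shape (below).

**Randomness fraction.** Individual 2's matrix is a copy of individual
1's with each entry independently *redrawn* (fresh Bernoulli(0.14)) with
probability `randomness_fraction` f — an i.i.d. per-entry mask rather
than an exact-count draw, so the expected fraction of independently set
synapses is f, f = 0 gives identical wiring and f = 1 fully independent
wiring.

**Noise.** The optional control adds Gaussian noise (sd `noise_sd`) to
each KC's summed input, independently per KC, odor and individual,
truncated so inputs stay non-negative. The placement (on summed input) is
a documented choice; it is exposed as a single parameter and off by
default.

**Linear transfer.** For the fixed-drive experiments a linear KC transfer
y = m·k − t (no rectification, negative responses kept) is available; m
is calibrated per iteration so the grand-mean total linear KC response
over all (odor, individual) cases equals the rectified model's grand mean
on the same inputs — a closed-form one-parameter match.

**Seeding.** Every runner takes one master seed and derives one child
generator per iteration via `numpy.random.SeedSequence(seed).spawn`, so
runs are bit-reproducible and any iteration can be regenerated alone.

## Experiments

`run_simulation` draws fresh odors and wiring per iteration and scores
both metrics on the MBON response, total KC response and total KC input,
plus per-KC metrics restricted to KCs that responded to at least one odor
in both individuals (for two-individual runs). The pooled per-KC mean
weights every qualifying KC equally across iterations. Controls:
`identical_connectivity` forces f = 0 (positive control — stereotypy is
exactly 1 without noise); `nonstereotypic_pns` draws an independent PN
response set per individual (negative control — stereotypy vanishes).
`normalize_mbon_weights` mean-subtracts the 0/1 KC→MBON weight vector
over all KCs before the readout, the weight normalization that collapses
readout stereotypy.

`run_learning`: per individual a random half of the odor panel is learned
sequentially; each event, with probability 1/2, connects or disconnects a
fraction `learning_rate` of the KCs activated by that odor that are
currently unconnected/connected to the MBON. Counts round to the nearest
integer; the eligible subset is taken from a full random permutation so
the random stream advances identically for every learning rate (paired
seeds stay comparable). Events apply strictly sequentially against the
current connectivity; MBON responses are recomputed afterwards.

`run_fixed_drive`: the total PN spike count is pinned to mean rate ×
(response probability × n_pns) = 500 and split over the active PNs by a
sequential bounded partition — part j is drawn uniformly from the
interval that keeps the remainder feasible, and the parts are permuted to
remove order bias; infeasible settings fail before sampling. The *base*
variant fixes 25 active PNs and the default [10, 30] range for both
odors, the fully matched condition in which stereotypy vanishes. (Letting
the active count vary binomially between odors reintroduces an
active-PN-count difference and with it strong stereotypy, so it is not a
null baseline.) Other variants change the range or the active count for
one or both odors, route through the calibrated linear transfer, or build
odor 2 by permuting odor 1's PN labels (`shuffled_labels`).

`run_parameter_sweep` reruns the simulation (two odors, two individuals
in the standard configuration) across values of one parameter — PN mean
rate (range mean ± 10), KC count, connection probability, KC threshold,
PN count, PN response probability — reporting stereotypy alongside the
mean active-KC count and mean active-KC rate. `drive_difference_analysis`
correlates per-iteration PRED with the absolute difference in total PN
output between the two odors; a constant drive difference yields an
undefined (NaN) correlation rather than a silent 0.

`run_convergence_randomness_grid` evaluates mean MBON PRED on a log grid
(default 21 × 21 on [0.01, 1]) of convergence c (Bernoulli KC→MBON mask,
shared across individuals) × randomness f, two odors and two individuals
per iteration, batching all iterations of a grid point through float32
matrix products (spike sums are small integers, so float32 is exact).
`fit_hill` fits S = r^a/(b + r^a) to the 441 (c/f, mean PRED) points by
nonlinear least squares (initial guess a = b = 1, bounds a ∈ (0, 10],
b ∈ (0, 100], tolerances 1e−10) and reports R² on the fitted points;
points with equal ratios are not pre-averaged. Constant stereotypy gives
a flagged degenerate fit with R² = 0.

## Analytical binary model

Binary PN patterns (each PN active with probability p), binary
per-individual connection matrices (entry probability c), KC active when
its count of active connected PNs reaches an integer threshold θ;
the population response is the active-KC count. The default θ is the
smallest integer keeping the expected active fraction at or below 12 %
(θ = 7 at the fly-like defaults, ≈ 5.8 % active).

The exact route factorizes the expectation: (i) the two odor patterns
enter only through (w1, w2, m) — the active counts and their overlap —
with a multinomial law over PNs (hypergeometric overlap in shuffled
mode); (ii) given the triple, one KC's joint activation for the two odors
follows from independent binomial counts of connected-active PNs on the
overlap and the exclusive sets; (iii) the joint pmf of the two response
counts is the n_kcs-fold convolution of that per-KC 2 × 2 law (a dynamic
program on the count grid); (iv) E[PRED] is the exact average of the
ratio over the two individuals' independent response pairs. Enumeration
is limited to n_pns ≤ 12 and n_kcs ≤ 64; larger instances are directed to
the Monte-Carlo estimator, which simulates (odor pair, individual pair)
tuples in float32 batches and returns the mean with its standard error.
In shuffled mode the enumeration gives exactly 0, matching the intuition
that label-shuffled odors carry no population-level signature.

## Problem sizes and what the tests show

The test suite and the acceptance script use the reference sizes (100
network iterations; the full 21 × 21 grid) for the headline quantities
and smaller panels (2–30 iterations, reduced networks) for structural
checks; the methods are O(iterations), so results at larger sizes differ
only in Monte-Carlo error. The synthetic generator reproduces the
idealized study conditions — perfectly stereotyped PN responses, exactly
random wiring, no trial-to-trial variability — so passing tests show the
circuit-level mechanism, not the noise floor of real recordings;
experimentally measured stereotypy is lower (the `noise_sd` control
illustrates the direction of that effect).

## Known limitations

- No membrane dynamics, spike timing or explicit inhibition; inhibitory
  effects are folded into firing rates and thresholds.
- Multi-trial variance is out of scope: table inputs are trial-averaged
  scalars.
- The permutation-null scheme and the noise placement are choices the
  data they emulate do not pin down; both are documented above and
  swappable.
- The binary model's printed expectation depends on θ, which is set by
  the sparseness rule rather than by an external reference.
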
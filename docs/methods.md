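# Methods

This note records the models, algorithms, parameter choices and known
limitations of the package, in the order of the processing chain.

## Maximum-entropy texture ensembles

A texture ensemble is defined by a *glider* — a set of lattice offsets with
a target parity — and is the uniform (maximum-entropy) distribution over
binary boards (white = +1, black = −1) in which the product of check values
over **every** complete glider placement equals the target parity.
Ensembles: 2×2 box with parity +1 (*even*: every 2×2 block has an even
number of white checks) and −1 (*odd*); an L-shaped three-check region with
parity +1 (*white triangle*: one or three white checks per region) and −1
(*black triangle*); a T-tetromino (*wye*) and an L-tetromino (*foot*), both
parity +1; and a *random* ensemble of fair coin flips. Triangle, wye and
foot geometries are configuration (the omitted triangle corner and the
tetromino shapes can be overridden via `GliderTemplate`); the defaults are
the visually natural choices and nothing statistical at ensemble level
depends on them.

Generation uses a causal raster-scan fill. For a given glider, the offset
that is raster-last determines, for each placement anchor, a unique check;
all checks never in that role are independent fair coins, and the
determined checks are filled in raster order from the parity rule. Because
each anchor determines a distinct check, the fill is conflict-free, every
constrained board is reachable, and all are equally likely — for the 2×2
box on a g×g grid, exactly 2^(2g−1) boards, verified exhaustively in the
tests for g ≤ 4. When glider offsets share the raster-last row (box, foot),
the determined row is filled left-to-right sequentially, since those source
checks are themselves determined by the preceding anchor.

Boundary handling: no wraparound; placements lie fully inside the grid.
One consequence is that the constraint set is exactly the placements
counted by `validate_parity`, which must return 1.0 on every generated
board. Two-point correlations vanish in every ensemble; tests verify this
within 4 standard errors using **board-level** SEs (mean placement product
per board is i.i.d. across boards; placement-level SEs would ignore the
within-board dependence of overlapping products).

## Simulated experiment

The protocol mirrors the characterization experiment: 7 stimulus types ×
1024 examples × 2 repeats, 320 ms per presentation, interleaved in a seeded
uniform random permutation, with no inter-trial gap (a continuous stimulus
stream; the gap is configurable). Check size in degrees is carried as
metadata only.

Model neurons produce a rate

    rate(t) = max(0, baseline + peak_rate · (drive/drive_scale) · k(t))

with `k(t)` a difference-of-gamma transient kernel normalized to peak 1 at
85 ms (inside the 70–100 ms latency range typical of these responses) with
≈40 ms FWHM and a 0.2-weight delayed undershoot. Spikes are an
inhomogeneous Poisson process at 1 ms resolution, times jittered uniformly
within their bin.

Neuron classes and their drives (per 16×16 board, edge signal
e(r,c) = s(r,c) − s(r,c+1) ∈ {−2, 0, 2}):

* **LN** — mean over sites of a static nonlinearity of e (quadratic by
  default). Any static function of a two-check edge depends only on
  P(edge) = (1 − E[ss])/2, a second-order quantity equal across all seven
  ensembles, so the expected LN drive is ensemble-blind; this is the
  insensitive control, rate-matched via `drive_scale = 2` (= E[e²] on any
  ensemble).
* **LNLN** — half-wave-rectified edge units pooled across two vertically
  adjacent positions with opposite polarity (a white→black edge above a
  black→white edge) through a second threshold. Over the 2×2 block the
  constrained moments of each ensemble are known exactly, giving per-site
  firing probability 1/8 on *even* and *white-triangle* boards, 0 on *odd*
  and *black-triangle*, and 1/16 on *random*, *wye* and *foot*: a neuron
  genuinely selective for the informative correlations, discriminating 16
  of the 21 pairs in expectation. `drive_scale = 0.5/16` rate-matches it
  to the LN control on random stimuli. The polarity-reversing geometry is
  a deliberate choice: same-polarity pooling is blind to the triangle
  ensembles (their constrained third-order moment cancels in any
  polarity-symmetric statistic), whereas one fixed polarity pattern
  separates both triangles from random and from each other's opposite.
* **patch** — a linear drive from a weighted window of checks (default
  all-ones 3×3), the known-ground-truth neuron for receptive-field
  recovery; `drive_scale` is the drive SD over random boards.
* **null** — constant baseline rate, no stimulus drive.

The simulator does not attempt biophysical realism (no adaptation,
conductances, correlated noise, or eye movements), and its Poisson spiking
understates the trial-to-trial variability of cortical neurons; passing
tests demonstrate that the analysis chain recovers known ground truth
under its own noise model, not that it is optimal for real recordings.

## Rate smoothing and the shuffle test

PSTHs are accumulated in 5 ms bins over the 320 ms presentation across all
trials of a type. The smoothed rate is a tricube-weighted local linear
regression evaluated on the analysis grid (55–250 ms in 5 ms steps, 40
bins), bandwidth 12 ms by default (supported 8–20 ms; local linear
regression is exact on straight lines, so the smoother introduces no bias
where the rate is locally linear). With a fixed design the smoother is a
linear operator `L`; this matters below.

Significance of a pair difference uses an adjacency-constrained permutation
test. Trials of the two types are greedily paired in session order, each
trial with the nearest unpaired partner within 4 s (two-sided; the pairing
algorithm is underdetermined by the adjacency requirement alone, and
greedy-nearest is deterministic). Each of the
3000 surrogates (500 in scaled-down test settings) exchanges every eligible
pair independently with probability ½ and rebuilds both smoothed rates.
Because whole trials are exchanged between equal-count labels, the
surrogate rate difference is linear in the exchange indicators, and the
entire null ensemble reduces to two matrix products with `L` — this is why
3000 surrogates × 21 pairs runs in seconds. Per-bin two-tailed p-values use
the add-one convention (1 + exceedances)/(surrogates + 1), never exactly
zero and slightly conservative. Benjamini–Hochberg at level 0.05 across the
40 bins of one pair (the family is the pair's time course, not pooled
across pairs) yields the data-determined threshold q and the significant
bins. A pair is discriminated if any bin in 55–250 ms is significant;
overall MCDI = n/21, stimulus-specific = n/6, pair-specific ∈ {0, 1}.
Surrogate exchange moves whole-trial spike trains (not binned counts), and
the 4 s adjacency window is interpreted two-sided; both are genuinely open
design choices, fixed here as stated.

## Receptive-field mapping

The per-example response is the total spike count over the presentation
averaged across repeats and mean-centered (centering is a documented
choice; without it the map differs by a constant offset map only when the
ensemble is exactly balanced). The RF map correlates the response with the
check sign at each location; summing spikes first is equivalent to
integrating the spike-triggered average over the presentation because the
stimulus is constant within a trial. Significance: 500 response
permutations per type, Gaussian z against the surrogate mean/SD per check,
two-tailed p, Benjamini–Hochberg at 0.05. The correction family for the
standalone per-map operation is that map's 256 checks; the session-level
analysis defaults to the joint family of all 7×256 checks
(`fdr_scope="session"`), because seven independent per-map corrections
would declare a null neuron mappable in ≈ 1 − 0.95⁷ ≈ 30% of sessions —
the joint family restores the ≈5% session-level error that the
"unmappable" designation presumes. Checks with zero surrogate SD are
non-significant with a warning.

RF extraction: union of the seven masks → 8-connected components → merge
smaller components into the largest when their boundaries are at most one
empty check apart (Chebyshev distance ≤ 2 between cells; connectivity and
gap are configurable) → convex hull of the retained cell centers → the RF
is the set of lattice checks whose centers lie inside or on the hull
(degenerate collinear/point hulls fall back to the cells on the segment).
An empty union means no mappable RF. The alternative pooled map
(responses of all 7×1024 stimuli, centered within type) is available via
`pooled=True` and agrees with the per-type maps on strong simulated RFs.

## Population summaries

The discrimination matrix averages pair-specific 0/1 outcomes across
neurons. Embedding uses classical (Torgerson) MDS — double-centering of
squared distances and eigendecomposition — with negative eigenvalues
truncated and reported, variance explained computed from the positive
eigenvalues, and a residual stress diagnostic. Group comparisons of MCDI
time courses use the two-tailed Wilcoxon rank-sum test per bin (exact null
for small tie-free samples, tie-corrected normal approximation otherwise,
as provided by scipy), BH-corrected across the 40 bins; bins where both
groups are identical constants report p = 1.

## Waveform widths and the dip test

Features are measured on the channel with the highest SNR (peak-to-peak of
the mean waveform over the SD of residuals — the SNR definition is a
documented choice). The trough is the global minimum, the peak the
maximum after it, both refined by three-point parabolic interpolation; the
half-peak crossing after the peak is located by linear interpolation
between samples. Labels: trough-to-peak < 405 µs → narrow, > 430 µs →
broad, the notch in between → unclassified. A 2-means clustering of the
widths is reported with its label agreement (up to cluster relabeling).

The dip statistic is computed exactly from its definition: the smallest
sup-norm distance between the empirical cdf and any unimodal cdf, where
unimodal means convex up to a mode and concave beyond it, the mode lying
either between observations or at an observation carrying a point mass
(hence the dip of a constant sample is 0). For each candidate mode
placement, a convex-minorant/concave-majorant scan yields a lower bound on
the required band half-width in O(n) amortized; candidates are resolved in
ascending bound order by a small linear program until no remaining bound
can beat the best exact value. An exhaustive-scan implementation of the
same definition serves as the oracle in the tests (300 random samples,
including heavily tied ones, agree to 1e−7), alongside hand-derived closed
forms (dip = 1/4 for two points, 1/(2n) for equally spaced values). The
significance test bootstraps uniform samples of the same size (the dip is
invariant under monotone rescaling); the bootstrap exploits that only the
comparison with the observed dip is needed, stopping each null evaluation
as soon as its dip is known to fall below the observed one.

## Problem sizes and determinism

Defaults follow the experimental protocol (1024 examples, 2 repeats, 3000
surrogates, 500 RF permutations). The test suite and the acceptance script
scale some stages down and say so where they do: ground-truth MCDI
sessions use 256 examples/set with 500 surrogates; the global-null size
simulation uses 200 sessions of 2×48 trials with 500 surrogates; null-RF
mappability uses 256-example sessions with 200 permutations; the dip
bootstrap uses 199 resamples at n = 500. Every random stage consumes a
named seed through `numpy.random.SeedSequence` spawning, so ensembles,
sessions, surrogates and bootstrap draws are independently reproducible.

## Known limitations

* The LNLN default is one specific instantiation of collinear-edge
  pooling; real V2 neurons presumably mix many geometries, orientations
  and scales.
* The shuffle test assumes exchangeability of adjacent trials under the
  null; slow rate drifts faster than the 4 s adjacency window would
  violate it (that is precisely what the adjacency constraint guards
  against, but no drift is simulated here).
* Classical MDS treats discrimination fractions as Euclidean distances;
  they are bounded and need not embed exactly (negative eigenvalues are
  reported, not hidden).
* The dip test's LP scan is exact but not the fastest known algorithm;
  for the few-hundred-sample use case here it runs in seconds.
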
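# mcdi — multipoint-correlation discrimination analysis

Tools for asking whether a visual neuron is sensitive to **multipoint
correlations** — image statistics of three or more pixels that carry the
"stuff" of natural scenes (corners, junctions, contours, figure/ground)
but leave the power spectrum untouched. The package provides the full
computational chain used in sensory neurophysiology experiments of this
kind, with a simulated experiment standing in for recordings so that every
stage can be exercised and validated end to end:

1. **Texture synthesis** (`mcdi.textures`) — seven maximum-entropy binary
   checkerboard ensembles. Six impose a parity constraint on a small
   *glider* of lattice cells: the *even*/*odd* ensembles extremize the
   four-point correlation α over a 2×2 block, the *white/black triangle*
   ensembles extremize the three-point correlation θ over an L-shaped
   region, and *wye*/*foot* extremize perceptually non-salient four-point
   configurations; the seventh is a fair-coin *random* ensemble. All
   ensembles match in their one-point statistics (half white) and have
   exactly zero two-point correlations, so any differential response
   isolates multipoint sensitivity.
2. **Simulated experiment** (`mcdi.session`, `mcdi.neurons`) — the
   interleaved protocol (7 types × 1024 examples × 2 repeats, 320 ms
   presentations in a seeded pseudorandom order) driving
   inhomogeneous-Poisson model neurons with known ground truth: an LN
   cascade that is provably blind to multipoint correlations and an LNLN
   cascade (rectified local edges pooled across collinear positions
   through a second threshold) that is selective for the informative ones.
3. **The MCDI statistic** (`mcdi.discrimination`) — for each of the 21
   stimulus-type pairs, the difference of locally-linear-smoothed firing
   rates is tested with an adjacency-constrained shuffle test (surrogates
   exchange whole-trial responses between types, restricted to trials
   within 4 s of each other), with Benjamini–Hochberg FDR correction
   across the 40 five-ms analysis bins from 55 to 250 ms. The
   **multipoint-correlation discrimination index** is n/21, the fraction
   of pairs discriminated.
4. **Receptive-field mapping** (`mcdi.rf`) — reverse correlation of
   per-example spike counts against check sign, surrogate-based
   significance, and RF extraction as the convex hull of the merged
   significant components.
5. **Population summaries** (`mcdi.population`) — pairwise discrimination
   matrices across neurons, classical multidimensional scaling (distance ↔
   fraction of discriminating neurons), and rank-sum comparisons of MCDI
   time courses between groups.
6. **Waveform classification** (`mcdi.waveforms`, `mcdi.dip`) —
   trough-to-peak / half-peak spike-width features, narrow (<405 µs) vs
   broad (>430 µs) labeling, Hartigan's dip test for width bimodality, and
   a k-means cross-check.

The analyses follow the statsmodels convention: a model object built from
data whose `fit()` returns a results object
(`MCDIAnalysis` → `MCDIResults`, `ReverseCorrelationAnalysis` →
`ReceptiveFieldResults`) carrying the estimates, per-bin p-values,
significance masks, and a `summary()`.

## Worked example

Simulate a multipoint-sensitive LNLN neuron through the full protocol and
quantify its discrimination:

```python
from mcdi import (generate_all_ensembles, build_protocol, make_lnln_neuron,
                  simulate_session, MCDIAnalysis)

ensembles = generate_all_ensembles(n_examples=256, seed=0)
protocol = build_protocol(n_examples_per_set=256, n_repeats=2)
neuron = make_lnln_neuron()          # collinear-edge-pooling cascade
session = simulate_session(neuron, ensembles, protocol, seed=0)
results = MCDIAnalysis(session, n_surrogates=500).fit(seed=0)
print(results.summary())
```

prints

```
MCDI analysis
==============================================
kinds:              random, even, odd, white_triangle, black_triangle, wye, foot
pairs tested:       21
surrogates:         500
window:             55-250 ms (40 bins of 5 ms)
overall MCDI:       16/21 = 0.762
peak per-bin MCDI:  0.762

stimulus-specific MCDI (n/6):
  random          0.667
  even            0.833
  odd             0.833
  white_triangle  0.833
  black_triangle  0.833
  wye             0.667
  foot            0.667

discriminated pairs:
  random vs even  (q = 0.0259)
  ...
  black_triangle vs foot  (q = 0.0359)
```

The neuron distinguishes every pair involving an informative correlation
(even, odd, white/black triangle) — 16 of 21 — and none of the three pairs
among the uninformative stimuli (random, wye, foot). Each `q` is the
data-determined FDR threshold of that pair's test. The matched-rate LN
control neuron (`make_ln_neuron()`) analyzed the same way yields an MCDI
of 0: its quadratic nonlinearity sees only second-order statistics, which
are identical across the ensembles by construction.

A command-line interface wraps the common round trips:

```bash
mcdi generate --kind all --n 1024 --seed 1 --out textures/
mcdi simulate --neuron lnln --seed 1 --out session.csv
mcdi analyze --session session.csv --surrogates 3000 --seed 1 --out report.json
```

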
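"""Texture-ensemble generation: parity, maximum entropy, correlation nulling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcdi import textures as tx

EXPECTED_SIGN = {
    "even": +1,
    "odd": -1,
    "white_triangle": +1,
    "black_triangle": -1,
    "wye": +1,
    "foot": +1,
}


def _board_level_z(boards, values_per_board):
    """z-score of a per-board statistic against zero, boards independent."""
    v = np.asarray(values_per_board, dtype=float)
    se = v.std(ddof=1) / np.sqrt(v.size)
    if se == 0:
        return 0.0 if v.mean() == 0 else np.inf
    return abs(v.mean()) / se


@pytest.fixture(scope="module")
def ensembles():
    return tx.generate_all_ensembles(n_examples=1024, seed=42)


@pytest.mark.parametrize("kind", tx.STRUCTURED_KINDS)
def test_parity_is_forced_on_every_generated_board(ensembles, kind):
    glider = tx.glider_for_kind(kind)
    boards = ensembles[kind]
    assert all(tx.validate_parity(b, glider) == 1.0 for b in boards)
    est = tx.estimate_glider_correlation(boards, glider)
    assert est.value == EXPECTED_SIGN[kind] * 1.0


def test_parity_of_hostile_boards():
    box_odd = tx.GLIDERS["box_odd"]
    all_white = np.ones((8, 8), dtype=np.int8)
    assert tx.validate_parity(all_white, box_odd) == 0.0
    assert tx.validate_parity(all_white, tx.GLIDERS["box_even"]) == 1.0
    rng = np.random.default_rng(0)
    fracs = [
        tx.validate_parity(rng.integers(0, 2, (16, 16)) * 2 - 1, tx.GLIDERS["box_even"])
        for _ in range(200)
    ]
    assert abs(np.mean(fracs) - 0.5) < 0.02  # random boards: parity is a coin flip


def test_even_2x2_exhaustive_support_and_uniformity():
    """On a 2x2 grid the even rule admits exactly the 8 even-parity boards,
    each equally often (oracle: enumerate all 16 boards and filter)."""
    oracle = {
        b
        for b in itertools.product((-1, 1), repeat=4)
        if b[0] * b[1] * b[2] * b[3] == 1
    }
    assert len(oracle) == 8
    spec = tx.ensemble_spec("even", height=2, width=2, n_examples=16000, seed=5)
    boards = tx.generate_ensemble(spec)
    seen, counts = np.unique(boards.reshape(-1, 4), axis=0, return_counts=True)
    assert {tuple(b) for b in seen} == oracle
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    from scipy.stats import chi2 as chi2_dist

    assert chi2_dist.sf(chi2, df=7) > 0.01


@pytest.mark.parametrize("g", [2, 3, 4])
def test_maximum_entropy_board_count_small_grids(g):
    """The even glider on a g x g grid admits 2^(2g-1) equally likely boards."""
    n = 3000 * 2 ** (2 * g - 1) // 8
    spec = tx.ensemble_spec("even", height=g, width=g, n_examples=n, seed=g)
    boards = tx.generate_ensemble(spec)
    _, counts = np.unique(boards.reshape(n, -1), axis=0, return_counts=True)
    k = 2 ** (2 * g - 1)
    assert counts.size == k
    chi2 = ((counts - n / k) ** 2 / (n / k)).sum()
    from scipy.stats import chi2 as chi2_dist

    assert chi2_dist.sf(chi2, df=k - 1) > 0.01


def test_one_point_matching(ensembles):
    for kind, boards in ensembles.items():
        n = boards.size
        assert abs(tx.white_fraction(boards) - 0.5) < 4.0 / np.sqrt(n), kind


def test_pair_correlation_nulling(ensembles):
    """No ensemble carries two-point structure: every offset up to 4 is
    within 4 board-level standard errors of zero."""
    H = W = 16
    for kind, boards in ensembles.items():
        b = boards.astype(np.int8)
        for dr, dc in itertools.product(range(5), range(-4, 5)):
            if (dr, dc) == (0, 0) or (dr == 0 and dc < 0):
                continue
            c0, c1 = max(0, -dc), min(W, W - dc)
            prod = b[:, : H - dr, c0:c1] * b[:, dr:, c0 + dc : c1 + dc]
            z = _board_level_z(boards, prod.mean(axis=(1, 2)))
            assert z < 4.0, (kind, dr, dc, z)


def test_cross_glider_correlation_nulling(ensembles):
    """Each structured ensemble extremizes its own correlation and leaves
    every other glider's correlation at zero."""
    own = {k: tx.glider_for_kind(k).offsets for k in tx.STRUCTURED_KINDS}
    for kind in tx.STRUCTURED_KINDS:
        boards = ensembles[kind]
        for gname, glider in tx.GLIDERS.items():
            if glider.offsets == own[kind]:
                continue  # same geometry extremizes both parities
            nrows = 16 - glider.height + 1
            ncols = 16 - glider.width + 1
            prod = np.ones((boards.shape[0], nrows, ncols), dtype=np.int8)
            for dr, dc in glider.offsets:
                prod = prod * boards[:, dr : dr + nrows, dc : dc + ncols]
            z = _board_level_z(boards, prod.mean(axis=(1, 2)))
            assert z < 4.0, (kind, gname, z)


def test_even_ensemble_is_null_for_wye(ensembles):
    est = tx.estimate_glider_correlation(ensembles["even"], tx.GLIDERS["wye"])
    prod = None  # board-level tolerance as above
    boards = ensembles["even"]
    g = tx.GLIDERS["wye"]
    nrows, ncols = 16 - g.height + 1, 16 - g.width + 1
    prod = np.ones((boards.shape[0], nrows, ncols), dtype=np.int8)
    for dr, dc in g.offsets:
        prod = prod * boards[:, dr : dr + nrows, dc : dc + ncols]
    assert _board_level_z(boards, prod.mean(axis=(1, 2))) < 4.0
    assert -1.0 <= est.value <= 1.0


def test_reproducibility_and_stream_independence():
    a = tx.generate_all_ensembles(n_examples=8, seed=3)
    b = tx.generate_all_ensembles(n_examples=8, seed=3)
    for kind in tx.KINDS:
        assert np.array_equal(a[kind], b[kind])
    sub = tx.generate_all_ensembles(n_examples=8, seed=3, kinds=["odd"])
    assert np.array_equal(sub["odd"], a["odd"])  # independent per-kind streams


def test_invalid_specs_raise():
    with pytest.raises(ValueError):
        tx.ensemble_spec("even", height=1, width=1)
    with pytest.raises(ValueError):
        tx.EnsembleSpec(kind="random", glider=tx.GLIDERS["box_even"])
    with pytest.raises(ValueError):
        tx.GliderTemplate("bad", ((1, 1), (1, 2)), +1)  # not anchored
    with pytest.raises(ValueError):
        tx.GliderTemplate("bad", ((0, 0), (0, 0)), +1)  # duplicate offsets
    with pytest.raises(ValueError):
        tx.GliderTemplate("bad", ((0, 0), (0, 1)), 2)  # parity not +-1
    with pytest.raises(ValueError):
        tx.estimate_glider_correlation(np.empty((0, 4, 4)), tx.GLIDERS["box_even"])
    with pytest.raises(ValueError):
        tx.estimate_pair_correlations(np.ones((1, 4, 4)), max_offset=4)
    big = tx.GliderTemplate("big", tuple((0, c) for c in range(20)), +1)
    with pytest.raises(ValueError):
        tx.validate_parity(np.ones((4, 4)), big)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    offs=st.sets(
        st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=2, max_size=4
    ),
    parity=st.sampled_from([-1, 1]),
    seed=st.integers(0, 2**16),
)
def test_parity_holds_for_arbitrary_gliders(offs, parity, seed):
    """Property: the causal fill satisfies the parity rule for any template."""
    offs = tuple(sorted(offs))
    rmin = min(r for r, _ in offs)
    cmin = min(c for _, c in offs)
    offs = tuple((r - rmin, c - cmin) for r, c in offs)
    if len(set(offs)) != len(offs):
        return
    glider = tx.GliderTemplate("hyp", offs, parity)
    spec = tx.EnsembleSpec(
        kind="even", glider=glider, height=6, width=6, n_examples=8, seed=seed
    )
    boards = tx.generate_ensemble(spec)
    assert all(tx.validate_parity(b, glider) == 1.0 for b in boards)
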
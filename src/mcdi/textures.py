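"""Maximum-entropy binary texture ensembles defined by glider parity rules.

A *glider* is a small set of lattice offsets together with a target parity.
Sliding the glider over a binary checkerboard (checks coded +1 for white,
-1 for black) and demanding that the product of the covered checks equal the
target parity at every placement defines a texture ensemble that extremizes
one multipoint correlation while leaving all lower-order and all other
multipoint correlations at zero.  Seven ensembles are provided:

==================  =========================  ==============
kind                glider                     target parity
==================  =========================  ==============
random              (none)                     --
even                2x2 box                    +1
odd                 2x2 box                    -1
white_triangle      L-shaped 3-check region    +1
black_triangle      L-shaped 3-check region    -1
wye                 T-tetromino                +1
foot                L-tetromino                +1
==================  =========================  ==============

With white = +1, the *even* ensemble has an even number of white checks in
every 2x2 neighborhood; the *white triangle* ensemble has one or three white
checks in every triangular region, and likewise for their opposites.

Boards are generated by a causal raster-scan fill: checks that are never the
raster-last element of any glider placement are independent fair coin flips,
and every remaining check is then uniquely determined by the parity rule.
Because each placement determines a distinct check, the fill is conflict-free
and the resulting distribution is uniform over all boards satisfying the
parity constraint -- the maximum-entropy ensemble.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "KINDS",
    "GliderTemplate",
    "EnsembleSpec",
    "CorrelationEstimate",
    "GLIDERS",
    "glider_for_kind",
    "ensemble_spec",
    "generate_ensemble",
    "generate_all_ensembles",
    "validate_parity",
    "estimate_glider_correlation",
    "estimate_pair_correlations",
    "white_fraction",
]

#: Canonical ordering of the seven stimulus types used throughout the package.
KINDS = (
    "random",
    "even",
    "odd",
    "white_triangle",
    "black_triangle",
    "wye",
    "foot",
)

STRUCTURED_KINDS = KINDS[1:]


@dataclass(frozen=True)
class GliderTemplate:
    """A parity-constraint template: lattice offsets plus a target parity.

    Offsets are (row, col) pairs anchored so that ``min row == min col == 0``.
    ``target_parity`` is the required product of check values (+1/-1) over
    every complete placement of the template on a board.
    """

    name: str
    offsets: tuple[tuple[int, int], ...]
    target_parity: int

    def __post_init__(self) -> None:
        offs = tuple((int(r), int(c)) for r, c in self.offsets)
        if len(set(offs)) != len(offs) or not offs:
            raise ValueError("glider offsets must be distinct and non-empty")
        rows = [r for r, _ in offs]
        cols = [c for _, c in offs]
        if min(rows) != 0 or min(cols) != 0:
            raise ValueError("glider offsets must be anchored at min row = min col = 0")
        if self.target_parity not in (+1, -1):
            raise ValueError("target_parity must be +1 or -1")
        object.__setattr__(self, "offsets", offs)

    @property
    def height(self) -> int:
        return max(r for r, _ in self.offsets) + 1

    @property
    def width(self) -> int:
        return max(c for _, c in self.offsets) + 1

    @property
    def raster_last(self) -> tuple[int, int]:
        """The offset that comes last in row-major (raster) order."""
        return max(self.offsets)

    def fits(self, height: int, width: int) -> bool:
        return self.height <= height and self.width <= width


def _box(parity: int, name: str) -> GliderTemplate:
    return GliderTemplate(name, ((0, 0), (0, 1), (1, 0), (1, 1)), parity)


def _triangle(parity: int, name: str, omit: str = "lower_right") -> GliderTemplate:
    corners = {
        "lower_right": ((0, 0), (0, 1), (1, 0)),
        "lower_left": ((0, 0), (0, 1), (1, 1)),
        "upper_right": ((0, 0), (1, 0), (1, 1)),
        "upper_left": ((0, 1), (1, 0), (1, 1)),
    }
    try:
        offsets = corners[omit]
    except KeyError:  # pragma: no cover - defensive
        raise ValueError(f"unknown omitted corner {omit!r}") from None
    return GliderTemplate(name, offsets, parity)


#: Default glider geometries.  The triangle omits the lower-right corner of a
#: 2x2 box; wye is a T-tetromino and foot an L-tetromino.  All are
#: configuration, not ground truth, and can be overridden by constructing a
#: custom :class:`GliderTemplate`.
GLIDERS: Mapping[str, GliderTemplate] = {
    "box_even": _box(+1, "box_even"),
    "box_odd": _box(-1, "box_odd"),
    "triangle_white": _triangle(+1, "triangle_white"),
    "triangle_black": _triangle(-1, "triangle_black"),
    "wye": GliderTemplate("wye", ((0, 0), (0, 1), (0, 2), (1, 1)), +1),
    "foot": GliderTemplate("foot", ((0, 0), (1, 0), (2, 0), (2, 1)), +1),
}

_KIND_TO_GLIDER = {
    "even": "box_even",
    "odd": "box_odd",
    "white_triangle": "triangle_white",
    "black_triangle": "triangle_black",
    "wye": "wye",
    "foot": "foot",
}


def glider_for_kind(kind: str) -> GliderTemplate | None:
    """Return the default glider for an ensemble kind (None for ``random``)."""
    if kind == "random":
        return None
    try:
        return GLIDERS[_KIND_TO_GLIDER[kind]]
    except KeyError:
        raise ValueError(f"unknown ensemble kind {kind!r}") from None


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of one texture ensemble."""

    kind: str
    glider: GliderTemplate | None = None
    height: int = 16
    width: int = 16
    n_examples: int = 1024
    seed: int = 0
    check_size_deg: float = 0.2  # metadata only; not used in generation

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.kind == "random":
            if self.glider is not None:
                raise ValueError("random ensembles take no glider")
        else:
            if self.glider is None:
                object.__setattr__(self, "glider", glider_for_kind(self.kind))
        if self.n_examples < 1:
            raise ValueError("n_examples must be >= 1")
        if self.glider is not None:
            if self.height < 2 or self.width < 2:
                raise ValueError("structured ensembles need height, width >= 2")
            if not self.glider.fits(self.height, self.width):
                raise ValueError(
                    f"glider {self.glider.name!r} ({self.glider.height}x"
                    f"{self.glider.width}) does not fit a "
                    f"{self.height}x{self.width} board"
                )


def ensemble_spec(kind: str, **overrides) -> EnsembleSpec:
    """Convenience constructor pairing a kind with its default glider."""
    return EnsembleSpec(kind=kind, glider=glider_for_kind(kind), **overrides)


@dataclass(frozen=True)
class CorrelationEstimate:
    """Mean product of check values over all placements of a glider."""

    glider: GliderTemplate
    value: float
    n_placements: int

    @property
    def standard_error(self) -> float:
        """Binomial-style sampling error of the mean product.

        Individual placement products are +-1; treating them as independent
        gives SE = sqrt((1 - value^2) / n).  Placements overlap, so this is a
        guide for tolerance-setting rather than an exact error bar.
        """
        v = min(1.0, max(-1.0, self.value))
        return float(np.sqrt(max(0.0, 1.0 - v * v) / self.n_placements))


def _anchors(glider: GliderTemplate, height: int, width: int) -> tuple[int, int]:
    """Number of anchor rows/cols for complete placements (no wraparound)."""
    return height - glider.height + 1, width - glider.width + 1


def generate_ensemble(
    spec: EnsembleSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``spec.n_examples`` boards from the maximum-entropy ensemble.

    Returns an int8 array of shape (n_examples, height, width) with values
    +-1.  Reproducible from ``spec.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, H, W = spec.n_examples, spec.height, spec.width
    coins = rng.integers(0, 2, size=(n, H, W), dtype=np.int8) * 2 - 1
    if spec.glider is None:
        return coins

    g = spec.glider
    lr, lc = g.raster_last
    prior = [off for off in g.offsets if off[0] < lr]
    same_row = [off for off in g.offsets if off[0] == lr and off != (lr, lc)]
    nrows, ncols = _anchors(g, H, W)
    boards = coins
    # Checks that are raster-last for some placement are parity-determined;
    # overwrite the coin flips there, scanning anchors in raster order so that
    # every source check is already final when read.  Sources in earlier rows
    # are final for the whole row at once; sources in the same row (e.g. the
    # (1, 0) check of the 2x2 box) force a left-to-right column scan because
    # they are themselves determined by the preceding anchor.
    for ar in range(nrows):
        r = ar + lr
        partial = np.full((n, ncols), g.target_parity, dtype=np.int8)
        for dr, dc in prior:
            partial *= boards[:, ar + dr, dc : dc + ncols]
        if not same_row:
            boards[:, r, lc : lc + ncols] = partial
        else:
            for ac in range(ncols):
                val = partial[:, ac].copy()
                for _, dc in same_row:
                    val *= boards[:, r, ac + dc]
                boards[:, r, ac + lc] = val
    return boards


def generate_all_ensembles(
    height: int = 16,
    width: int = 16,
    n_examples: int = 1024,
    seed: int = 0,
    kinds: Iterable[str] = KINDS,
) -> dict[str, np.ndarray]:
    """Generate every requested ensemble with independent seeded streams.

    Each kind draws from its own child of ``numpy.random.SeedSequence(seed)``
    (spawned in the order of :data:`KINDS`), so individual ensembles are
    reproducible regardless of which subset is requested.
    """
    kinds = list(kinds)
    children = {k: s for k, s in zip(KINDS, np.random.SeedSequence(seed).spawn(len(KINDS)))}
    out = {}
    for kind in kinds:
        spec = ensemble_spec(kind, height=height, width=width, n_examples=n_examples)
        out[kind] = generate_ensemble(spec, rng=np.random.default_rng(children[kind]))
    return out


def _placement_products(boards: np.ndarray, glider: GliderTemplate) -> np.ndarray:
    boards = np.asarray(boards)
    if boards.ndim == 2:
        boards = boards[None]
    n, H, W = boards.shape
    if not glider.fits(H, W):
        raise ValueError(f"glider {glider.name!r} does not fit a {H}x{W} board")
    nrows, ncols = _anchors(glider, H, W)
    prod = np.ones((n, nrows, ncols), dtype=np.int8)
    for dr, dc in glider.offsets:
        prod = prod * boards[:, dr : dr + nrows, dc : dc + ncols]
    return prod


def validate_parity(board: np.ndarray, glider: GliderTemplate) -> float:
    """Fraction of complete glider placements satisfying the target parity."""
    prod = _placement_products(board, glider)
    return float(np.mean(prod == glider.target_parity))


def estimate_glider_correlation(
    boards: np.ndarray, glider: GliderTemplate
) -> CorrelationEstimate:
    """Mean product of check values over all placements and boards."""
    boards = np.asarray(boards)
    if boards.size == 0:
        raise ValueError("need at least one board")
    prod = _placement_products(boards, glider)
    return CorrelationEstimate(glider, float(prod.mean()), int(prod.size))


def estimate_pair_correlations(
    boards: np.ndarray, max_offset: int
) -> dict[tuple[int, int], float]:
    """Two-point correlations for all nonzero offsets up to ``max_offset``.

    Offsets are taken over the canonical half-plane (dr > 0, or dr == 0 and
    dc > 0); the correlation at -(dr, dc) is identical by symmetry.
    """
    boards = np.asarray(boards)
    if boards.ndim == 2:
        boards = boards[None]
    if boards.size == 0:
        raise ValueError("need at least one board")
    n, H, W = boards.shape
    if max_offset >= min(H, W):
        raise ValueError("max_offset must be smaller than the grid size")
    out: dict[tuple[int, int], float] = {}
    for dr, dc in itertools.product(range(max_offset + 1), range(-max_offset, max_offset + 1)):
        if (dr, dc) == (0, 0) or (dr == 0 and dc < 0):
            continue
        r0, r1 = 0, H - dr
        c0, c1 = max(0, -dc), min(W, W - dc)
        a = boards[:, r0:r1, c0:c1]
        b = boards[:, dr : dr + (r1 - r0), c0 + dc : c1 + dc]
        out[(dr, dc)] = float(np.mean(a * b))
    return out


def white_fraction(boards: np.ndarray) -> float:
    """Empirical fraction of white (+1) checks."""
    boards = np.asarray(boards)
    return float(np.mean(boards == 1))
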
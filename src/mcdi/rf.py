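"""Reverse-correlation receptive-field mapping with shuffle significance.

The RF map for one stimulus type correlates the per-example response (total
spikes over the 320 ms presentation, averaged across repeats and
mean-centered) with the check sign (+1 white, -1 black) at each location.
Significance is assessed per check against 500 response-permutation
surrogates via a Gaussian z-score, Benjamini-Hochberg corrected across the
256 checks.  The RF is the convex hull of the union of the seven significant
masks, after merging small connected components into the largest one when
they are separated by no more than a single check; a neuron with an empty
union is unmappable.

Organized as a model/results pair: ``ReverseCorrelationAnalysis(session,
ensembles).fit(seed=0)`` returns a :class:`ReceptiveFieldResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .discrimination import bh_fdr
from .session import Session

__all__ = [
    "RFMap",
    "RFRegion",
    "example_responses",
    "reverse_correlation_map",
    "map_significance",
    "extract_rf",
    "ReverseCorrelationAnalysis",
    "ReceptiveFieldResults",
]


@dataclass(frozen=True)
class RFMap:
    kind: str
    values: np.ndarray  # (H, W) response-check correlation
    z: np.ndarray | None = None
    sig_mask: np.ndarray | None = None


@dataclass(frozen=True)
class RFRegion:
    hull_checks: frozenset[tuple[int, int]]
    n_checks: int
    area_deg2: float
    mappable: bool


def example_responses(session: Session, kind: str) -> np.ndarray:
    """Total spike count per example, averaged across repeats."""
    trials = session.trials_of_kind(kind)
    n_ex = session.protocol.n_examples_per_set
    total = np.zeros(n_ex)
    reps = np.zeros(n_ex)
    for t in trials:
        total[t.example_id] += len(t.spike_times_s)
        reps[t.example_id] += 1
    if np.any(reps == 0):
        raise ValueError(f"some examples of kind {kind!r} were never presented")
    return total / reps


def _correlate(responses: np.ndarray, boards: np.ndarray) -> np.ndarray:
    r = responses - responses.mean()
    n, H, W = boards.shape
    return (r @ boards.reshape(n, -1)).reshape(H, W) / n


def reverse_correlation_map(
    session: Session, boards: np.ndarray, kind: str
) -> RFMap:
    """First-order reverse-correlation map for one stimulus type.

    Summing spikes over the presentation and correlating with check sign is
    equivalent to integrating the spike-triggered average over the stimulus
    duration, since the stimulus is constant within a trial.
    """
    responses = example_responses(session, kind)
    if boards.shape[0] < responses.size:
        raise ValueError("fewer boards than presented examples")
    boards = np.asarray(boards[: responses.size], dtype=float)
    return RFMap(kind, _correlate(responses, boards))


def pooled_reverse_correlation_map(
    session: Session, ensembles: dict[str, np.ndarray]
) -> RFMap:
    """Alternative map correlating responses with all stimuli of all types
    pooled together (centering within type to remove type-mean rate
    differences)."""
    rs, bs = [], []
    for kind in session.protocol.set_kinds:
        r = example_responses(session, kind)
        rs.append(r - r.mean())
        bs.append(np.asarray(ensembles[kind][: r.size], dtype=float))
    r = np.concatenate(rs)
    boards = np.concatenate(bs)
    return RFMap("pooled", _correlate(r, boards))


def _surrogate_z(
    rf_map: RFMap,
    session: Session,
    boards: np.ndarray,
    n_surrogates: int,
    seed,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-check z-scores and Gaussian p-values vs response-permutation
    surrogates; returns (z, p, zero_sd_mask)."""
    responses = example_responses(session, rf_map.kind)
    if np.unique(responses).size < 2:
        raise ValueError("need at least two distinct responses for a null")
    boards = np.asarray(boards[: responses.size], dtype=float)
    n, H, W = boards.shape
    flat = boards.reshape(n, -1)
    rng = np.random.default_rng(seed)
    r = responses - responses.mean()
    surr = np.empty((n_surrogates, H * W))
    for s in range(n_surrogates):
        surr[s] = r[rng.permutation(n)] @ flat
    surr /= n
    mu = surr.mean(axis=0).reshape(H, W)
    sd = surr.std(axis=0, ddof=1).reshape(H, W)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} checks had zero surrogate SD; "
            "marked non-significant"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero_sd, 0.0, (rf_map.values - mu) / np.where(zero_sd, 1.0, sd))
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return z, p, zero_sd


def map_significance(
    rf_map: RFMap,
    session: Session,
    boards: np.ndarray,
    n_surrogates: int = 500,
    level: float = 0.05,
    seed: int | np.random.SeedSequence | None = 0,
) -> RFMap:
    """Attach surrogate-based z-scores and an FDR significance mask.

    Responses are permuted against stimuli ``n_surrogates`` times; the
    surrogate mean and SD at each check define a Gaussian null for the
    actual map value; Benjamini-Hochberg correction runs across the checks
    of this map.  Checks with zero surrogate SD are non-significant.
    """
    z, p, zero_sd = _surrogate_z(rf_map, session, boards, n_surrogates, seed)
    _, mask = bh_fdr(p.ravel(), level)
    mask = mask.reshape(z.shape) & ~zero_sd
    return RFMap(rf_map.kind, rf_map.values, z=z, sig_mask=mask)


def _hull_checks(cells: np.ndarray) -> set[tuple[int, int]]:
    """Lattice checks whose centers lie inside or on the convex hull of the
    given cell centers (row, col)."""
    from scipy.spatial import Delaunay, QhullError

    pts = np.asarray(cells, dtype=float)
    if len(pts) == 0:
        return set()
    if len(pts) <= 2 or np.linalg.matrix_rank(pts - pts[0]) < 2:
        # degenerate hull: a point or collinear segment; take lattice points
        # on the segment between the two extremes
        out = set(map(tuple, cells.astype(int)))
        if len(pts) >= 2:
            d = pts - pts[0]
            t = d @ (pts[-1] - pts[0])
            lo, hi = pts[np.argmin(t)], pts[np.argmax(t)]
            span = hi - lo
            steps = int(round(max(abs(span[0]), abs(span[1]))))
            for s in range(steps + 1):
                q = lo + span * (s / max(steps, 1))
                if np.allclose(q, np.round(q), atol=1e-9):
                    out.add((int(round(q[0])), int(round(q[1]))))
        return out
    try:
        tri = Delaunay(pts)
    except QhullError:
        return set(map(tuple, cells.astype(int)))
    r0, c0 = pts.min(axis=0).astype(int)
    r1, c1 = pts.max(axis=0).astype(int)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    inside = tri.find_simplex(grid, tol=1e-9) >= 0
    return {(int(r), int(c)) for (r, c), ok in zip(grid.astype(int), inside) if ok}


def extract_rf(
    sig_masks: list[np.ndarray] | np.ndarray,
    check_size_deg: float = 0.2,
    merge_gap_checks: int = 1,
) -> RFRegion:
    """RF extraction from the per-type significance masks.

    Union of the masks -> 8-connected components -> merge smaller components
    into the largest when separated by at most ``merge_gap_checks`` empty
    checks (Chebyshev gap) -> convex hull of the retained cells -> count of
    lattice checks inside the hull.
    """
    masks = np.asarray(sig_masks, dtype=bool)
    if masks.ndim == 2:
        masks = masks[None]
    if len({m.shape for m in masks}) != 1:
        raise ValueError("masks must share one grid shape")
    union = masks.any(axis=0)
    if not union.any():
        return RFRegion(frozenset(), 0, 0.0, mappable=False)
    labels, n_comp = ndimage.label(union, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(union, labels, index=np.arange(1, n_comp + 1))
    largest = int(np.argmax(sizes)) + 1
    keep = labels == largest
    if n_comp > 1:
        # component boundaries separated by <= merge_gap_checks empty checks
        # <=> cells within Chebyshev distance merge_gap_checks + 1
        grown = ndimage.binary_dilation(
            keep,
            structure=np.ones((3, 3), dtype=bool),
            iterations=merge_gap_checks + 1,
        )
        for lab in range(1, n_comp + 1):
            if lab != largest and np.any(grown & (labels == lab)):
                keep |= labels == lab
    cells = np.argwhere(keep)
    hull = _hull_checks(cells)
    return RFRegion(
        hull_checks=frozenset(hull),
        n_checks=len(hull),
        area_deg2=len(hull) * check_size_deg**2,
        mappable=True,
    )


class ReverseCorrelationAnalysis:
    """Reverse-correlation RF mapping for one neuron across all stimulus
    types.

    Set ``pooled=True`` to additionally compute the map obtained from all
    stimuli of all types pooled together.  ``fdr_scope`` selects the family
    of the Benjamini-Hochberg correction: ``"session"`` (default) corrects
    jointly across the checks of all seven maps, so that a neuron with no
    true RF is declared mappable in only ~5% of sessions; ``"map"``
    corrects each map's checks separately.
    """

    def __init__(
        self,
        session: Session,
        ensembles: dict[str, np.ndarray],
        n_surrogates: int = 500,
        level: float = 0.05,
        pooled: bool = False,
        fdr_scope: str = "session",
    ) -> None:
        for kind in session.protocol.set_kinds:
            if kind not in ensembles:
                raise ValueError(f"missing ensemble for kind {kind!r}")
        if fdr_scope not in ("session", "map"):
            raise ValueError("fdr_scope must be 'session' or 'map'")
        self.session = session
        self.ensembles = ensembles
        self.n_surrogates = n_surrogates
        self.level = level
        self.pooled = pooled
        self.fdr_scope = fdr_scope

    def fit(self, seed: int = 0) -> "ReceptiveFieldResults":
        kinds = self.session.protocol.set_kinds
        children = np.random.SeedSequence(seed).spawn(len(kinds))
        maps = {}
        if self.fdr_scope == "map":
            for kind, child in zip(kinds, children):
                raw = reverse_correlation_map(self.session, self.ensembles[kind], kind)
                maps[kind] = map_significance(
                    raw,
                    self.session,
                    self.ensembles[kind],
                    n_surrogates=self.n_surrogates,
                    level=self.level,
                    seed=child,
                )
        else:
            zs, ps, zsds, raws = {}, [], {}, {}
            for kind, child in zip(kinds, children):
                raw = reverse_correlation_map(self.session, self.ensembles[kind], kind)
                z, p, zero_sd = _surrogate_z(
                    raw, self.session, self.ensembles[kind], self.n_surrogates, child
                )
                raws[kind], zs[kind], zsds[kind] = raw, z, zero_sd
                ps.append(p.ravel())
            _, joint_mask = bh_fdr(np.concatenate(ps), self.level)
            npc = ps[0].size
            for i, kind in enumerate(kinds):
                mask = joint_mask[i * npc : (i + 1) * npc].reshape(zs[kind].shape)
                maps[kind] = RFMap(
                    kind,
                    raws[kind].values,
                    z=zs[kind],
                    sig_mask=mask & ~zsds[kind],
                )
        pooled_map = (
            pooled_reverse_correlation_map(self.session, self.ensembles)
            if self.pooled
            else None
        )
        region = extract_rf(
            [m.sig_mask for m in maps.values()],
            check_size_deg=self.session.protocol.check_size_deg,
        )
        return ReceptiveFieldResults(self, maps, region, pooled_map)


@dataclass
class ReceptiveFieldResults:
    model: ReverseCorrelationAnalysis
    maps: dict[str, RFMap]
    region: RFRegion
    pooled_map: RFMap | None = None

    def summary(self) -> str:
        lines = [
            "Reverse-correlation RF mapping",
            "=" * 46,
            f"surrogates per map: {self.model.n_surrogates}",
            f"mappable:           {self.region.mappable}",
            f"RF size:            {self.region.n_checks} checks "
            f"({self.region.area_deg2:.3f} deg^2)",
            "",
            "significant checks per stimulus type:",
        ]
        for kind, m in self.maps.items():
            lines.append(f"  {kind:15s} {int(m.sig_mask.sum()):4d}")
        return "\n".join(lines)

    def plot_maps(self, axes=None):
        import matplotlib.pyplot as plt

        kinds = list(self.maps)
        if axes is None:
            _, axes = plt.subplots(1, len(kinds), figsize=(2.2 * len(kinds), 2.4))
        vmax = max(np.abs(m.values).max() for m in self.maps.values()) or 1.0
        for ax, kind in zip(np.atleast_1d(axes), kinds):
            ax.imshow(self.maps[kind].values, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_title(kind, fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
        return axes
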
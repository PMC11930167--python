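"""Derived analyses on cluster-parameter map stacks.

Three families of analysis live here:

* display and sensitivity transforms — logarithmic display scale, min-max
  normalization, and the summed gradient-length ("sum gradient") maps whose
  low-valued regions are the *process windows*: (epsilon, N) regions where
  the clustering output is insensitive to its input parameters;
* process-window extraction, per treatment and summed over treatments (with
  the gradient-length limit scaled by the treatment count);
* edge-line fits that quantify how sample properties shift the maps — the
  onset edge of the average-cluster-area map (its epsilon-axis intercept
  tracks the nanofocus size) and the background-affected band edge of the
  average-localization-number map (its slope tracks the nonspecific
  localization density).

All transforms are pure: input stacks are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .clustering import MapStack

__all__ = [
    "EdgeFit",
    "ProcessWindow",
    "log_display",
    "normalize_map",
    "sum_gradient",
    "process_window",
    "combined_window",
    "onset_edge_fit",
    "band_edge_fit",
    "FIVE_MAPS",
    "THREE_MAPS",
]

#: Map selections for the sum gradient: all five, or SDs + cluster number only.
FIVE_MAPS = ("av_area", "sd_area", "av_nloc", "sd_nloc", "n_clusters")
THREE_MAPS = ("sd_area", "sd_nloc", "n_clusters")


@dataclass(frozen=True)
class EdgeFit:
    """A line N = slope * epsilon + c fitted to a map edge.

    ``intercept_eps`` is the epsilon-axis intercept -c/slope (nm), i.e. the
    extrapolated epsilon at N = 0; it is NaN when the slope is 0.
    """

    edge_points: np.ndarray      # (k, 2): epsilon (nm), N
    slope: float                 # 1/nm
    intercept: float             # c, dimensionless (N at epsilon = 0)
    r_squared: float

    @property
    def intercept_eps(self) -> float:
        if self.slope == 0:
            return float("nan")
        return -self.intercept / self.slope


@dataclass(frozen=True)
class ProcessWindow:
    """Boolean (epsilon, N) mask where the sum-gradient length is below limit."""

    mask: np.ndarray
    threshold: float
    source_maps: tuple
    treatments: tuple = ("sample",)


def log_display(stack: MapStack) -> MapStack:
    """Return a copy of the stack on a base-10 logarithmic display scale.

    Zeros (e.g. empty cells of the cluster-number map) become NaN on the
    display scale.  Applying the transform to a stack already on the display
    scale raises a domain error if any value <= 0 is present, since such
    values have no logarithm.
    """
    already_log = stack.metadata.get("scale") == "log10"
    out = stack.copy()
    out.metadata["scale"] = "log10"
    for metric in MapStack.METRICS:
        m = out.maps[metric]
        finite = np.isfinite(m)
        if already_log and np.any(m[finite] <= 0):
            raise ValueError(
                "log display of a display-scale stack: values <= 0 have no logarithm"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            res = np.where(finite & (m > 0), np.log10(np.where(m > 0, m, 1.0)), np.nan)
        out.maps[metric] = res
    return out


def normalize_map(map_values: np.ndarray) -> np.ndarray:
    """Min-max normalize a matrix to [0, 1] over its finite cells.

    Constant maps normalize to 0.5 everywhere (finite); NaN is preserved.
    Raises a domain error for an all-NaN map.
    """
    m = np.asarray(map_values, dtype=float)
    finite = np.isfinite(m)
    if not finite.any():
        raise ValueError("cannot normalize an all-NaN map")
    lo = m[finite].min()
    hi = m[finite].max()
    out = np.full(m.shape, np.nan)
    if hi == lo:
        out[finite] = 0.5
    else:
        out[finite] = (m[finite] - lo) / (hi - lo)
    return out


def _gradient_length(m: np.ndarray) -> np.ndarray:
    """Euclidean length of the 2-component gradient on grid-index units.

    Central differences in the interior, one-sided at the borders; any
    difference that touches a NaN neighbor is NaN (NaN propagates through
    ``np.gradient``), so the rim of an undefined region stays undefined
    rather than producing spurious window boundaries.
    """
    ge, gn = np.gradient(m)
    return np.hypot(ge, gn)


def sum_gradient(stack: MapStack, which: str = "five") -> np.ndarray:
    """Summed gradient-length map over the selected (normalized) maps.

    ``which`` selects "five" (both AVs, both SDs, cluster number) or "three"
    (both SDs and cluster number).  Each selected map is min-max normalized,
    its gradient length taken on index units, and the lengths summed; cells
    where every selected map yields NaN are NaN.
    """
    try:
        selection = {"five": FIVE_MAPS, "three": THREE_MAPS}[which]
    except KeyError:
        raise ValueError("which must be 'five' or 'three'") from None
    lengths = [ _gradient_length(normalize_map(stack.maps[m])) for m in selection ]
    arr = np.stack(lengths)
    all_nan = np.all(np.isnan(arr), axis=0)
    with np.errstate(invalid="ignore"):
        total = np.nansum(arr, axis=0)
    total[all_nan] = np.nan
    return total


def process_window(sum_grad: np.ndarray, threshold: float) -> ProcessWindow:
    """Mask of cells whose sum-gradient length is below the threshold.

    NaN cells are excluded (False).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    sg = np.asarray(sum_grad, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = sg < threshold
    mask[~np.isfinite(sg)] = False
    return ProcessWindow(mask=mask, threshold=float(threshold), source_maps=())


def combined_window(sum_grads: Sequence[np.ndarray], threshold: float,
                    treatments: Optional[Sequence[str]] = None) -> ProcessWindow:
    """Summed-treatment process window.

    The sum of the per-treatment sum gradients is compared against the
    threshold multiplied by the number of treatments, so a single treatment
    reduces exactly to :func:`process_window`.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mats = [np.asarray(m, dtype=float) for m in sum_grads]
    if not mats:
        raise ValueError("need at least one sum-gradient matrix")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("sum-gradient matrices must share the grid shape")
    k = len(mats)
    total = np.sum(np.stack(mats), axis=0)
    with np.errstate(invalid="ignore"):
        mask = total < threshold * k
    mask[~np.isfinite(total)] = False
    labels = tuple(treatments) if treatments is not None else tuple(
        f"treatment_{i}" for i in range(k)
    )
    return ProcessWindow(mask=mask, threshold=float(threshold), source_maps=(), treatments=labels)


def _ols_fit(eps_pts: np.ndarray, n_pts: np.ndarray) -> tuple[float, float, float]:
    """Unweighted OLS of N on epsilon; returns (slope, intercept, r_squared)."""
    res = stats.linregress(eps_pts, n_pts)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else float("nan")
    return float(res.slope), float(res.intercept), r2


def onset_edge_fit(stack: MapStack, area_level: Optional[float] = None) -> EdgeFit:
    """Fit a line to the cluster-onset edge of the map stack.

    For every N row the edge point is the smallest epsilon at which at least
    one cluster exists (rows with no clusters anywhere are skipped);
    ``area_level`` switches to an iso-contour edge on the average-area map
    (smallest epsilon with av_area >= area_level).  A line N = slope*eps + c
    is fitted by ordinary least squares; ``intercept_eps`` extrapolates it to
    the epsilon axis (N = 0).
    """
    eps = stack.grid.epsilons
    ns = stack.grid.Ns
    pts = []
    for j, N in enumerate(ns):
        if area_level is None:
            col = stack.maps["n_clusters"][:, j] >= 1
        else:
            with np.errstate(invalid="ignore"):
                col = stack.maps["av_area"][:, j] >= area_level
        idx = np.nonzero(col)[0]
        if idx.size:
            pts.append((eps[idx[0]], N))
    if len(pts) < 2:
        raise ValueError("onset edge fit needs at least 2 rows with clusters")
    pts = np.asarray(pts, dtype=float)
    slope, intercept, r2 = _ols_fit(pts[:, 0], pts[:, 1])
    return EdgeFit(edge_points=pts, slope=slope, intercept=intercept, r_squared=r2)


def band_edge_fit(stack_bg: MapStack, stack_ref: MapStack, delta: float = 0.2) -> EdgeFit:
    """Fit a line to the background-affected band edge of the av_nloc maps.

    ``stack_ref`` must be the zero-background reference of the same pattern
    on the same grid.  For every epsilon column, cells are *affected* when
    the average localization number deviates from the reference by more than
    ``delta`` relative (cells defined in only one of the two stacks count as
    affected).  Scanning N upward from N_min, the edge point is the largest N
    of the contiguous affected band starting at N_min; columns whose N_min
    cell is unaffected are skipped.  The band-edge points are fitted by OLS
    of N on epsilon.
    """
    if not (np.array_equal(stack_bg.grid.epsilons, stack_ref.grid.epsilons)
            and np.array_equal(stack_bg.grid.Ns, stack_ref.grid.Ns)):
        raise ValueError("band edge fit requires identical grids")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    eps = stack_bg.grid.epsilons
    ns = stack_bg.grid.Ns
    a_bg = stack_bg.maps["av_nloc"]
    a_ref = stack_ref.maps["av_nloc"]
    fin_bg = np.isfinite(a_bg)
    fin_ref = np.isfinite(a_ref)
    affected = fin_bg ^ fin_ref  # defined in exactly one stack
    both = fin_bg & fin_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(a_bg - a_ref) / np.abs(a_ref)
    affected[both] = rel[both] > delta
    if not affected.any():
        raise ValueError("no affected cells: the two stacks agree everywhere")
    pts = []
    for i, e in enumerate(eps):
        col = affected[i]
        if not col[0]:
            continue
        run_end = np.argmin(col) - 1 if not col.all() else ns.size - 1
        pts.append((e, ns[run_end]))
    if len(pts) < 2:
        raise ValueError("band edge fit needs at least 2 affected columns")
    pts = np.asarray(pts, dtype=float)
    slope, intercept, r2 = _ols_fit(pts[:, 0], pts[:, 1])
    return EdgeFit(edge_points=pts, slope=slope, intercept=intercept, r_squared=r2)
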
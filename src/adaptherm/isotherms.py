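"""Noise-robust isotherm extraction from 2D temperature maps.

An isotherm is the polyline of constant temperature.  Instead of marching
squares on the noisy map, the map is first turned into a cost image

    D_i = |T_i - T_iso|        for every pixel i,

and the isotherm is the minimum-total-cost path through that image,
constrained to advance strictly along the needle-axis direction (one vertex
per image row, lateral drift bounded by the connectivity step).  Summing the
positive and negative deviations along the whole path averages out
zero-mean pixel noise, so the extracted contour is far more stable than any
per-pixel thresholding.

The monotone-row constraint makes the path graph a DAG, so the shortest
path is computed by deterministic dynamic programming (equivalent to
Dijkstra on this graph) with a leftmost-column tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thermometry import TemperatureMap

__all__ = [
    "CostMap",
    "Isotherm",
    "IsothermSet",
    "cost_map",
    "extract_isotherm",
    "extract_isotherm_set",
    "default_isovalues",
    "NoValidDataError",
]


class NoValidDataError(ValueError):
    """Raised when a row has no valid pixel on the requested side."""


@dataclass
class CostMap:
    """Per-pixel absolute deviation from one temperature isovalue (°C)."""

    values: np.ndarray
    isovalue: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)


@dataclass
class Isotherm:
    """One extracted constant-temperature path.

    ``vertices`` holds exactly one ``(row, col)`` per traversed row, rows
    strictly increasing.  ``extrapolated`` flags isovalues never reached by
    the map (the path then hugs the hottest ridge).
    """

    isovalue: float
    vertices: np.ndarray  # (n, 2) int
    side: str  # "left" | "right"
    total_cost: float
    costs: np.ndarray | None = None  # per-vertex measured deviation, °C
    extrapolated: bool = False

    @property
    def rows(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.vertices[:, 1]


@dataclass
class IsothermSet:
    """All isotherms (both sides x all isovalues) of one temperature map."""

    isotherms: list[Isotherm]
    tmap: TemperatureMap | None = None

    def __iter__(self):
        return iter(self.isotherms)

    def __len__(self) -> int:
        return len(self.isotherms)


def cost_map(tmap: TemperatureMap, isovalue: float) -> CostMap:
    """Absolute temperature deviation from the isovalue; invalid pixels +inf."""
    if not np.isfinite(isovalue):
        raise ValueError("isovalue must be finite")
    vals = np.abs(np.where(tmap.valid_mask, tmap.values, np.nan) - isovalue)
    vals = np.where(tmap.valid_mask, vals, np.inf)
    return CostMap(values=vals, isovalue=float(isovalue))


def _column_range(n_cols: int, axis_column: float, side: str) -> tuple[int, int]:
    # columns strictly left / right of the axis; an integer axis column is
    # excluded from both sides
    c0 = float(axis_column)
    if side == "left":
        lo, hi = 0, int(np.ceil(c0))
    elif side == "right":
        lo, hi = int(np.floor(c0)) + 1, n_cols
    else:
        raise ValueError("side must be 'left' or 'right'")
    return lo, min(hi, n_cols)


def extract_isotherm(
    costs: CostMap,
    axis_column: float,
    side: str,
    connectivity: int = 1,
) -> Isotherm:
    """Minimum-cost monotone path on one side of the axis.

    The path starts at a virtual zero-cost source above the first row and
    ends below the last row; between rows it may shift laterally by at most
    ``connectivity`` columns.  Ties are broken toward the column nearest the
    axis (then first-found), which makes the result fully deterministic and
    keeps the path from wandering outward across flat (unheated) regions.
    """
    grid = costs.values
    n_rows, n_cols = grid.shape
    lo, hi = _column_range(n_cols, axis_column, side)
    sub = grid[:, lo:hi]
    if sub.shape[1] == 0 or np.any(~np.isfinite(sub).any(axis=1)):
        raise NoValidDataError(
            f"a row has no valid pixel on the {side} side of the axis"
        )
    if side == "left":
        # mirror so that "leftmost" in DP coordinates means nearest the axis
        sub = sub[:, ::-1]
    w = sub.shape[1]
    k = connectivity
    # DP over rows; acc[c] = best total cost of any monotone path reaching
    # (row, c).  parent stores the argmin predecessor column (leftmost wins).
    acc = sub[0].copy()
    parents = np.empty((n_rows, w), dtype=np.int32)
    parents[0] = -1
    cols_idx = np.arange(w)
    for r in range(1, n_rows):
        # windowed min over predecessor columns [c-k, c+k]; offsets are
        # scanned in increasing source-column order and only strictly better
        # costs replace, so ties resolve to the leftmost predecessor
        best = np.full(w, np.inf)
        best_arg = np.zeros(w, dtype=np.int32)
        for off in range(-k, k + 1):
            shifted = np.full(w, np.inf)
            src = cols_idx + off
            ok = (src >= 0) & (src < w)
            shifted[ok] = acc[src[ok]]
            better = shifted < best
            best[better] = shifted[better]
            best_arg[better] = src[better]
        acc = sub[r] + best
        parents[r] = best_arg
    # sink: nearest-axis minimal end column (leftmost in DP coordinates)
    end = int(np.flatnonzero(acc == acc.min())[0])
    total = float(acc[end])
    cols = np.empty(n_rows, dtype=np.int64)
    c = end
    for r in range(n_rows - 1, -1, -1):
        cols[r] = c
        c = parents[r, c]
    if side == "left":
        cols = (w - 1) - cols
    vertices = np.stack([np.arange(n_rows), cols + lo], axis=1)
    return Isotherm(
        isovalue=costs.isovalue,
        vertices=vertices,
        side=side,
        total_cost=total,
        costs=grid[vertices[:, 0], vertices[:, 1]],
    )


def default_isovalues(
    baseline_T0: float,
    span: float = 24.0,
    count: int = 8,
) -> np.ndarray:
    """Uniform ladder of isovalues anchored at the baseline temperature.

    Eight values spanning 24 °C above a 21 °C baseline gives
    {21, 24.43, ..., 45} °C.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if span <= 0:
        raise ValueError("span must be positive")
    if count == 1:
        return np.array([float(baseline_T0)])
    return baseline_T0 + np.linspace(0.0, span, count)


def extract_isotherm_set(
    tmap: TemperatureMap,
    isovalues=None,
    axis_column: float | None = None,
    connectivity: int = 1,
    strict: bool = True,
) -> IsothermSet:
    """Extract left and right isotherms for every isovalue of one map.

    With ``strict=False`` a side whose rows contain no valid data (e.g. a
    dropped-out half image) is silently omitted instead of raising; only a
    completely unextractable map raises :class:`NoValidDataError`.
    """
    if isovalues is None:
        isovalues = default_isovalues(tmap.baseline_T0)
    isovalues = np.asarray(isovalues, float)
    if isovalues.size == 0:
        raise ValueError("isovalues must be non-empty")
    if isovalues.size > 1 and np.any(np.diff(isovalues) <= 0):
        raise ValueError("isovalues must be strictly increasing")
    if axis_column is None:
        axis_column = tmap.frame.axis_column
    if not np.any(tmap.valid_mask):
        raise NoValidDataError("temperature map has no valid pixels")
    vmax = float(np.max(tmap.values[tmap.valid_mask]))
    result = []
    for iso in isovalues:
        cm = cost_map(tmap, iso)
        for side in ("left", "right"):
            try:
                it = extract_isotherm(cm, axis_column, side, connectivity)
            except NoValidDataError:
                if strict:
                    raise
                continue
            # an isovalue hotter than anything measured: the path merely hugs
            # the hottest ridge, so mark it as an extrapolation
            it.extrapolated = iso > vmax
            result.append(it)
    if not result:
        raise NoValidDataError("no isotherm could be extracted on either side")
    return IsothermSet(isotherms=result, tmap=tmap)


def isotherms_to_frame(iso_set: IsothermSet):
    """DataFrame serialization (isovalue, side, row, col)."""
    import pandas as pd

    rows = []
    for iso in iso_set:
        for r, c in iso.vertices:
            rows.append((iso.isovalue, iso.side, int(r), int(c)))
    return pd.DataFrame(rows, columns=["isovalue", "side", "row", "col"])
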
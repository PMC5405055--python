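"""Population-level statistics and parameter-space visualization.

Covers three analyses of biomarker tables produced across a population
and a set of ischemic severities:

* descriptive variability statistics (variance, range, histograms) of a
  biomarker per condition, over non-excluded members only;
* column plots: one row per member (ordered by control APD90), one
  column per ischemia time point, cell colour = normalised biomarker;
* clutter-based dimension reordering (CBDR): the lossless linear
  projection x' = sum_i (x_i - 1) * prod_{j<i} N_j + 1 that arranges a
  full-factorial n-dimensional conductance grid into one or two
  dimensions by nested slicing, so that the fastest-varying dimension
  shows its effect at the smallest spatial scale of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PopulationResult", "GridSpec", "SummaryStats",
    "population_summary", "column_plot_matrix",
    "cbdr_project", "cbdr_image",
    "BIOMARKER_METRICS", "EXCLUSION_REASONS",
]

BIOMARKER_METRICS = ("apd90", "erp", "v_rest", "v_max", "dvdt_max")
EXCLUSION_REASONS = ("failed excitation", "solver failure", "unrepolarised")

#: required columns of a population-result table
RESULT_COLUMNS = ("member_id", "time_min", "preset", "excluded", "reason",
                  *BIOMARKER_METRICS)


@dataclass
class PopulationResult:
    """Per member x ischemia time point x preset biomarker table.

    Wraps a tidy DataFrame with one row per (member, condition); the
    ``excluded`` flag carries a reason from :data:`EXCLUSION_REASONS`.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")
        bad = self.table.loc[self.table["excluded"] & (self.table["reason"] == "")]
        if len(bad):
            raise ValueError("excluded entries must carry a reason")

    def included(self) -> pd.DataFrame:
        return self.table.loc[~self.table["excluded"]]

    def condition(self, time_min: float, preset: str | None = None) -> pd.DataFrame:
        t = self.table
        sel = t["time_min"] == time_min
        if preset is not None:
            sel &= t["preset"] == preset
        return t.loc[sel]

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "PopulationResult":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=True,
                               na_values=[""]).fillna({"reason": ""}))


@dataclass
class SummaryStats:
    variance: float
    range: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n_included: int
    n_excluded: int


def _fd_bins(x: np.ndarray) -> int | np.ndarray:
    """Freedman-Diaconis bin count (>= 1); falls back to 10 bins."""
    if x.size < 2:
        return 1
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 10
    width = 2 * iqr / x.size ** (1 / 3)
    span = x.max() - x.min()
    return max(1, int(np.ceil(span / width))) if span > 0 else 1


def population_summary(results: PopulationResult, metric: str,
                       bins=None) -> pd.DataFrame:
    """Variance, range and histogram of ``metric`` per condition.

    Statistics are over non-excluded members with a finite metric value
    (population variance, ddof = 0); the excluded count is reported
    alongside. All-excluded conditions yield null statistics.
    """
    if metric not in BIOMARKER_METRICS:
        raise ValueError(f"metric must be one of {BIOMARKER_METRICS}")
    rows = []
    for (preset, tmin), grp in results.table.groupby(["preset", "time_min"]):
        ok = grp.loc[~grp["excluded"], metric].to_numpy(float)
        ok = ok[np.isfinite(ok)]
        n_exc = int(len(grp) - ok.size)
        if ok.size == 0:
            rows.append(dict(preset=preset, time_min=tmin, n=0,
                             n_excluded=n_exc, variance=np.nan, range=np.nan,
                             mean=np.nan, hist_counts=None, hist_edges=None))
            continue
        counts, edges = np.histogram(ok, bins=bins if bins is not None
                                     else _fd_bins(ok))
        rows.append(dict(preset=preset, time_min=tmin, n=int(ok.size),
                         n_excluded=n_exc,
                         variance=float(np.var(ok)),
                         range=float(ok.max() - ok.min()),
                         mean=float(ok.mean()),
                         hist_counts=counts, hist_edges=edges))
    return pd.DataFrame(rows)


def column_plot_matrix(results: PopulationResult, metric: str,
                       preset: str | None = None,
                       normalise: bool = True):
    """Member x time-point matrix of ``metric`` for a column plot.

    Rows are members sorted ascending by their control (t = 0) value of
    APD90; columns are the ischemia time points in increasing order.
    Values are min-max normalised over all non-excluded cells (global
    per metric); excluded cells carry NaN as the sentinel.

    Returns ``(matrix, member_order, time_points)``.
    """
    t = results.table if preset is None else \
        results.table.loc[(results.table["preset"] == preset)
                          | (results.table["time_min"] == 0)]
    times = np.sort(t["time_min"].unique())
    if times.size < 2:
        raise ValueError("column plot needs results at >= 2 time points")
    control = t.loc[(t["time_min"] == 0) & ~t["excluded"]]
    order = (control.sort_values("apd90", kind="stable")["member_id"]
             .to_numpy())
    mat = np.full((order.size, times.size), np.nan)
    lookup = {(r.member_id, r.time_min): getattr(r, metric)
              for r in t.itertuples() if not r.excluded}
    for i, mid in enumerate(order):
        for k, tp in enumerate(times):
            mat[i, k] = lookup.get((mid, tp), np.nan)
    if normalise:
        finite = np.isfinite(mat)
        if finite.any():
            lo, hi = np.nanmin(mat), np.nanmax(mat)
            if hi > lo:
                mat = (mat - lo) / (hi - lo)
            else:
                mat = np.where(finite, 0.5, np.nan)
    return mat, order, times


def plot_columns(matrix: np.ndarray, times: np.ndarray, path,
                 rows_per_bar: int = 100, title: str = "") -> None:
    """Render a column-plot matrix as PNG, split into bars of
    ``rows_per_bar`` members placed side by side (excluded cells grey)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = matrix.shape[0]
    nbars = max(1, int(np.ceil(n / rows_per_bar)))
    fig, axes = plt.subplots(1, nbars, figsize=(2.2 * nbars, 6), squeeze=False)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.7")
    for b in range(nbars):
        ax = axes[0, b]
        chunk = matrix[b * rows_per_bar:(b + 1) * rows_per_bar]
        ax.imshow(np.ma.masked_invalid(chunk), aspect="auto", cmap=cmap,
                  vmin=0, vmax=1, interpolation="nearest")
        ax.set_xticks(range(len(times)))
        ax.set_xticklabels([f"{t:g}" for t in times], fontsize=7)
        ax.set_yticks([])
        ax.set_xlabel("ischemia (min)", fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# clutter-based dimension reordering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Ordered level lists of a full-factorial conductance grid."""

    levels: tuple = field(default=())   # tuple of per-dimension value tuples

    def __post_init__(self):
        if not self.levels or any(len(l) < 1 for l in self.levels):
            raise ValueError("every dimension needs >= 1 level")

    @property
    def shape(self) -> tuple:
        return tuple(len(l) for l in self.levels)

    @property
    def n_total(self) -> int:
        return int(np.prod(self.shape))


def cbdr_project(coords, sizes) -> int:
    """Project 1-based grid indices to a unique 1-based linear index.

    x' = sum_i (x_i - 1) * prod_{j<i} N_j + 1, a bijection from the
    full-factorial grid onto {1..N}. Dimension 1 varies fastest.
    """
    coords = np.atleast_1d(np.asarray(coords, dtype=np.int64))
    sizes = np.atleast_1d(np.asarray(sizes, dtype=np.int64))
    if coords.shape != sizes.shape:
        raise ValueError("coords and sizes must have equal length")
    if np.any(coords < 1) or np.any(coords > sizes):
        raise ValueError(f"grid index out of range: {coords} for sizes {sizes}")
    out = 1
    stride = 1
    for x, n in zip(coords, sizes):
        out += (int(x) - 1) * stride
        stride *= int(n)
    return int(out)


def cbdr_image(values: np.ndarray, grid: GridSpec,
               x_dims: tuple, y_dims: tuple) -> np.ndarray:
    """Arrange full-factorial grid values into a 2D image by CBDR.

    ``values`` is an array of grid shape (one value per grid cell; NaN
    marks missing/excluded cells and is preserved as the sentinel).
    ``x_dims`` and ``y_dims`` are disjoint 0-based dimension index
    sequences that together cover all dimensions; within each, the
    first listed dimension varies fastest (smallest spatial scale).
    Every grid cell maps to exactly one pixel.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(
            f"values shape {values.shape} does not match the factorial grid "
            f"{grid.shape}; CBDR needs a full-factorial sweep (use the grid "
            "sweep mode, not the random population)")
    ndim = len(grid.shape)
    claimed = list(x_dims) + list(y_dims)
    if sorted(claimed) != list(range(ndim)):
        raise ValueError("x_dims and y_dims must partition the dimensions")
    nx = [grid.shape[d] for d in x_dims]
    ny = [grid.shape[d] for d in y_dims]
    img = np.full((int(np.prod(ny)), int(np.prod(nx))), np.nan)
    for idx in np.ndindex(*grid.shape):
        cx = [idx[d] + 1 for d in x_dims]
        cy = [idx[d] + 1 for d in y_dims]
        col = cbdr_project(cx, nx) - 1
        row = cbdr_project(cy, ny) - 1
        img[row, col] = values[idx]
    return img


def variance_dimension_order(values: np.ndarray) -> list:
    """0-based dimension indices ordered by decreasing along-axis
    variance of the grid values (an optional automatic CBDR ordering;
    the default everywhere is user-specified order)."""
    values = np.asarray(values, dtype=float)
    scores = []
    for d in range(values.ndim):
        moved = np.moveaxis(values, d, 0)
        flat = moved.reshape(moved.shape[0], -1)
        scores.append(np.nanmean(np.nanvar(flat, axis=0)))
    return list(np.argsort(scores)[::-1])
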
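"""Planar topographic maps on the rat epidural electrode montage.

Per-electrode values (band power, change rate, ...) are interpolated over
the convex hull of the electrode positions — barycentric linear on a
Delaunay triangulation by default (exact at electrodes, bounded between
the extreme electrode values), thin-plate spline optionally — and masked
outside the hull. Maps are qualitative analysis artifacts; no quantitative
claim is read off the interpolated colors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RBFInterpolator
from scipy.spatial import Delaunay

__all__ = ["Montage", "TopoMap", "load_default_montage", "interpolate_map", "plot_map"]

#: labels excluded from maps (not scalp signal electrodes)
NON_SCALP = {"REF", "GND"}


@dataclass(frozen=True)
class Montage:
    """Electrode label -> (anterior_mm, lateral_mm) planar coordinates."""

    positions: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError("montage needs at least 3 electrodes")

    @property
    def scalp_labels(self) -> list[str]:
        return [lab for lab in self.positions if lab not in NON_SCALP]

    def coords(self, labels: list[str]) -> np.ndarray:
        return np.array([self.positions[lab] for lab in labels])

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "Montage":
        return cls(
            {
                str(r["label"]): (float(r["anterior_mm"]), float(r["lateral_mm"]))
                for _, r in df.iterrows()
            }
        )


def load_default_montage() -> Montage:
    """The packaged 14-electrode rat epidural montage (12 scalp + REF/GND)."""
    text = resources.files("eegbico.data").joinpath("montage_rat14.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    return Montage.from_table(df)


@dataclass
class TopoMap:
    """An interpolated scalar field over the electrode hull.

    ``grid`` is (resolution, resolution) with NaN outside the convex hull;
    ``x``/``y`` are the grid coordinate vectors (anterior, lateral mm).
    """

    grid: np.ndarray
    x: np.ndarray
    y: np.ndarray
    labels: list[str]
    electrode_xy: np.ndarray
    electrode_values: np.ndarray
    significance: np.ndarray | None = None
    method: str = "linear"
    interpolant: object = None

    def value_at(self, xq: float, yq: float) -> float:
        """Interpolated value at an arbitrary point (NaN outside hull).

        Evaluates the underlying interpolant, so electrode positions
        reproduce their input values exactly.
        """
        if self.interpolant is not None:
            return float(np.asarray(self.interpolant(np.atleast_1d(xq),
                                                     np.atleast_1d(yq)))[0])
        ix = np.argmin(np.abs(self.x - xq))
        iy = np.argmin(np.abs(self.y - yq))
        return float(self.grid[ix, iy])


def interpolate_map(
    values: dict[str, float] | pd.Series,
    montage: Montage | None = None,
    resolution: int = 64,
    method: str = "linear",
    significance: dict[str, bool] | None = None,
) -> TopoMap:
    """Interpolate per-electrode values over the montage plane.

    The interpolant reproduces electrode values exactly at electrode
    positions and is evaluated on a ``resolution`` x ``resolution`` grid
    spanning the electrode bounding box, masked to the convex hull (no
    extrapolation). ``method`` is 'linear' (barycentric, bounded) or
    'thin_plate' (smooth spline, may over/undershoot).
    """
    montage = montage if montage is not None else load_default_montage()
    if isinstance(values, pd.Series):
        values = values.to_dict()
    labels = [lab for lab in values if lab in montage.positions and lab not in NON_SCALP]
    if len(labels) < 3:
        raise ValueError("need values on at least 3 montage electrodes")
    xy = montage.coords(labels)
    if np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        raise ValueError("electrodes are collinear; cannot triangulate")
    v = np.array([values[lab] for lab in labels], dtype=float)
    if method == "linear":
        interp = LinearNDInterpolator(xy, v)
    elif method == "thin_plate":
        rbf = RBFInterpolator(xy, v, kernel="thin_plate_spline")
        hull = Delaunay(xy)

        def interp(pts_x, pts_y):  # mask outside hull like the linear path
            pts = np.column_stack([np.ravel(pts_x), np.ravel(pts_y)])
            out = rbf(pts)
            out[hull.find_simplex(pts) < 0] = np.nan
            return out.reshape(np.shape(pts_x))

    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    x = np.linspace(xy[:, 0].min(), xy[:, 0].max(), resolution)
    y = np.linspace(xy[:, 1].min(), xy[:, 1].max(), resolution)
    gx, gy = np.meshgrid(x, y, indexing="ij")
    grid = np.asarray(interp(gx, gy), dtype=float)
    sig = None
    if significance is not None:
        sig = np.array([bool(significance.get(lab, False)) for lab in labels])
    return TopoMap(
        grid=grid, x=x, y=y, labels=labels, electrode_xy=xy,
        electrode_values=v, significance=sig, method=method, interpolant=interp,
    )


def plot_map(tmap: TopoMap, ax=None, cmap: str = "RdBu_r", title: str = ""):
    """Render a topographic map with electrode markers.

    Significant electrodes (if a mask is present) are drawn as filled
    markers, others as open circles. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.pcolormesh(tmap.x, tmap.y, tmap.grid.T, cmap=cmap, shading="auto")
    sig = (
        tmap.significance
        if tmap.significance is not None
        else np.zeros(len(tmap.labels), dtype=bool)
    )
    ax.scatter(*tmap.electrode_xy[~sig].T, s=25, facecolors="none",
               edgecolors="k", zorder=3)
    if sig.any():
        ax.scatter(*tmap.electrode_xy[sig].T, s=40, c="k", zorder=3)
    for lab, (px, py) in zip(tmap.labels, tmap.electrode_xy):
        ax.annotate(lab, (px, py), fontsize=6, xytext=(2, 2),
                    textcoords="offset points")
    ax.set_xlabel("anterior (mm)")
    ax.set_ylabel("lateral (mm)")
    ax.set_title(title)
    ax.set_aspect("equal")
    return ax
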
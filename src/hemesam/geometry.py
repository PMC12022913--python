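"""Monolayer height–packing-density relation.

Simulated monolayers show that denser packing gives thicker films and
that sparse packings have broader height distributions, so the height
h (nm) is regressed on packing density d_p (chains/nm^2) by weighted
least squares with weights 1/variance, and a measured height is
inverted to a packing-density estimate with delta-method uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["HeightDensityData", "RegressionLine", "wls_fit",
           "predict_density", "monolayer_height", "read_height_density_csv"]


@dataclass
class HeightDensityData:
    """One replica's terminal-window height summary at one packing."""

    packing_density: float   # d_p, chains/nm^2
    height_mean: float       # nm
    height_var: float        # nm^2, variance of frame heights
    replica_id: str = "rep0"
    n_helix: int | None = None

    def __post_init__(self) -> None:
        if self.packing_density <= 0:
            raise ValueError("packing_density must be > 0")
        if self.height_var <= 0:
            raise ValueError("height_var must be > 0")


@dataclass
class RegressionLine:
    """h = slope * d_p + intercept with parameter (co)variances."""

    slope: float             # nm per (chains/nm^2)
    intercept: float         # nm
    slope_var: float
    intercept_var: float
    cov_slope_intercept: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.slope_var < 0 or self.intercept_var < 0:
            raise ValueError("parameter variances must be >= 0")

    def predict(self, d_p: float | np.ndarray):
        return self.slope * np.asarray(d_p, float) + self.intercept


def wls_fit(data: Sequence[HeightDensityData]) -> RegressionLine:
    """Closed-form weighted least squares, weights 1/height_var.

    Parameter variances come from the weighted design assuming the
    weights are true inverse variances (unit-scale chi^2), matching the
    generator contract where each observation's variance is known.
    """
    if len(data) < 3:
        raise ValueError("need >= 3 observations")
    x = np.array([d.packing_density for d in data])
    y = np.array([d.height_mean for d in data])
    w = np.array([1.0 / d.height_var for d in data])
    if np.ptp(x) == 0:
        raise ValueError("singular design: all packing densities equal")
    S, Sx, Sy = w.sum(), (w * x).sum(), (w * y).sum()
    Sxx, Sxy = (w * x * x).sum(), (w * x * y).sum()
    delta = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    return RegressionLine(
        slope=float(slope), intercept=float(intercept),
        slope_var=float(S / delta), intercept_var=float(Sxx / delta),
        cov_slope_intercept=float(-Sx / delta), n_obs=len(data))


@dataclass
class DensityPrediction:
    d_p: float
    se: float
    ci_low: float
    ci_high: float


def predict_density(line: RegressionLine, h: float,
                    h_var: float = 0.0) -> DensityPrediction:
    """Inverse prediction d_p = (h - intercept)/slope.

    Delta-method variance propagates the parameter covariance (and an
    optional variance of the measured height). A 95% interval is
    attached. Raises for a slope indistinguishable from zero.
    """
    if line.slope == 0 or abs(line.slope) < 3.0 * np.sqrt(line.slope_var):
        raise ValueError("slope is (near) zero relative to its SE; "
                         "inverse prediction is unstable")
    d = (h - line.intercept) / line.slope
    g = np.array([-d / line.slope, -1.0 / line.slope])  # d(d_p)/d(slope, intercept)
    cov = np.array([[line.slope_var, line.cov_slope_intercept],
                    [line.cov_slope_intercept, line.intercept_var]])
    var = float(g @ cov @ g) + h_var / line.slope**2
    se = float(np.sqrt(max(var, 0.0)))
    return DensityPrediction(float(d), se, float(d - 1.96 * se),
                             float(d + 1.96 * se))


def monolayer_height(
    z_frames: np.ndarray,
    percentile: float = 98.0,
    substrate_z: float = 0.0,
    method: Literal["percentile", "density_threshold"] = "percentile",
    threshold_fraction: float = 0.5,
) -> np.ndarray:
    """Monolayer height per frame from particle z-coordinates (nm).

    ``z_frames`` is (n_frames, n_particles) or a single frame. The
    default estimator is the 98th percentile of z minus the substrate
    plane — the upper edge of the mass distribution, insensitive to a
    few protruding chains. The alternative finds where the z-density
    falls below ``threshold_fraction`` of its interior plateau.
    """
    z = np.atleast_2d(np.asarray(z_frames, float))
    if z.shape[1] < 10:
        raise ValueError("need >= 10 particles per frame")
    if method == "percentile":
        return np.percentile(z, percentile, axis=1) - substrate_z
    if method != "density_threshold":
        raise ValueError(f"unknown method {method!r}")
    out = np.empty(z.shape[0])
    for i, frame in enumerate(z):
        hist, edges = np.histogram(frame, bins=30)
        centers = 0.5 * (edges[:-1] + edges[1:])
        plateau = np.mean(hist[: max(len(hist) // 2, 1)])
        above = np.where(hist >= threshold_fraction * plateau)[0]
        edge = centers[above[-1]] if above.size else float(frame.max())
        out[i] = edge - substrate_z
    return out


def read_height_density_csv(path) -> list[HeightDensityData]:
    df = pd.read_csv(path)
    req = {"d_p_chains_per_nm2", "h_mean_nm", "h_var_nm2"}
    if not req.issubset(df.columns):
        raise ValueError(f"height-density CSV needs columns {sorted(req)}")
    out = []
    for _, row in df.iterrows():
        out.append(HeightDensityData(
            packing_density=row["d_p_chains_per_nm2"],
            height_mean=row["h_mean_nm"], height_var=row["h_var_nm2"],
            replica_id=str(row.get("replica_id", "rep0")),
            n_helix=int(row["n_helix"]) if "n_helix" in row else None))
    return out
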
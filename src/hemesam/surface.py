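"""Monolayer surface metrology: AFM scratch thickness, XPS composition,
amide-I secondary-structure classification.

Thickness comes from the height difference between a scratched region
(substrate exposed) and the surrounding film, read off a two-component
Gaussian fit to the pooled height histogram after plane detrending.
Relative packing density across samples is the S 2p : Au 4f XPS area
ratio (each chain carries exactly one sulfur, in the anchoring
cysteine), which sidesteps absolute quantification and attenuation
corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HeightMap", "ThicknessEstimate", "XPSSpectrum",
    "thickness_from_scratch", "xps_peak_area", "s_au_ratio",
    "classify_amide_I", "read_height_map", "read_xps_csv",
]


@dataclass
class HeightMap:
    """2-D AFM height grid (nm) with optional scratch rectangle
    (row0, row1, col0, col1), half-open pixel coordinates."""

    heights: np.ndarray
    pixel_size_nm: float
    scratch_region: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.scratch_region is not None:
            r0, r1, c0, c1 = self.scratch_region
            nr, nc = self.heights.shape
            if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
                raise ValueError("scratch_region outside grid")

    def scratch_mask(self) -> np.ndarray:
        m = np.zeros(self.heights.shape, bool)
        if self.scratch_region is not None:
            r0, r1, c0, c1 = self.scratch_region
            m[r0:r1, c0:c1] = True
        return m


@dataclass
class ThicknessEstimate:
    thickness: float
    mode_low: float
    mode_high: float
    method: Literal["two_gaussian", "region_medians"]
    se: float

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")


def _detrend_plane(h: np.ndarray, mask_exclude: np.ndarray) -> np.ndarray:
    """Subtract the least-squares plane fitted outside the excluded
    region (scanner tilt removal); the plane offset is retained so
    absolute levels survive."""
    nr, nc = h.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    keep = ~mask_exclude
    A = np.column_stack([np.ones(keep.sum()), rr[keep], cc[keep]])
    coef, *_ = np.linalg.lstsq(A, h[keep], rcond=None)
    return h - coef[1] * rr - coef[2] * cc


def _auto_scratch(h: np.ndarray) -> tuple[int, int, int, int]:
    """Lowest-median rectangular window (window = 1/4 of each dim,
    stride = 1/8) — a cheap scratch detector for centred scratches."""
    nr, nc = h.shape
    wr, wc = max(nr // 4, 2), max(nc // 4, 2)
    best, rect = np.inf, (0, wr, 0, wc)
    for r0 in range(0, nr - wr + 1, max(nr // 8, 1)):
        for c0 in range(0, nc - wc + 1, max(nc // 8, 1)):
            m = np.median(h[r0:r0 + wr, c0:c0 + wc])
            if m < best:
                best, rect = m, (r0, r0 + wr, c0, c0 + wc)
    return rect


def _two_gaussian_modes(vals: np.ndarray, mu0: float, mu1: float):
    hist, edges = np.histogram(vals, bins=80, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(x, a0, m0, s0, a1, m1, s1):
        return (a0 * np.exp(-0.5 * ((x - m0) / s0) ** 2)
                + a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2))

    s_init = max(np.std(vals) / 4, 1e-3)
    popt, _ = curve_fit(
        model, centers, hist,
        p0=[hist.max(), mu0, s_init, hist.max(), mu1, s_init],
        bounds=([0, vals.min(), 1e-4, 0, vals.min(), 1e-4],
                [np.inf, vals.max(), np.ptp(vals) + 1e-6,
                 np.inf, vals.max(), np.ptp(vals) + 1e-6]),
        maxfev=10000)
    m_lo, m_hi = sorted((popt[1], popt[4]))
    return m_lo, m_hi


def thickness_from_scratch(
    hmap: HeightMap,
    method: Literal["two_gaussian", "region_medians"] = "two_gaussian",
    detrend: bool = True,
    n_boot: int = 200,
    seed: int = 0,
) -> ThicknessEstimate:
    """Monolayer thickness from a scratched height map.

    The scratch region (given, or auto-detected as the lowest-median
    window) exposes the substrate; thickness is the separation of the
    two modes of the pooled height histogram (two-Gaussian fit, falling
    back to the difference of region medians when the fit fails or the
    histogram is effectively unimodal). SE by pixel bootstrap of the
    region medians.
    """
    h = hmap.heights
    region = hmap.scratch_region
    auto = region is None
    if auto:
        region = _auto_scratch(h)
    mask = np.zeros(h.shape, bool)
    r0, r1, c0, c1 = region
    mask[r0:r1, c0:c1] = True
    if detrend:
        h = _detrend_plane(h, mask)
    inside, outside = h[mask], h[~mask]
    med_in, med_out = float(np.median(inside)), float(np.median(outside))
    pooled_sd = float(np.std(h))
    if auto and abs(med_out - med_in) < 1.0 * pooled_sd:
        raise ValueError(
            "height histogram looks unimodal and no scratch_region was "
            "given; specify the scratch rectangle explicitly")

    used = method
    if method == "two_gaussian":
        try:
            m_lo, m_hi = _two_gaussian_modes(h.ravel(), med_in, med_out)
            if m_hi - m_lo < 1e-9:  # degenerate fit collapsed onto one mode
                raise RuntimeError
        except Exception:
            used = "region_medians"
            m_lo, m_hi = sorted((med_in, med_out))
    else:
        m_lo, m_hi = sorted((med_in, med_out))

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bi = rng.choice(inside, size=inside.size, replace=True)
        bo = rng.choice(outside, size=outside.size, replace=True)
        boots.append(abs(np.median(bo) - np.median(bi)))
    se = float(np.std(boots))
    return ThicknessEstimate(float(m_hi - m_lo), m_lo, m_hi, used, se)


@dataclass
class XPSSpectrum:
    """One XPS region scan; stored with ascending binding energy."""

    binding_energy: np.ndarray
    counts: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        self.binding_energy = np.asarray(self.binding_energy, float)
        self.counts = np.asarray(self.counts, float)
        if self.binding_energy.shape != self.counts.shape:
            raise ValueError("binding_energy and counts must have equal length")
        if self.binding_energy[0] > self.binding_energy[-1]:
            self.binding_energy = self.binding_energy[::-1]
            self.counts = self.counts[::-1]


def _shirley(E: np.ndarray, y: np.ndarray, tol: float = 1e-6,
             max_iter: int = 200) -> np.ndarray:
    """Iterative Shirley background between the window endpoints."""
    y0, y1 = y[0], y[-1]
    B = np.full_like(y, min(y0, y1))
    for _ in range(max_iter):
        net = y - B
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (net[1:] + net[:-1]) * np.diff(E))])
        total = cum[-1]
        if total <= 0:
            return np.linspace(y0, y1, y.size)
        # Shirley: background at E proportional to the net area at
        # higher kinetic energy (here: toward the low-BE endpoint)
        Bn = y1 + (y0 - y1) * (1.0 - cum / total)
        if np.max(np.abs(Bn - B)) <= tol * max(np.max(np.abs(B)), 1e-12):
            return Bn
        B = Bn
    warnings.warn("Shirley background did not reach 1e-6 relative "
                  "convergence", stacklevel=2)
    return B


def xps_peak_area(
    spec: XPSSpectrum,
    window: tuple[float, float],
    background: Literal["linear", "shirley", "none"] = "linear",
) -> float:
    """Background-subtracted trapezoidal peak area (counts·eV) in a
    binding-energy window. A negative net area is returned with a
    warning rather than clipped."""
    lo, hi = sorted(window)
    E, y = spec.binding_energy, spec.counts
    if lo < E.min() - 1e-9 or hi > E.max() + 1e-9:
        raise ValueError("window outside spectrum range")
    sel = (E >= lo) & (E <= hi)
    Ew, yw = E[sel], y[sel]
    if Ew.size < 3:
        raise ValueError("window contains fewer than 3 samples")
    if background == "linear":
        # anchor each end on a strip average (~5% of the window, >=3
        # points) at the strip's centroid energy: unbiased for a linear
        # background and robust to counting noise on single samples
        m = max(3, Ew.size // 20)
        e0, y0 = Ew[:m].mean(), yw[:m].mean()
        e1, y1 = Ew[-m:].mean(), yw[-m:].mean()
        slope = (y1 - y0) / (e1 - e0)
        B = y0 + slope * (Ew - e0)
    elif background == "shirley":
        B = _shirley(Ew, yw)
    elif background == "none":
        B = np.zeros_like(yw)
    else:
        raise ValueError(f"unknown background {background!r}")
    area = float(np.trapezoid(yw - B, Ew))
    if area < 0:
        warnings.warn(f"negative net area {area:.3g} in window ({lo}, {hi})",
                      stacklevel=2)
    return area


def s_au_ratio(
    spec_s: XPSSpectrum,
    spec_au: XPSSpectrum,
    window_s: tuple[float, float],
    window_au: tuple[float, float],
    background: Literal["linear", "shirley", "none"] = "linear",
) -> float:
    """S 2p : Au 4f peak-area ratio — the relative packing-density
    proxy (one cysteine sulfur per chain). The full S 2p window is
    integrated, covering both the gold-bound and disulfide doublet
    components."""
    a_s = xps_peak_area(spec_s, window_s, background)
    a_au = xps_peak_area(spec_au, window_au, background)
    if a_au == 0:
        raise ZeroDivisionError("Au 4f area is zero; ratio undefined")
    return a_s / a_au


def classify_amide_I(
    peak_position_cm1: float,
) -> Literal["helical", "unordered_or_beta", "outside_amide_I"]:
    """Secondary structure from the amide-I peak position.

    Helical: (1648, 1670] cm^-1; unordered or beta-sheet: [1625, 1648]
    (the shared 1648 endpoint is assigned to the unordered class);
    anything else is outside the amide-I band.
    """
    x = float(peak_position_cm1)
    if x <= 0:
        raise ValueError("wavenumber must be positive")
    if 1648.0 < x <= 1670.0:
        return "helical"
    if 1625.0 <= x <= 1648.0:
        return "unordered_or_beta"
    return "outside_amide_I"


def read_height_map(path, pixel_size_nm: float | None = None) -> HeightMap:
    """Plain-text matrix (whitespace or comma separated) of heights in
    nm, with an optional JSON sidecar ``<path>.json`` carrying
    pixel_size_nm and scratch_region."""
    import json
    from pathlib import Path

    arr = np.loadtxt(path, delimiter="," if str(path).endswith(".csv") else None)
    side = Path(str(path) + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    px = pixel_size_nm or meta.get("pixel_size_nm", 1.0)
    region = meta.get("scratch_region")
    return HeightMap(arr, px, tuple(region) if region else None)


def read_xps_csv(path, region: str = "") -> XPSSpectrum:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    ec = cols.get("binding_energy_ev") or cols.get("binding_energy")
    cc = cols.get("counts")
    if ec is None or cc is None:
        raise ValueError("XPS CSV needs columns binding_energy_eV,counts")
    return XPSSpectrum(df[ec].values, df[cc].values, region=region)
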
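"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its parameters and seed: repeated
calls are byte-identical. Randomness flows from one master seed through
named substreams (seed sequence keyed by a CRC of the generator name),
so stages can be regenerated independently without cross-coupling.

Noise models are the simplest consistent with how junction, titration,
AFM and XPS data present: log-normal scan-to-scan current dispersion,
Gaussian absorbance and height noise, Poisson X-ray counts.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Sequence

import numpy as np

from .jv import IVTrace, JVSummary, summarize_traces
from .surface import HeightMap, XPSSpectrum
from .titration import TitrationSeries
from .geometry import HeightDensityData
from .transport import TransportParams, current_per_molecule

__all__ = [
    "substream",
    "gen_jv_ensemble",
    "gen_loading_series",
    "gen_titration",
    "gen_height_map",
    "gen_xps",
    "gen_height_density",
]

DEFAULT_VOLTAGES = np.round(np.linspace(-1.0, 1.0, 41), 3)
# packing density matching 0.215 chains/nm^2
DEFAULT_PACKING_PER_CM2 = 0.215e14


def reference_hopping_params() -> TransportParams:
    """Reference heme-loaded (hopping) junction: a redox-active level
    close to the electrode Fermi energy (0.15 eV) with a modest
    reorganization energy (0.3 eV, a dry low-water SAM environment) and
    weak symmetric couplings — the resonance sits well inside the ±1 V
    sweep so all model parameters are identifiable from the curve."""
    return TransportParams("hopping", 0.15, 5e-3, 5e-3, lambda_reorg=0.3)


def reference_tunneling_params() -> TransportParams:
    """Reference heme-free (tunneling) junction: an off-resonant level
    at 0.4 eV with weak symmetric couplings."""
    return TransportParams("tunneling", 0.4, 5e-3, 5e-3)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def gen_jv_ensemble(
    model: TransportParams,
    noise_decades: float,
    n_scans: int = 70,
    voltages: np.ndarray | None = None,
    disorder_ev: float | None = None,
    pointwise_fraction: float = 0.25,
    packing_density_per_cm2: float = DEFAULT_PACKING_PER_CM2,
    log_offset: float = 0.0,
    seed: int = 0,
    name: str = "jv",
) -> list[IVTrace]:
    """Ensemble of scans with log-normal dispersion about a model curve.

    Per scan, log10|J| = model curve + scan offset ~ N(0, noise_decades)
    + pointwise noise ~ N(0, noise_decades*sqrt(pointwise_fraction)), so
    the total per-voltage SD is noise_decades*sqrt(1+pointwise_fraction).
    ``disorder_ev`` draws a per-scan perturbation of the level offset —
    site-energy disorder, to which thermally activated hopping ensembles
    are far more sensitive than tunneling ensembles (the current-spread
    heuristic).
    """
    if noise_decades < 0:
        raise ValueError("noise_decades must be >= 0")
    rng = substream(seed, name)
    V = DEFAULT_VOLTAGES if voltages is None else np.asarray(voltages, float)
    sgn = np.sign(V)
    base_params = model
    traces = []
    for i in range(n_scans):
        p = base_params
        if disorder_ev:
            p = p.with_(level_offset=base_params.level_offset
                        + disorder_ev * rng.standard_normal())
        J = np.abs(current_per_molecule(p, V, fast=True)) * packing_density_per_cm2
        with np.errstate(divide="ignore"):
            logJ = np.where(J > 0, np.log10(np.maximum(J, 1e-300)), -np.inf)
        logJ = logJ + log_offset + noise_decades * rng.standard_normal()
        logJ = logJ + (noise_decades * np.sqrt(pointwise_fraction)
                       * rng.standard_normal(V.size))
        Jn = np.where(np.isfinite(logJ), sgn * 10.0 ** logJ, 0.0)
        traces.append(IVTrace(V, Jn, scan_id=f"scan{i}",
                              location_id=f"loc{i % 7}"))
    return traces


def gen_loading_series(
    plateau_fold: float,
    half_saturation_ratio: float,
    ratios: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
    base_model: TransportParams | None = None,
    hill_n: float = 2.0,
    noise_decades: float = 0.1,
    n_scans: int = 70,
    voltages: np.ndarray | None = None,
    packing_density_per_cm2: float = DEFAULT_PACKING_PER_CM2,
    seed: int = 0,
) -> dict[float, JVSummary]:
    """J–V summaries keyed by heme:peptide loading ratio.

    The median |J| follows a saturating Hill-type multiplier between 1
    (no heme) and ``plateau_fold`` with half saturation at
    ``half_saturation_ratio`` — a 3-decade plateau reproduces the
    headline 1000-fold current enhancement as a pipeline property.
    """
    if plateau_fold < 1:
        raise ValueError("plateau_fold must be >= 1")
    if base_model is None:
        base_model = TransportParams("tunneling", 0.6, 2e-3, 2e-3)
    out = {}
    for j, r in enumerate(ratios):
        mult = 1.0 + (plateau_fold - 1.0) * r**hill_n / (
            half_saturation_ratio**hill_n + r**hill_n) if r > 0 else 1.0
        traces = gen_jv_ensemble(
            base_model, noise_decades, n_scans=n_scans, voltages=voltages,
            packing_density_per_cm2=packing_density_per_cm2,
            log_offset=np.log10(mult), seed=seed, name=f"loading/{j}")
        out[float(r)] = summarize_traces(traces)
    return out


def gen_titration(
    breakpoint: float,
    slope_low: float,
    slope_high: float,
    noise_sd: float,
    n: int = 12,
    ratio_max: float = 2.0,
    intercept: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Absorbance-vs-ratio series: continuous piecewise-linear mean plus
    Gaussian noise. Equal slopes give the linear (no-histidine) analog."""
    if n < 6:
        raise ValueError("need n >= 6 titration points")
    rng = substream(seed, "titration")
    x = np.linspace(0.0, ratio_max, n)
    mean = intercept + slope_low * np.minimum(x, breakpoint) + slope_high * np.maximum(
        x - breakpoint, 0.0)
    return TitrationSeries(x, mean + noise_sd * rng.standard_normal(n))


def gen_height_map(
    thickness: float = 3.0,
    roughness_sd: float = 0.2,
    tilt: tuple[float, float] = (0.0, 0.0),
    scratch_rect: tuple[int, int, int, int] = (48, 80, 48, 80),
    shape: tuple[int, int] = (128, 128),
    pixel_size_nm: float = 4.0,
    seed: int = 0,
) -> HeightMap:
    """Stepped AFM-like height map: film plane at ``thickness`` with
    Gaussian roughness, a rectangular scratch down to the substrate, and
    an optional plane tilt (nm across the full field in row/col)."""
    r0, r1, c0, c1 = scratch_rect
    nr, nc = shape
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise ValueError("scratch_rect outside map bounds")
    rng = substream(seed, "height_map")
    h = np.full(shape, float(thickness))
    h[r0:r1, c0:c1] = 0.0
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    h = h + tilt[0] * rr / max(nr - 1, 1) + tilt[1] * cc / max(nc - 1, 1)
    h = h + roughness_sd * rng.standard_normal(shape)
    return HeightMap(h, pixel_size_nm, scratch_region=(r0, r1, c0, c1))


def gen_xps(
    peaks: Sequence[Mapping[str, float]],
    background: Mapping[str, float] | None = None,
    energy: np.ndarray | None = None,
    poisson: bool = True,
    region: str = "",
    seed: int = 0,
    name: str = "xps",
) -> XPSSpectrum:
    """Gaussian peaks {center, amplitude, sd} on a linear background
    {slope, intercept}, optionally Poisson-sampled as X-ray counts."""
    if energy is None:
        energy = np.arange(150.0, 175.0, 0.05)
    energy = np.asarray(energy, float)
    y = np.zeros_like(energy)
    if background:
        y = y + background.get("intercept", 0.0) + background.get("slope", 0.0) * energy
    for p in peaks:
        if not energy.min() <= p["center"] <= energy.max():
            raise ValueError(f"peak center {p['center']} outside energy grid")
        y = y + p["amplitude"] * np.exp(
            -0.5 * ((energy - p["center"]) / p["sd"]) ** 2)
    if poisson:
        rng = substream(seed, name)
        y = rng.poisson(np.maximum(y, 0.0)).astype(float)
    return XPSSpectrum(energy, y, region=region)


def gen_height_density(
    slope: float = 8.0,
    intercept: float = 1.3,
    n_helix_levels: Sequence[int] = (10, 15, 20, 25, 30),
    area_nm2: float = 100.0,
    replicas: int = 3,
    sd_at_low: float = 0.3,
    seed: int = 0,
) -> list[HeightDensityData]:
    """Height–packing-density observations around a known line.

    Heights are drawn as N(slope*d_p + intercept, var(d_p)) with the
    variance decreasing in d_p (sd = sd_at_low * (d_min/d_p)): lower
    packing densities give broader height distributions, as the replica
    spread of the simulated monolayers shows.
    """
    rng = substream(seed, "height_density")
    d_min = min(n_helix_levels) / area_nm2
    out = []
    for n_helix in n_helix_levels:
        d_p = n_helix / area_nm2
        sd = sd_at_low * (d_min / d_p)
        for rep in range(replicas):
            h = slope * d_p + intercept + sd * rng.standard_normal()
            out.append(HeightDensityData(
                packing_density=d_p, height_mean=float(h),
                # strictly positive variance even for noiseless draws
                height_var=float(max(sd**2, 1e-18)),
                replica_id=f"rep{rep}", n_helix=int(n_helix)))
    return out
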
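"""Aggregation and model fitting of multi-scan junction J–V data.

EGaIn-style junction measurements are log-normal-like across scans and
locations, with occasional shorted or compliance-limited traces, so all
cross-scan statistics here are medians and quantiles of log10|J| rather
than means. Transport-model fits are performed in log10|J| space on the
median curve (the data span decades; linear-space residuals would be
dominated by the largest currents).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .transport import TransportParams, current_per_molecule

__all__ = [
    "IVTrace",
    "JVSummary",
    "FitResult",
    "ModelSelection",
    "summarize_traces",
    "fit_model",
    "compare_models",
    "spread_statistic",
    "enhancement_ratio",
    "loading_curve",
    "read_traces_csv",
    "write_traces_csv",
]


@dataclass
class IVTrace:
    """One voltage sweep at one junction location (signed J in A/cm^2)."""

    voltages: np.ndarray
    current_density: np.ndarray
    scan_id: str = "scan0"
    location_id: str = "loc0"
    contact_area_um2: float | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, float)
        self.current_density = np.asarray(self.current_density, float)
        if self.voltages.shape != self.current_density.shape:
            raise ValueError("voltages and current_density must have equal length")

    def log_abs_at(self, V: float | np.ndarray) -> np.ndarray:
        """log10|J| linearly interpolated at V (NaN where |J| = 0)."""
        order = np.argsort(self.voltages)
        absJ = np.interp(V, self.voltages[order], np.abs(self.current_density)[order])
        with np.errstate(divide="ignore"):
            return np.where(absJ > 0, np.log10(np.maximum(absJ, 1e-300)), np.nan)


@dataclass
class JVSummary:
    """Per-voltage median and 25/75 percentiles of log10|J| across scans."""

    voltages: np.ndarray
    median_logJ: np.ndarray
    pct25_logJ: np.ndarray
    pct75_logJ: np.ndarray
    n_scans: int
    n_censored: np.ndarray | None = None  # zeros excluded per voltage

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")

    def at(self, V: float, interpolate: bool = True) -> float:
        """median log10|J| at V (interpolated if off-grid)."""
        idx = np.where(np.isclose(self.voltages, V))[0]
        if idx.size:
            return float(self.median_logJ[idx[0]])
        if not interpolate:
            raise KeyError(f"V={V} not on summary grid")
        if V < self.voltages.min() or V > self.voltages.max():
            raise ValueError(f"V={V} outside summary range; refusing to extrapolate")
        ok = np.isfinite(self.median_logJ)
        return float(np.interp(V, self.voltages[ok], self.median_logJ[ok]))


def summarize_traces(
    traces: Sequence[IVTrace], grid: np.ndarray | None = None
) -> JVSummary:
    """Median and 25–75 percentile summary of log10|J| over scans.

    Traces are aligned by linear interpolation onto ``grid`` (default:
    the first trace's voltage grid; no extrapolation beyond each trace's
    range is attempted since all traces share the sweep protocol). Exact
    zeros are excluded from the quantiles and counted as censored.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    if grid is None:
        grid = np.sort(np.unique(traces[0].voltages))
    logJ = np.vstack([t.log_abs_at(grid) for t in traces])  # (scan, V)
    n_censored = np.sum(~np.isfinite(logJ), axis=0)
    if np.any(n_censored == len(traces)):
        warnings.warn("all scans censored (|J|=0) at some voltages; "
                      "summary is NaN there", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(logJ, axis=0)
        p25 = np.nanpercentile(logJ, 25, axis=0)
        p75 = np.nanpercentile(logJ, 75, axis=0)
    return JVSummary(grid, med, p25, p75, n_scans=len(traces), n_censored=n_censored)


@dataclass
class FitResult:
    """Outcome of a transport-model fit to a J–V summary."""

    params: TransportParams
    packing_density_per_cm2: float
    residual_norm: float      # RMSE in log10 units
    aic: float
    bic: float
    param_se: dict
    converged: bool
    n_points: int = 0
    n_free: int = 0
    message: str = ""


_FIT_BOUNDS = {
    "level_offset": (0.05, 1.5),
    "log10_gamma": (-4.5, -0.5),
    # reorganization energies below ~0.1 eV are unphysical for
    # condensed-phase outer-sphere transfer; cap at 2 eV
    "log10_lambda": (-1.0, 0.301),
}


def _model_logJ(mechanism, x, voltages, eta, T, density):
    if mechanism == "hopping":
        p = TransportParams("hopping", x[0], 10.0 ** x[1], 10.0 ** x[2],
                            lambda_reorg=10.0 ** x[3], eta=eta, temperature=T)
    else:
        p = TransportParams("tunneling", x[0], 10.0 ** x[1], 10.0 ** x[2],
                            eta=eta, temperature=T)
    J = np.abs(current_per_molecule(p, voltages, fast=True)) * density
    with np.errstate(divide="ignore"):
        return np.log10(np.maximum(J, 1e-300))


def fit_model(
    summary: JVSummary,
    mechanism: Literal["hopping", "tunneling"],
    packing_density_per_cm2: float,
    init: TransportParams | None = None,
    eta: float = 0.5,
    temperature: float = 298.0,
    v_exclude: float = 0.05,
    n_starts: int | None = None,
) -> FitResult:
    """Nonlinear least squares of model log10|J| against the median curve.

    Couplings and (for hopping) the reorganization energy are fitted on a
    log10 scale inside physical bounds; a small multistart grid guards
    against local minima. Free parameters: tunneling 3 (level offset and
    the two couplings), hopping 4 (adds lambda); ``eta`` is held fixed.
    """
    grid_ok = np.abs(summary.voltages) >= v_exclude
    gv = summary.voltages[grid_ok]
    if gv.size < 8 or gv.min() >= 0 or gv.max() <= 0:
        raise ValueError("need >=8 grid points spanning both polarities")
    ok = np.isfinite(summary.median_logJ) & grid_ok
    V = summary.voltages[ok]
    y = summary.median_logJ[ok]
    n = V.size
    k = 4 if mechanism == "hopping" else 3
    degenerate = (n < 8 or V.size == 0 or V.min() >= 0 or V.max() <= 0
                  or np.ptp(y) == 0)
    if degenerate:
        return FitResult(
            params=init or TransportParams(mechanism, 0.5, 1e-3, 1e-3,
                                           lambda_reorg=0.5 if k == 4 else None,
                                           eta=eta, temperature=temperature),
            packing_density_per_cm2=packing_density_per_cm2,
            residual_norm=np.inf, aic=np.inf, bic=np.inf, param_se={},
            converged=False, n_points=n, n_free=k,
            message="degenerate (flat or empty) summary",
        )

    def resid(x):
        return _model_logJ(mechanism, x, V, eta, temperature,
                           packing_density_per_cm2) - y

    lo = [_FIT_BOUNDS["level_offset"][0], *[_FIT_BOUNDS["log10_gamma"][0]] * 2]
    hi = [_FIT_BOUNDS["level_offset"][1], *[_FIT_BOUNDS["log10_gamma"][1]] * 2]
    if k == 4:
        lo.append(_FIT_BOUNDS["log10_lambda"][0])
        hi.append(_FIT_BOUNDS["log10_lambda"][1])

    starts = []
    if init is not None:
        s = [init.level_offset, np.log10(init.gamma_l), np.log10(init.gamma_r)]
        if k == 4:
            s.append(np.log10(init.lambda_reorg))
        starts.append(s)
    de_grid = (0.2, 0.4, 0.7) if n_starts is None else (0.3, 0.6)[: max(1, n_starts)]
    for de in de_grid:
        s = [de, -2.5, -2.5]
        if k == 4:
            s.append(np.log10(0.5))
        starts.append(s)

    best = None
    for s in starts:
        try:
            sol = least_squares(resid, s, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return FitResult(
            params=TransportParams(mechanism, 0.5, 1e-3, 1e-3,
                                   lambda_reorg=0.5 if k == 4 else None,
                                   eta=eta, temperature=temperature),
            packing_density_per_cm2=packing_density_per_cm2,
            residual_norm=np.inf, aic=np.inf, bic=np.inf, param_se={},
            converged=False, n_points=n, n_free=k, message="no converged start",
        )
    x = best.x
    rss = 2.0 * best.cost
    rmse = float(np.sqrt(rss / n))
    # Gaussian log-space likelihood
    aic = n * np.log(max(rss / n, 1e-300)) + 2 * k
    bic = n * np.log(max(rss / n, 1e-300)) + k * np.log(n)
    # parameter covariance from the Jacobian at the optimum
    se = {}
    try:
        J = best.jac
        s2 = rss / max(n - k, 1)
        cov = s2 * np.linalg.pinv(J.T @ J)
        names = ["level_offset", "log10_gamma_l", "log10_gamma_r"]
        if k == 4:
            names.append("log10_lambda")
        se = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    except Exception:
        pass
    params = TransportParams(
        mechanism, float(x[0]), float(10.0 ** x[1]), float(10.0 ** x[2]),
        lambda_reorg=float(10.0 ** x[3]) if k == 4 else None,
        eta=eta, temperature=temperature,
    )
    return FitResult(params, packing_density_per_cm2, rmse, float(aic), float(bic),
                     se, converged=True, n_points=n, n_free=k,
                     message=best.message)


@dataclass
class ModelSelection:
    """AIC-based preference between hopping and tunneling fits."""

    preferred: Literal["hopping", "tunneling", "tie", "inconclusive"]
    delta_aic: float              # aic_hopping - aic_tunneling
    residual_hopping: float
    residual_tunneling: float


def compare_models(fit_h: FitResult, fit_t: FitResult) -> ModelSelection:
    """Prefer the mechanism with lower AIC; withhold if either fit failed."""
    if not (fit_h.converged and fit_t.converged):
        return ModelSelection("inconclusive", np.nan,
                              fit_h.residual_norm, fit_t.residual_norm)
    d = fit_h.aic - fit_t.aic
    if d == 0.0:
        pref = "tie"
    else:
        pref = "hopping" if d < 0 else "tunneling"
    return ModelSelection(pref, float(d), fit_h.residual_norm, fit_t.residual_norm)


def spread_statistic(
    traces: Sequence[IVTrace], V: float, inner: float = 0.90
) -> float:
    """Decades of |J| spanned across scans at bias V.

    Robust spread: the central ``inner`` inter-quantile range (default
    5th–95th percentile) of log10|J| at the query voltage. Hopping
    ensembles with site-energy disorder show a much broader spread than
    tunneling ensembles — the mechanism heuristic this statistic serves.
    """
    if len(traces) < 10:
        warnings.warn("fewer than 10 traces: spread estimate has wide "
                      "uncertainty", stacklevel=2)
    vals = np.array([t.log_abs_at(V) for t in traces], float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite currents at this voltage")
    a = (1.0 - inner) / 2.0
    return float(np.quantile(vals, 1 - a) - np.quantile(vals, a))


@dataclass
class EnhancementResult:
    ratio: float
    ci_low: float
    ci_high: float
    V: float


def enhancement_ratio(
    summary_a: JVSummary, summary_b: JVSummary, V: float = -1.0
) -> EnhancementResult:
    """Fold change of median |J| of a over b at bias V.

    The uncertainty interval propagates each summary's interquartile
    range to a standard error of the median (IQR/1.349/sqrt(n)) and
    combines them in quadrature; exact reciprocity
    ``ratio(a,b)*ratio(b,a) == 1`` holds by construction.
    """
    ma, mb = summary_a.at(V), summary_b.at(V)

    def med_se(s: JVSummary) -> float:
        idx = int(np.argmin(np.abs(s.voltages - V)))
        iqr = s.pct75_logJ[idx] - s.pct25_logJ[idx]
        return 1.2533 * iqr / 1.349 / np.sqrt(s.n_scans)

    d = ma - mb
    se = float(np.hypot(med_se(summary_a), med_se(summary_b)))
    return EnhancementResult(10.0 ** d, 10.0 ** (d - 1.96 * se),
                             10.0 ** (d + 1.96 * se), V)


@dataclass
class HillFit:
    plateau_fold: float
    half_saturation: float
    hill_n: float
    converged: bool


def loading_curve(
    summaries: Mapping[float, JVSummary], V: float = -1.0, hill: bool = True
) -> tuple[pd.DataFrame, HillFit | None]:
    """Median |J| versus heme:peptide loading ratio at bias V.

    Returns a ratio-sorted table (duplicates aggregated by mean of the
    median log10|J|, with a note) and, optionally, a saturating Hill-type
    fit of the fold enhancement over the lowest ratio.
    """
    if len(summaries) < 2:
        raise ValueError("need summaries at >=2 loading ratios")
    rows = []
    for r, s in summaries.items():
        idx = int(np.argmin(np.abs(s.voltages - V)))
        rows.append({"ratio": float(r), "median_logJ": s.at(V),
                     "pct25_logJ": float(s.pct25_logJ[idx]),
                     "pct75_logJ": float(s.pct75_logJ[idx]),
                     "n_scans": s.n_scans})
    df = pd.DataFrame(rows)
    dup = df["ratio"].duplicated().any()
    df = (df.groupby("ratio", as_index=False)
            .agg({"median_logJ": "mean", "pct25_logJ": "mean",
                  "pct75_logJ": "mean", "n_scans": "sum"})
            .sort_values("ratio", ignore_index=True))
    df.attrs["note"] = "duplicate ratios aggregated" if dup else ""
    df["abs_J"] = 10.0 ** df["median_logJ"]

    fit = None
    if hill:
        base = df["median_logJ"].iloc[0]

        def model(r, logF, logK, h):
            F, K = 10.0 ** logF, 10.0 ** logK
            return base + np.log10(1.0 + (F - 1.0) * r**h / (K**h + r**h))

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, df["ratio"].values, df["median_logJ"].values,
                    p0=[2.0, 0.0, 2.0],
                    bounds=([0.0, -2.0, 0.5], [8.0, 1.5, 6.0]), maxfev=5000)
            fit = HillFit(float(10.0 ** popt[0]), float(10.0 ** popt[1]),
                          float(popt[2]), True)
        except Exception:
            fit = HillFit(np.nan, np.nan, np.nan, False)
    return df, fit


# -- CSV interfaces (long format: scan_id,location_id,voltage_V,
#    current_density_A_per_cm2) -------------------------------------------

def read_traces_csv(path) -> list[IVTrace]:
    df = pd.read_csv(path)
    req = {"scan_id", "voltage_V", "current_density_A_per_cm2"}
    if not req.issubset(df.columns):
        raise ValueError(f"traces CSV must have columns {sorted(req)}")
    if "location_id" not in df.columns:
        df["location_id"] = "loc0"
    out = []
    for (sid, lid), g in df.groupby(["scan_id", "location_id"], sort=False):
        out.append(IVTrace(g["voltage_V"].values,
                           g["current_density_A_per_cm2"].values,
                           scan_id=str(sid), location_id=str(lid)))
    return out


def write_traces_csv(traces: Sequence[IVTrace], path) -> None:
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "scan_id": t.scan_id, "location_id": t.location_id,
            "voltage_V": t.voltages,
            "current_density_A_per_cm2": t.current_density}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
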
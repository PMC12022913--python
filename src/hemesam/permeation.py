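"""Coarse-grained 1-D Langevin model of heme permeation into a peptide
monolayer with reversible histidine coordination.

The atomistic picture — heme molecules released above a peptide SAM,
diffusing down, and reversibly ligating histidine epsilon-nitrogens
through a Morse potential while excluded-volume walls confine them to
the box — is reduced to one dimension along the membrane normal: the
observables of interest are z-distributions over time, so lateral
structure is absorbed into a crowding barrier that grows with depth
inside the monolayer. Particles are independent (no heme–heme
interaction, the anti-aggregation control made structural), counts are
conserved exactly, and both walls reflect.

Sequence analogs differ only in their coordination-site depths:
PHH shallow+deep, PAH shallow only, PHA deep only, PAA none. Time is in
simulation units; no mapping to experimental hours or atomistic
microseconds is implied.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MorseParams", "PermeationConfig", "Trajectory", "PermeationProfile",
    "BondEvent", "morse_energy", "simulate_permeation",
    "detect_coordination", "permeation_profile", "bound_fraction",
    "nonspecific_contacts", "SEQUENCE_SITES", "config_for_sequence",
]

# site depths (nm) for the four sequence analogs: shallow sites sit just
# under the monolayer top, deep sites near the substrate-proximal third
SEQUENCE_SITES = {
    "PHH": (2.5, 1.0),
    "PAH": (2.5,),
    "PHA": (1.0,),
    "PAA": (),
}


@dataclass(frozen=True)
class MorseParams:
    """Reversible coordination bond: well depth (kT units), inverse
    width (1/nm), equilibrium offset (nm).

    In the 1-D normal coordinate the separation r = |z - z_site| passes
    through zero, so the 3-D Fe–N equilibrium bond length collapses into
    the site position and the default offset is r_e = 0 (a nonzero r_e
    would place a steep repulsive spike exactly at the site). The well
    depth default gives reversible binding on simulable time scales.
    """

    D_e: float = 6.0
    a: float = 20.0
    r_e: float = 0.0

    def max_force(self) -> float:
        """Largest |dU/dr| over r >= 0 (kT/nm), for stability checks."""
        e0 = np.exp(self.a * self.r_e)
        peak = max(0.25, e0 * abs(e0 - 1.0))
        return 2.0 * self.D_e * self.a * peak


def morse_energy(r, morse: MorseParams):
    """Morse potential D_e[(1 - e^{-a(r-r_e)})^2 - 1], zero at infinite
    separation, minimum -D_e at r = r_e; harmonic near the minimum with
    curvature 2*D_e*a^2."""
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("separation must be >= 0")
    e = np.exp(-morse.a * (r - morse.r_e))
    out = morse.D_e * ((1.0 - e) ** 2 - 1.0)
    return float(out) if out.ndim == 0 else out


def _morse_force(dz, morse: MorseParams):
    """-dU/dz for signed displacement dz = z - z_site."""
    r = np.abs(dz)
    e = np.exp(-morse.a * (r - morse.r_e))
    dU_dr = 2.0 * morse.D_e * morse.a * e * (1.0 - e)
    return -np.sign(dz) * dU_dr


@dataclass
class PermeationConfig:
    """Specification of one coarse-grained permeation run.

    The crowding barrier is piecewise linear through ``barrier_knots``
    [(z, U/kT), ...] and flat outside their range; the default ramps
    from ``barrier_height`` at the substrate to zero at the monolayer
    top — deeper means more crowded.
    """

    n_heme: int = 30
    box_height: float = 6.0          # nm
    monolayer_top: float = 3.0       # nm
    his_depths: tuple[float, ...] = SEQUENCE_SITES["PHH"]
    morse: MorseParams = field(default_factory=MorseParams)
    barrier_height: float = 4.0      # kT at z=0
    barrier_knots: tuple[tuple[float, float], ...] | None = None
    kT: float = 1.0
    friction: float = 1.0            # zeta; D = kT/zeta
    dt: float = 1e-4
    n_steps: int = 100_000
    save_every: int = 100
    n_replicas: int = 3
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_heme <= 0:
            raise ValueError("n_heme must be > 0")
        if not 0 < self.monolayer_top < self.box_height:
            raise ValueError("need 0 < monolayer_top < box_height")
        if self.barrier_knots is None:
            self.barrier_knots = ((0.0, self.barrier_height),
                                  (self.monolayer_top, 0.0))
        # overdamped stability: the deterministic step must stay well
        # below the Morse width and the site spacing
        fmax = ((self.morse.max_force() if self.his_depths else 0.0)
                + self._barrier_fmax())
        step = self.dt * fmax * self.kT / self.friction
        limit = 0.25 / self.morse.a
        if step > limit:
            raise ValueError(
                f"unstable time step: max drift {step:.3g} nm exceeds "
                f"{limit:.3g} nm; use dt <= {self.dt * limit / step:.2e}")

    def _barrier_fmax(self) -> float:
        zs = [z for z, _ in self.barrier_knots]
        us = [u for _, u in self.barrier_knots]
        sl = [abs((us[i + 1] - us[i]) / (zs[i + 1] - zs[i]))
              for i in range(len(zs) - 1) if zs[i + 1] != zs[i]]
        return max(sl, default=0.0)

    def _knot_arrays(self):
        if not hasattr(self, "_kz"):
            self._kz = np.array([z0 for z0, _ in self.barrier_knots])
            self._ku = np.array([u for _, u in self.barrier_knots])
            self._kslope = np.diff(self._ku) / np.diff(self._kz)
        return self._kz, self._ku, self._kslope

    def barrier_energy(self, z):
        zs, us, _ = self._knot_arrays()
        return np.interp(z, zs, us)

    def barrier_force(self, z):
        zs, _, slopes = self._knot_arrays()
        idx = np.clip(np.searchsorted(zs, z, side="right") - 1, 0,
                      len(slopes) - 1)
        inside = (z > zs[0]) & (z < zs[-1])
        return np.where(inside, -slopes[idx], 0.0)

    def total_energy(self, z):
        """U(z)/kT including crowding barrier and all Morse sites."""
        z = np.asarray(z, float)
        U = self.barrier_energy(z).astype(float)
        for zs in self.his_depths:
            U = U + morse_energy(np.abs(z - zs), self.morse)
        return U

    def hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()
                   if k != "morse" and not k.startswith("_")}
        payload["morse"] = self.morse.__dict__
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def config_for_sequence(sequence: str, **kw) -> PermeationConfig:
    """Preset config for one of the PHH/PAH/PHA/PAA analogs."""
    if sequence not in SEQUENCE_SITES:
        raise ValueError(f"unknown sequence {sequence!r}")
    return PermeationConfig(his_depths=SEQUENCE_SITES[sequence],
                            label=sequence, **kw)


@dataclass
class Trajectory:
    """Particle z time series from one replica."""

    times: np.ndarray                # (n_frames,)
    z: np.ndarray                    # (n_particles, n_frames), nm
    replica_id: str
    config: PermeationConfig
    bound_site: np.ndarray | None = None  # (n_particles, n_frames), -1 = free


def _reflect(z, box):
    z = np.abs(z)
    z = box - np.abs(box - z)
    return np.clip(z, 0.0, box)  # guards pathological multi-fold steps


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


@njit(cache=False)
def _advance(z, noise, mob, kTbar, kz, ku, kslope, sites, De, a, re,
             box, saved, save_every, frame0):
    n = z.shape[0]
    n_steps = noise.shape[0]
    frame = frame0
    for step in range(n_steps):
        for p in range(n):
            zp = z[p]
            # piecewise-linear crowding barrier force (kT units -> kT/nm)
            F = 0.0
            if kz[0] < zp < kz[-1]:
                k = 0
                while k < kslope.shape[0] - 1 and zp >= kz[k + 1]:
                    k += 1
                F = -kslope[k]
            # Morse coordination sites
            for s in range(sites.shape[0]):
                dz = zp - sites[s]
                r = abs(dz)
                e = np.exp(-a * (r - re))
                dU = 2.0 * De * a * e * (1.0 - e)
                if dz > 0.0:
                    F -= dU
                elif dz < 0.0:
                    F += dU
            zp = zp + mob * F * kTbar + noise[step, p]
            # reflecting walls
            if zp < 0.0:
                zp = -zp
            if zp > box:
                zp = 2.0 * box - zp
            if zp < 0.0:
                zp = 0.0
            elif zp > box:
                zp = box
            z[p] = zp
        if (step + 1) % save_every == 0:
            for p in range(n):
                saved[p, frame] = z[p]
            frame += 1
    return frame


def simulate_permeation(config: PermeationConfig) -> list[Trajectory]:
    """Run all replicas of the overdamped Langevin model.

    Update per particle: ``z += dt*F/zeta + sqrt(2*kT*dt/zeta)*xi`` with
    reflecting walls at z=0 and z=box_height. Particles start uniformly
    in the solution layer above the monolayer and never interact with
    each other, so the count is conserved trivially and exactly. Each
    replica draws from its own seeded stream; the Gaussian increments
    are pre-generated in chunks so results are independent of the
    compiled integrator's internals.
    """
    c = config
    sites = np.asarray(c.his_depths, float)
    sigma = np.sqrt(2.0 * c.kT * c.dt / c.friction)
    mob = c.dt / c.friction
    n_frames = c.n_steps // c.save_every + 1
    kz, ku, kslope = c._knot_arrays()
    if kslope.size == 0:
        kz, kslope = np.array([0.0, c.box_height]), np.array([0.0])
    chunk = max(c.save_every, 20_000 // max(c.n_heme // 30, 1))
    chunk -= chunk % c.save_every
    out = []
    for rep in range(c.n_replicas):
        rng = np.random.default_rng(
            np.random.SeedSequence([c.seed & 0x7FFFFFFF, rep]))
        z = rng.uniform(c.monolayer_top, c.box_height, size=c.n_heme)
        zs = np.empty((c.n_heme, n_frames))
        zs[:, 0] = z
        frame = 1
        done = 0
        while done < c.n_steps:
            nsub = min(chunk, c.n_steps - done)
            noise = sigma * rng.standard_normal((nsub, c.n_heme))
            frame = _advance(z, noise, mob, c.kT, kz, ku, kslope, sites,
                             c.morse.D_e, c.morse.a, c.morse.r_e,
                             c.box_height, zs, c.save_every, frame)
            done += nsub
        times = np.arange(n_frames) * c.save_every * c.dt
        out.append(Trajectory(times, zs, replica_id=f"rep{rep}", config=c))
    return out


@dataclass
class BondEvent:
    particle: int
    site: int
    t_form: float
    t_rupture: float | None  # None if still bound at the end


def detect_coordination(
    traj: Trajectory, capture_r: float = 0.3, release_r: float = 0.5
) -> list[BondEvent]:
    """Hysteretic bond bookkeeping on a saved trajectory.

    A free particle binds a site when |z - z_site| < capture_r (and the
    site is unoccupied — one heme per histidine, first come first
    served); a bound particle unbinds when the distance exceeds
    release_r. The capture/release gap suppresses chattering. Fills
    ``traj.bound_site`` in place and returns the event list.
    """
    if release_r <= capture_r:
        raise ValueError("release_r must exceed capture_r (hysteresis)")
    sites = np.asarray(traj.config.his_depths, float)
    n, nf = traj.z.shape
    bound = np.full((n, nf), -1, dtype=int)
    state = np.full(n, -1, dtype=int)
    occupied = np.full(len(sites), -1, dtype=int)  # particle index or -1
    open_events: dict[int, BondEvent] = {}
    events: list[BondEvent] = []
    for f in range(nf):
        zf = traj.z[:, f]
        # ruptures first
        for p in np.where(state >= 0)[0]:
            s = state[p]
            if abs(zf[p] - sites[s]) > release_r:
                ev = open_events.pop(p)
                ev.t_rupture = float(traj.times[f])
                events.append(ev)
                occupied[s] = -1
                state[p] = -1
        # formations
        if len(sites):
            free = np.where(state < 0)[0]
            if free.size:
                d = np.abs(zf[free][:, None] - sites[None, :])
                for i, p in enumerate(free):
                    close = np.where(d[i] < capture_r)[0]
                    for s in close[np.argsort(d[i][close])]:
                        if occupied[s] < 0:
                            occupied[s] = p
                            state[p] = s
                            open_events[p] = BondEvent(
                                int(p), int(s), float(traj.times[f]), None)
                            break
        bound[:, f] = state
    events.extend(open_events.values())
    traj.bound_site = bound
    return events


@dataclass
class PermeationProfile:
    """Replica mean ± SD z-histograms per time window (counts per frame,
    integrating to n_heme) plus the histidine-site band."""

    window_edges: np.ndarray         # (n_windows+1,) times
    bin_edges: np.ndarray            # (n_bins+1,) z
    mean: np.ndarray                 # (n_windows, n_bins)
    sd: np.ndarray                   # (n_windows, n_bins)
    his_band: tuple[float, float] | None  # (mean, sd) of site depths


def permeation_profile(
    trajs: Sequence[Trajectory], n_windows: int = 4, n_bins: int = 40
) -> PermeationProfile:
    """Time-windowed z-distributions averaged over replicas."""
    if not trajs:
        raise ValueError("need >= 1 replica")
    box = trajs[0].config.box_height
    if any(abs(t.config.box_height - box) > 1e-12 for t in trajs):
        raise ValueError("replicas have inconsistent box heights")
    t_end = trajs[0].times[-1]
    wedges = np.linspace(0.0, t_end, n_windows + 1)
    bedges = np.linspace(0.0, box, n_bins + 1)
    per_rep = np.empty((len(trajs), n_windows, n_bins))
    for r, tr in enumerate(trajs):
        for w in range(n_windows):
            sel = (tr.times >= wedges[w]) & (tr.times <= wedges[w + 1])
            zw = tr.z[:, sel]
            counts, _ = np.histogram(zw, bins=bedges)
            per_rep[r, w] = counts / max(sel.sum(), 1)
    sites = np.asarray(trajs[0].config.his_depths, float)
    band = ((float(sites.mean()), float(sites.std())) if sites.size else None)
    return PermeationProfile(wedges, bedges, per_rep.mean(axis=0),
                             per_rep.std(axis=0), band)


def bound_fraction(trajs: Sequence[Trajectory]):
    """Replica-averaged occupancy time series.

    Returns (times, site_occupancy_mean, heme_bound_mean, site_sd,
    heme_sd): the fraction of sites occupied and the fraction of hemes
    bound at each frame. Runs coordination detection on any trajectory
    that lacks it. With no sites the series are identically zero.
    """
    times = trajs[0].times
    n_sites = len(trajs[0].config.his_depths)
    so, hb = [], []
    for tr in trajs:
        if tr.bound_site is None:
            detect_coordination(tr)
        nb = (tr.bound_site >= 0).sum(axis=0)
        hb.append(nb / tr.z.shape[0])
        so.append(nb / n_sites if n_sites else np.zeros_like(times))
    so, hb = np.array(so), np.array(hb)
    return (times, so.mean(axis=0), hb.mean(axis=0),
            so.std(axis=0), hb.std(axis=0))


def nonspecific_contacts(
    trajs: Sequence[Trajectory], monolayer_top: float | None = None
):
    """Replica-averaged count of hemes inside the monolayer slab that
    are not coordinated to any site. Returns (times, mean, sd)."""
    times = trajs[0].times
    top = (trajs[0].config.monolayer_top
           if monolayer_top is None else monolayer_top)
    counts = []
    for tr in trajs:
        if tr.bound_site is None:
            detect_coordination(tr)
        inside = tr.z < top
        unbound = tr.bound_site < 0
        counts.append((inside & unbound).sum(axis=0))
    counts = np.array(counts, float)
    return times, counts.mean(axis=0), counts.std(axis=0)


def write_trajectories_csv(trajs: Sequence[Trajectory], path) -> None:
    """Long-format CSV: replica,frame,time,particle,z_nm,bound_site."""
    import pandas as pd

    rows = []
    for tr in trajs:
        n, nf = tr.z.shape
        bs = tr.bound_site if tr.bound_site is not None else np.full((n, nf), -1)
        for f in range(nf):
            for p in range(n):
                rows.append((tr.replica_id, f, tr.times[f], p,
                             tr.z[p, f], bs[p, f]))
    pd.DataFrame(rows, columns=["replica", "frame", "time", "particle",
                                "z_nm", "bound_site"]).to_csv(path, index=False)


def read_trajectories_csv(path, config: PermeationConfig) -> list[Trajectory]:
    """Ingest externally produced z-tables in the same schema (e.g. z
    coordinates extracted upstream from MD trajectories)."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for rid, g in df.groupby("replica", sort=False):
        piv = g.pivot_table(index="particle", columns="frame", values="z_nm")
        times = g.groupby("frame")["time"].first().values
        out.append(Trajectory(times, piv.values, replica_id=str(rid),
                              config=config))
    return out
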
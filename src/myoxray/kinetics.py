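"""Strain-dependent three-state crossbridge cycle and the isometric
Monte Carlo driver.

States: 1 detached, 2 weakly attached (pre-stroke), 3 post-stroke.  Free
energies in kBT units at crossbridge strain-coordinate x = z_crown - z_site:

    G1 = 0
    G2(x) = dG_bind + kappa x^2 / (2 kBT)
    G3(x) = dG_bind + dG_stroke + kappa (x + d)^2 / (2 kBT)

so the post-stroke spring is unstrained when the actin site sits one stroke
length d beyond the crown toward the M-band, which is what makes a stroked
head pull actin toward the sarcomere centre.  Transition rates follow the
Duke-style forms (Gaussian-weighted attachment, sigmoidal stroke rate capped
at k23cap, strain-accelerated ADP release for negatively strained post-stroke
heads); whenever a cap engages, the partner rate is recomputed from the
equilibrium constant so detailed balance k_ij/k_ji = exp(-dG_ij) holds at
every strain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .lattice import Attachment, LatticeState, build_half_sarcomere
from .mechanics import _arrays_from_lattice, _engine_scalars
from .params import RateParams, SimulationConfig

__all__ = [
    "RateSet",
    "state_free_energy",
    "transition_rates",
    "mc_update",
    "run_isometric",
    "bound_fraction",
    "SimulationTrace",
]

_EVENT_NAMES = {
    _engine.EV_BIND: "bind",
    _engine.EV_UNBIND: "unbind",
    _engine.EV_STROKE: "stroke",
    _engine.EV_REVERSE: "reverse_stroke",
    _engine.EV_RELEASE: "release",
}


@dataclass(frozen=True)
class RateSet:
    """The six transition rates (s^-1) evaluated at one strain or an array
    of strains."""

    k12: np.ndarray
    k21: np.ndarray
    k23: np.ndarray
    k32: np.ndarray
    k31: np.ndarray
    k13: np.ndarray


def state_free_energy(state, x, params: RateParams, kappa_xb: float):
    """Free energy of a crossbridge state at strain-coordinate x (kBT units)."""
    x = np.asarray(x, dtype=float)
    if state == 1:
        return np.zeros_like(x) if x.ndim else 0.0
    if state == 2:
        g = params.dG_bind_kBT + kappa_xb * x ** 2 / (2.0 * params.kBT_pN_nm)
    elif state == 3:
        g = (params.dG_bind_kBT + params.dG_stroke_kBT
             + kappa_xb * (x + params.stroke_d_nm) ** 2 / (2.0 * params.kBT_pN_nm))
    else:
        raise ValueError(f"state must be 1, 2 or 3, got {state}")
    return g if g.ndim else float(g)


def transition_rates(x, params: RateParams, kappa_xb: float) -> RateSet:
    """All six strain-dependent rates at strain-coordinate(s) x.

    Vectorised over x.  Caps: k23 <= cap_k23 (built into the sigmoid),
    k32 <= cap_k32 and k31 <= cap_k31, each with its detailed-balance
    partner recomputed from K_ij(x) when the cap engages.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("strain x must be finite (got NaN)")
    kBT = params.kBT_pN_nm
    d = params.stroke_d_nm
    scalar = x.ndim == 0
    x = np.atleast_1d(x)

    k12 = params.k_bind_per_s * np.exp(-kappa_xb * x ** 2 / (2.0 * kBT))
    # K12(x) = exp(-(G2-G1)); k21 = k12/K12 = k_bind * exp(dG_bind), constant
    k21 = np.full_like(x, params.k_bind_per_s * math.exp(params.dG_bind_kBT))

    dG23 = params.dG_stroke_kBT + kappa_xb * ((x + d) ** 2 - x ** 2) / (2.0 * kBT)
    e = np.exp(np.clip(dG23, -700.0, 700.0))
    k23 = params.cap_k23_per_s / (1.0 + e)
    k32 = k23 * e
    over = k32 > params.cap_k32_per_s
    k32 = np.where(over, params.cap_k32_per_s, k32)
    k23 = np.where(over, params.cap_k32_per_s / e, k23)

    s3 = x + d
    accel = np.exp(np.clip(
        -(kappa_xb * params.delta2_nm * s3
          + kappa_xb * params.delta2_nm ** 2 / 2.0) / kBT, -700.0, 700.0))
    k31 = np.where(s3 <= 0,
                   np.minimum(params.k_adp0_per_s * accel, params.cap_k31_per_s),
                   params.k_adp0_per_s)
    k13 = np.full_like(x, params.k13_per_s)

    if scalar:
        return RateSet(*(float(a[0]) for a in (k12, k21, k23, k32, k31, k13)))
    return RateSet(k12, k21, k23, k32, k31, k13)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Time series of an isometric run plus the final lattice state.

    ``thin_force`` is the Z-disc (I-band) tension of every thin filament;
    ``n2``/``n3`` count attached heads per thick filament by state;
    ``xb_force_sum``/``xb_count`` give the instantaneous total crossbridge
    force and the number of attached heads; ``snapshots`` holds absolute
    monomer positions (n_snap, n_thin, n_monomers) from ``snapshot_t`` on.
    """

    t: np.ndarray
    thin_force: np.ndarray
    n2: np.ndarray
    n3: np.ndarray
    xb_force_sum: np.ndarray
    xb_count: np.ndarray
    snapshot_t: np.ndarray
    snapshots: np.ndarray
    events: np.ndarray          # (n_events, 5): step, head, code, filament, monomer
    seed: int
    duration_s: float
    config: SimulationConfig
    final_state: LatticeState | None = None
    event_overflow: bool = False

    @property
    def heads_total(self) -> int:
        return self.n2.shape[1] * self.config.geometry.heads_per_half_thick

    def bound_fraction_series(self) -> np.ndarray:
        return (self.n2.sum(axis=1) + self.n3.sum(axis=1)) / self.heads_total

    def mean_xb_force_series(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.xb_count > 0, self.xb_force_sum / self.xb_count, 0.0)

    def plateau_start(self, window_s: float = 0.05, drift: float = 0.01) -> float:
        """First time from which the windowed mean force drifts < ``drift``
        (relative) over ``window_s``.  Raises if no plateau is reached."""
        if self.t.size == 0:
            raise ValueError("empty trace")
        total = self.thin_force.sum(axis=1)
        dt_rec = float(self.t[1] - self.t[0]) if self.t.size > 1 else self.duration_s
        w = max(1, int(round(window_s / dt_rec)))
        if 2 * w > total.size:
            raise ValueError("trace shorter than two detection windows")
        scale = max(abs(float(np.mean(total[-w:]))), 1e-12)
        for i in range(0, total.size - 2 * w + 1):
            m1 = float(np.mean(total[i:i + w]))
            m2 = float(np.mean(total[i + w:i + 2 * w]))
            if abs(m2 - m1) < drift * scale:
                return float(self.t[i + w])
        raise ValueError("no steady-state plateau detected (force still drifting)")

    def plateau_mask(self, window_s: float | None = None) -> np.ndarray:
        """Boolean mask over records in the analysis window: the last
        ``window_s`` seconds, or everything past the detected plateau."""
        if window_s is not None:
            if window_s > self.duration_s + 1e-12:
                raise ValueError(
                    f"window {window_s} s exceeds trace duration {self.duration_s} s")
            return self.t >= self.duration_s - window_s - 1e-12
        t0 = self.plateau_start()
        return self.t >= t0


def _n_steps(duration_s: float, dt: float) -> int:
    return int(round(duration_s / dt))


def run_isometric(
    config: SimulationConfig | None = None,
    duration_s: float = 0.5,
    seed: int = 0,
) -> SimulationTrace:
    """Isometric force development of a half sarcomere with fixed ends.

    Fixed-step Monte Carlo at config.rates.dt_s; mechanics re-equilibrated
    only on crossbridge events (the elastic configuration is piecewise
    constant between events under isometric boundary conditions).
    """
    config = config or SimulationConfig()
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rates = config.rates
    kdt = rates.max_rate_per_s() * rates.dt_s
    if kdt >= 0.05:
        raise ValueError(
            f"dt too large: max_rate*dt = {kdt:.3g} >= 0.05 violates the "
            "first-order transition-probability approximation")

    lattice = build_half_sarcomere(config.geometry, config.elastic, seed=seed)
    arr = _arrays_from_lattice(lattice)
    sc = _engine_scalars(lattice)

    dt = rates.dt_s
    n_steps = _n_steps(duration_s, dt)
    record_every = max(1, _n_steps(config.record_every_s, dt))
    snap_every = max(1, _n_steps(config.snapshot_every_s, dt))
    snap_start = max(1, _n_steps(config.snapshot_after_s, dt))
    n_rec = n_steps // record_every
    if snap_start <= n_steps:
        n_snap = (n_steps - snap_start) // snap_every + 1
    else:
        n_snap = 0

    F, M = arr["u_thin"].shape
    T = arr["u_thick"].shape[0]
    Nh = arr["head_state"].shape[0]
    rec_t = np.zeros(n_rec)
    rec_fthin = np.zeros((n_rec, F))
    rec_n2 = np.zeros((n_rec, T), dtype=np.int64)
    rec_n3 = np.zeros((n_rec, T), dtype=np.int64)
    rec_xbF = np.zeros(n_rec)
    rec_xbN = np.zeros(n_rec, dtype=np.int64)
    snap_t = np.zeros(n_snap)
    snaps = np.zeros((n_snap, F, M))
    max_events = max(200_000, int(Nh * duration_s * 800))
    events = np.zeros((max_events, 5), dtype=np.int64)

    kappa = config.elastic.kappa_xb_pN_per_nm
    d_act = config.solve_tol_pN / (kappa * 512.0)
    n_events, status = _engine.run_mc(
        np.int64(seed % 2**31), np.int64(n_steps), dt,
        arr["z0_thin"], arr["z0_crown"], arr["head_target"], arr["head_crown"],
        arr["hot_idx"], arr["hot"], np.int64(lattice.heads_per_thick),
        sc["ka_seg"], sc["km_seg"], sc["k_anchor"], sc["titin_k"], kappa,
        rates.dG_bind_kBT, rates.dG_stroke_kBT, rates.k_bind_per_s,
        rates.k_adp0_per_s, rates.stroke_d_nm, rates.delta2_nm,
        rates.cap_k23_per_s, rates.cap_k32_per_s, rates.cap_k31_per_s,
        rates.kBT_pN_nm,
        config.binding_reach_nm, config.geometry.monomer_spacing_s0_nm,
        d_act, max(d_act, 1.0e-5), max(d_act, 1.0e-4), 1.0e-3,
        np.int64(200), np.int64(20_000), np.int64(200_000),
        arr["u_thin"], arr["u_thick"], arr["head_state"], arr["head_f"],
        arr["head_j"], arr["occ"], arr["att_count"], arr["att_heads"],
        arr["att_slot"],
        np.int64(record_every), np.int64(snap_start), np.int64(snap_every),
        rec_t, rec_fthin, rec_n2, rec_n3, rec_xbF, rec_xbN,
        snap_t, snaps,
        events, np.int64(max_events),
    )
    if status == 1:
        raise RuntimeError(
            f"mechanics failed to converge during the run (seed {seed}); "
            "front re-solve budget exhausted")

    # final lattice state with explicit attachments
    lattice.thin_z = arr["z0_thin"][None, :] + arr["u_thin"]
    lattice.thick_z = arr["z0_crown"][None, :] + arr["u_thick"]
    atts = []
    d = rates.stroke_d_nm
    for hid in range(Nh):
        st = int(arr["head_state"][hid])
        if st >= 2:
            atts.append(Attachment(
                head_id=hid,
                filament_id=int(arr["head_f"][hid]),
                monomer_index=int(arr["head_j"][hid]),
                state=st,
                zero_strain_offset=d if st == 3 else 0.0,
            ))
    lattice.attachments = atts

    return SimulationTrace(
        t=rec_t, thin_force=rec_fthin, n2=rec_n2, n3=rec_n3,
        xb_force_sum=rec_xbF, xb_count=rec_xbN,
        snapshot_t=snap_t, snapshots=snaps,
        events=events[:n_events].copy(),
        seed=seed, duration_s=duration_s, config=config,
        final_state=lattice, event_overflow=(status == 2),
    )


def mc_update(
    lattice: LatticeState,
    rates: RateParams,
    dt: float | None = None,
    seed: int = 0,
    n_steps: int = 1,
    binding_reach_nm: float = 8.0,
    solve_tol_pN: float = 1.0e-6,
) -> list[tuple[int, int, str, int, int]]:
    """Advance the Monte Carlo by ``n_steps`` fixed steps on an existing
    lattice, mutating it in place; returns the event list as
    (step, head_id, transition, filament, monomer) tuples.
    """
    dt = rates.dt_s if dt is None else dt
    kdt = rates.max_rate_per_s() * dt
    if kdt >= 0.05:
        raise ValueError(
            f"dt too large: max_rate*dt = {kdt:.3g} >= 0.05 violates the "
            "first-order transition-probability approximation")
    arr = _arrays_from_lattice(lattice)
    sc = _engine_scalars(lattice)
    kappa = lattice.elastic.kappa_xb_pN_per_nm
    F, M = arr["u_thin"].shape
    max_events = max(1000, 16 * n_steps)
    events = np.zeros((max_events, 5), dtype=np.int64)
    empty_f = np.zeros(0)
    empty_if = np.zeros((0, F))
    empty_it = np.zeros((0, arr["u_thick"].shape[0]), dtype=np.int64)
    empty_snap = np.zeros((0, F, M))
    n_events, status = _engine.run_mc(
        np.int64(seed % 2**31), np.int64(n_steps), dt,
        arr["z0_thin"], arr["z0_crown"], arr["head_target"], arr["head_crown"],
        arr["hot_idx"], arr["hot"], np.int64(lattice.heads_per_thick),
        sc["ka_seg"], sc["km_seg"], sc["k_anchor"], sc["titin_k"], kappa,
        rates.dG_bind_kBT, rates.dG_stroke_kBT, rates.k_bind_per_s,
        rates.k_adp0_per_s, rates.stroke_d_nm, rates.delta2_nm,
        rates.cap_k23_per_s, rates.cap_k32_per_s, rates.cap_k31_per_s,
        rates.kBT_pN_nm,
        binding_reach_nm, lattice.geometry.monomer_spacing_s0_nm,
        solve_tol_pN / (kappa * 512.0),
        max(solve_tol_pN / (kappa * 512.0), 1.0e-5),
        max(solve_tol_pN / (kappa * 512.0), 1.0e-4), 1.0e-3,
        np.int64(200), np.int64(20_000), np.int64(200_000),
        arr["u_thin"], arr["u_thick"], arr["head_state"], arr["head_f"],
        arr["head_j"], arr["occ"], arr["att_count"], arr["att_heads"],
        arr["att_slot"],
        np.int64(0), np.int64(n_steps + 1), np.int64(0),
        empty_f, empty_if, empty_it, empty_it, empty_f,
        np.zeros(0, dtype=np.int64), empty_f, empty_snap,
        events, np.int64(max_events),
    )
    if status == 1:
        raise RuntimeError("mechanics failed to converge during mc_update")

    lattice.thin_z = arr["z0_thin"][None, :] + arr["u_thin"]
    lattice.thick_z = arr["z0_crown"][None, :] + arr["u_thick"]
    atts = []
    for hid in range(arr["head_state"].shape[0]):
        st = int(arr["head_state"][hid])
        if st >= 2:
            atts.append(Attachment(
                head_id=hid, filament_id=int(arr["head_f"][hid]),
                monomer_index=int(arr["head_j"][hid]), state=st,
                zero_strain_offset=rates.stroke_d_nm if st == 3 else 0.0))
    lattice.attachments = atts
    return [
        (int(s), int(h), _EVENT_NAMES[int(c)], int(f), int(j))
        for s, h, c, f, j in events[:n_events]
    ]


def bound_fraction(trace: SimulationTrace, window_s: float | None = None):
    """Time-averaged fraction of heads in attached states over the plateau.

    Returns (fraction, per_thick) where ``per_thick`` is the time-averaged
    bound fraction of each thick filament.
    """
    mask = trace.plateau_mask(window_s)
    if not np.any(mask):
        raise ValueError("analysis window contains no trace records")
    hpt = trace.config.geometry.heads_per_half_thick
    per_thick = (trace.n2[mask] + trace.n3[mask]).mean(axis=0) / hpt
    frac = float((trace.n2[mask].sum() + trace.n3[mask].sum())
                 / (mask.sum() * trace.heads_total))
    return frac, per_thick
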
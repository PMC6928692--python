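"""Force estimation from meridional reflections and conversion to tension.

The estimation chain: (i) mean inter-monomer spacing of the relaxed and
contracted states from the order-1 reflection (centroid of the top half);
(ii) the mean strain is converted to the plateau (I-band) strain through the
mean-to-plateau ratio g of the spacing profile — taken from the simulated
ensemble when available, else from the linear-tension-decay geometry
g = (L_I + L_ov/2)/L_thin; (iii) the plateau force per thin filament is
F = Ka * plateau_strain; (iv) the myosin binding rate is titrated until the
simulated plateau force matches F; (v) the matched ensemble supplies the
distribution of per-filament forces and the whole-muscle tension through the
hexagonal-lattice areal filament density.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .diffraction import BeamModel, MeridionalProfile, multi_order_profile, peak_order_window
from .kinetics import SimulationTrace, run_isometric
from .lattice import overlap_bounds
from .mechanics import SpacingStats, ensemble_spacing_stats
from .params import GeometryParams, SimulationConfig
from .profiles import PeakMetrics, peak_top_half_centroid, subtract_background

__all__ = [
    "DensityResult",
    "ForceEstimate",
    "EstimateConfig",
    "filament_density",
    "tension_from_actin_force",
    "geometric_g",
    "plateau_strain_from_mean",
    "force_from_plateau_strain",
    "titrate_kbind",
    "plateau_thin_forces",
    "force_statistics",
    "estimate_from_profiles",
]

# The order-1 actin window must stay clear of the 2.86 nm myosin meridional
# reflection sitting just below it in Z.
_MYOSIN_M3_EXCLUDE_NM = 2.80


@dataclass(frozen=True)
class DensityResult:
    """Filaments per unit muscle cross-section (half sarcomere)."""

    thick_per_um2: float
    actin_per_um2: float


def filament_density(d10_slack_nm: float = 37.0, occupancy: float = 0.8) -> DensityResult:
    """Areal filament densities from the hexagonal lattice spacing d10.

    Each thick filament owns a cross-section area (2/sqrt(3))*d10^2; the
    myofibril occupancy discounts inter-myofibrillar space.  Actin density
    is exactly twice the thick density (2:1 thin:thick stoichiometry).
    """
    if d10_slack_nm <= 0:
        raise ValueError("d10 must be positive")
    if not (0 < occupancy <= 1):
        raise ValueError("occupancy must be in (0, 1]")
    area_nm2 = (2.0 / np.sqrt(3.0)) * d10_slack_nm**2
    thick = occupancy * 1.0e6 / area_nm2
    return DensityResult(thick_per_um2=thick, actin_per_um2=2.0 * thick)


def tension_from_actin_force(F_pN: float, density: DensityResult) -> float:
    """Muscle tension (kPa) from the mean force per thin filament:
    pN/filament x filaments/um^2 x 1e-3 = kPa."""
    if F_pN < 0:
        raise ValueError("force must be >= 0")
    return F_pN * density.actin_per_um2 * 1.0e-3


def geometric_g(L_I: float, L_ov: float, L_thin: float) -> float:
    """Mean-to-plateau strain ratio for tension decaying linearly across the
    overlap: g = (L_I + L_ov/2) / L_thin.

    This is the monomer-averaged ratio; the observed order-1 centroid is
    biased a few percent above it because the uniformly stretched I-band
    segment diffracts coherently and dominates the peak.  Use
    ``effective_g`` for the ratio of the *observed* mean strain.
    """
    if L_thin <= 0 or L_ov <= 0 or L_I < 0:
        raise ValueError("lengths must be positive (L_I >= 0)")
    return (L_I + L_ov / 2.0) / L_thin


_EFFECTIVE_G_CACHE: dict = {}


def effective_g(geometry: GeometryParams, Ka_pN: float = 0.65e5,
                n_loads: int = 54, n_filaments: int = 64,
                probe_force_pN: float = 300.0, seed: int = 210) -> float:
    """Ratio of the order-1-centroid-observed mean strain to the I-band
    plateau strain, calibrated on the forward model.

    Probes the full chain (overlap-distributed stepwise loads -> diffraction
    -> top-half centroid) at a reference plateau force; the ratio is
    insensitive to the probe force in the linear regime.  This is the
    quantity that converts an observed spacing shift into a plateau strain.
    """
    key = (geometry, round(Ka_pN, 6), n_loads, n_filaments, seed)
    if key in _EFFECTIVE_G_CACHE:
        return _EFFECTIVE_G_CACHE[key]
    from .diffraction import meridional_intensity, order_window_grid
    from .profiles import peak_top_half_centroid
    from .synthetic import stepwise_strained_filament, uniform_filament

    s0 = geometry.monomer_spacing_s0_nm
    n = geometry.n_monomers
    z_lo, z_hi = overlap_bounds(geometry)
    if z_hi - z_lo <= 0:
        raise ValueError("zero thick-thin overlap: no force estimate possible")
    j_lo = int(np.ceil(z_lo / s0))
    rng = np.random.default_rng(seed)
    ens = []
    for _ in range(n_filaments):
        idx = np.sort(rng.integers(j_lo, n, size=n_loads))
        ens.append(stepwise_strained_filament(
            n, s0, [(int(j), probe_force_pN / n_loads) for j in idx], Ka_pN))
    grid = order_window_grid(1, s0, points_per_percent=1500)
    m_rel = peak_top_half_centroid(
        meridional_intensity([uniform_filament(n, s0)], grid), order=1)
    m_con = peak_top_half_centroid(meridional_intensity(ens, grid), order=1)
    strain_obs = m_con.spacing / m_rel.spacing - 1.0
    g = strain_obs / (probe_force_pN / Ka_pN)
    _EFFECTIVE_G_CACHE[key] = g
    return g


def plateau_strain_from_mean(
    mean_strain: float,
    spacing_stats: SpacingStats | None = None,
    geometry: GeometryParams | None = None,
    g: float | None = None,
    Ka_pN: float = 0.65e5,
) -> tuple[float, float]:
    """Convert the observed mean strain to the I-band plateau strain.

    Priority of the ratio g = mean/plateau: explicit ``g``; the simulated
    ensemble spacing profile; the forward-model-calibrated ``effective_g``
    for the geometry.  Returns (plateau_strain, g_used).  Refuses when the
    geometry has no overlap.
    """
    if g is None and spacing_stats is not None:
        if geometry is None:
            raise ValueError("geometry required to locate the I-band plateau")
        z_lo, z_hi = overlap_bounds(geometry)
        if z_hi <= z_lo:
            raise ValueError("zero thick-thin overlap: no force estimate possible")
        g = spacing_stats.mean_to_plateau_ratio(z_lo)
    elif g is None:
        if geometry is None:
            raise ValueError("need spacing_stats, geometry or an explicit g")
        g = effective_g(geometry, Ka_pN)
    if not (0 < g <= 1.0000001):
        raise ValueError(f"mean-to-plateau ratio g = {g:.4g} outside (0, 1]")
    return mean_strain / g, g


def force_from_plateau_strain(strain: float, Ka_pN: float) -> float:
    """Plateau force per thin filament F = Ka * strain (linear elasticity)."""
    if strain < 0:
        raise ValueError("strain must be >= 0")
    if Ka_pN <= 0:
        raise ValueError("Ka must be positive")
    return Ka_pN * strain


# ---------------------------------------------------------------------------
# ensemble statistics and titration
# ---------------------------------------------------------------------------

def plateau_thin_forces(trace: SimulationTrace, window_s: float | None = None) -> np.ndarray:
    """Instantaneous per-thin-filament I-band forces over the plateau,
    shape (n_records, n_thin)."""
    mask = trace.plateau_mask(window_s)
    if not np.any(mask):
        raise ValueError("no plateau records in the trace")
    return trace.thin_force[mask]


@dataclass
class ForceEstimate:
    """Result of the estimation chain (per-thin-filament I-band force)."""

    mean_force_pN: float
    tension_kPa: float
    g: float
    mean_strain: float
    plateau_strain: float
    sd_force_pN: float | None = None
    hist_edges_pN: np.ndarray | None = None
    hist_counts: np.ndarray | None = None
    kbind_matched_per_s: float | None = None
    relaxed_metrics: dict = field(default_factory=dict)
    contracted_metrics: dict = field(default_factory=dict)
    overlay_residual: float | None = None


def force_statistics(forces, density: DensityResult | None = None,
                     bins: int = 30) -> ForceEstimate:
    """Mean, SD and histogram of per-thin-filament forces.

    ``forces`` is 1D (one value per filament) or 2D (records x filaments;
    the SD is then the time-average of the across-filament SD, matching an
    instantaneous-distribution histogram pooled over exposure time).
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise ValueError("empty force ensemble")
    density = density or filament_density()
    if forces.ndim == 1:
        mean = float(forces.mean())
        sd = float(forces.std(ddof=0))
        pooled = forces
    elif forces.ndim == 2:
        mean = float(forces.mean())
        sd = float(forces.std(axis=1, ddof=0).mean())
        pooled = forces.ravel()
    else:
        raise ValueError("forces must be 1D or 2D")
    counts, edges = np.histogram(pooled, bins=bins)
    return ForceEstimate(
        mean_force_pN=mean,
        tension_kPa=tension_from_actin_force(max(mean, 0.0), density),
        g=float("nan"), mean_strain=float("nan"), plateau_strain=float("nan"),
        sd_force_pN=sd, hist_edges_pN=edges, hist_counts=counts)


def _measure_mean_force(config: SimulationConfig, duration_s: float, seeds,
                        window_s: float | None):
    traces = [run_isometric(config, duration_s, s) for s in seeds]
    means = [float(plateau_thin_forces(tr, window_s).mean()) for tr in traces]
    return float(np.mean(means)), traces


def titrate_kbind(
    target_mean_force_pN: float,
    config: SimulationConfig,
    duration_s: float = 0.5,
    seeds=(0, 1, 2),
    tol: float = 0.03,
    window_s: float | None = None,
    max_iter: int = 12,
) -> tuple[float, list[SimulationTrace]]:
    """Bisection on the binding rate until the simulated plateau mean
    per-thin-filament force matches the target within ``tol`` (relative).

    Plateau force grows monotonically with k_bind; sampling noise is tamed
    by averaging over seeds.  Returns (k_bind, traces at the match).
    """
    if target_mean_force_pN < 0:
        raise ValueError("target force must be >= 0")
    if target_mean_force_pN == 0:
        return 0.0, []

    def at(k):
        cfg = config.replace(rates=dataclasses.replace(config.rates, k_bind_per_s=k))
        return _measure_mean_force(cfg, duration_s, seeds, window_s)

    k = config.rates.k_bind_per_s
    F, traces = at(k)
    if abs(F - target_mean_force_pN) <= tol * target_mean_force_pN:
        return k, traces

    # bracket the target
    k_lo, F_lo, k_hi, F_hi = None, None, None, None
    if F < target_mean_force_pN:
        k_lo, F_lo = k, F
        for _ in range(8):
            k *= 2.0
            F, traces = at(k)
            if F >= target_mean_force_pN:
                k_hi, F_hi = k, F
                break
            k_lo, F_lo = k, F
    else:
        k_hi, F_hi = k, F
        for _ in range(8):
            k /= 2.0
            F, traces = at(k)
            if F <= target_mean_force_pN:
                k_lo, F_lo = k, F
                break
            k_hi, F_hi = k, F
    if k_lo is None or k_hi is None:
        raise RuntimeError(
            f"could not bracket target force {target_mean_force_pN:.1f} pN "
            f"(last k_bind {k:.1f} s^-1 gave {F:.1f} pN)")

    best_k, best_traces, best_err = k, traces, abs(F - target_mean_force_pN)
    for _ in range(max_iter):
        k = np.sqrt(k_lo * k_hi)
        F, traces = at(k)
        err = abs(F - target_mean_force_pN)
        if err < best_err:
            best_k, best_traces, best_err = k, traces, err
        if err <= tol * target_mean_force_pN:
            return k, traces
        if F < target_mean_force_pN:
            k_lo = k
        else:
            k_hi = k
    return best_k, best_traces


# ---------------------------------------------------------------------------
# end-to-end estimation from observed profiles
# ---------------------------------------------------------------------------

@dataclass
class EstimateConfig:
    """Options for estimate_from_profiles."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    g_mode: str = "geometric"           # geometric | fixed | simulate
    g_value: float | None = None        # for g_mode = fixed
    window_halfwidth: float = 0.02
    background: str = "linear_endpoints"
    subtract_bg: bool = True
    sim_duration_s: float = 0.5
    sim_seeds: tuple = (0, 1, 2)
    titrate_tol: float = 0.03
    plateau_window_s: float | None = None
    beam: BeamModel | None = None       # for the overlay check
    hist_bins: int = 30


def _order_metrics(profile: MeridionalProfile, order: int, s0: float,
                   cfg: EstimateConfig) -> PeakMetrics:
    z_lo, z_hi = peak_order_window(order, s0, cfg.window_halfwidth)
    if order == 1:
        z_lo = max(z_lo, 1.0 / _MYOSIN_M3_EXCLUDE_NM)
    work = profile
    if cfg.subtract_bg:
        work = subtract_background(profile, cfg.background, window=(z_lo, z_hi))
        return peak_top_half_centroid(work, window=None, order=order)
    return peak_top_half_centroid(work, window=(z_lo, z_hi), order=order)


def _g_from_ensemble(positions: np.ndarray, geometry: GeometryParams,
                     max_filaments: int = 200) -> float:
    """Observed-mean-to-plateau strain ratio of a simulated ensemble: the
    order-1 centroid shift of its diffraction over the plateau strain of its
    spacing profile (same observable as the experimental estimate)."""
    from .diffraction import meridional_intensity, order_window_grid
    from .profiles import peak_top_half_centroid
    from .synthetic import uniform_filament

    s0 = geometry.monomer_spacing_s0_nm
    stats = ensemble_spacing_stats(positions, s0_nm=s0)
    z_lo, z_hi = overlap_bounds(geometry)
    plateau = stats.plateau_strain(z_lo)
    if plateau <= 0:
        raise ValueError("ensemble carries no plateau strain")
    sub = positions[:max_filaments]
    grid = order_window_grid(1, s0, points_per_percent=1500)
    m_ref = peak_top_half_centroid(
        meridional_intensity([uniform_filament(positions.shape[1], s0)], grid),
        order=1)
    m_ens = peak_top_half_centroid(meridional_intensity(sub, grid), order=1)
    return (m_ens.spacing / m_ref.spacing - 1.0) / plateau


def _overlay_residual(observed: MeridionalProfile, predicted: MeridionalProfile,
                      order: int, s0: float, cfg: EstimateConfig) -> float:
    """Peak-local normalized residual between observed and predicted
    reflection shapes (each scaled to unit peak height on a common grid)."""
    z_lo, z_hi = peak_order_window(order, s0, cfg.window_halfwidth)
    obs = observed.window(z_lo, z_hi)
    pred = predicted.window(z_lo, z_hi)
    if obs.Z.size < 5 or pred.Z.size < 5:
        raise ValueError(f"order-{order} window missing from a profile")
    oi = obs.intensity / obs.intensity.max()
    pi = np.interp(obs.Z, pred.Z, pred.intensity / pred.intensity.max())
    core = oi >= 0.2
    return float(np.sqrt(np.mean((oi[core] - pi[core]) ** 2)))


def estimate_from_profiles(
    relaxed: MeridionalProfile,
    contracted: MeridionalProfile,
    config: EstimateConfig | None = None,
) -> ForceEstimate:
    """Estimate per-thin-filament force and muscle tension from a pair of
    meridional profiles (steps i-v of the estimation chain).

    In ``simulate`` mode the binding rate is titrated so the simulated
    ensemble reproduces the measured plateau force; the force histogram, the
    self-consistent g and the beam-convolved overlay residual come from that
    matched ensemble.  ``geometric``/``fixed`` modes stop after step iii
    (no distribution, only the mean force and tension).
    """
    cfg = config or EstimateConfig()
    geo = cfg.sim.geometry
    s0 = geo.monomer_spacing_s0_nm
    density = filament_density(geo.d10_slack_nm, geo.myofibril_occupancy)

    rel, con = {}, {}
    for order in (1, 2):
        rel[order] = _order_metrics(relaxed, order, s0, cfg)
        con[order] = _order_metrics(contracted, order, s0, cfg)
    s_r, s_c = rel[1].spacing, con[1].spacing
    mean_strain = (s_c - s_r) / s_r

    if mean_strain <= 0:
        return ForceEstimate(
            mean_force_pN=0.0, tension_kPa=0.0, g=float("nan"),
            mean_strain=mean_strain, plateau_strain=0.0, sd_force_pN=0.0,
            relaxed_metrics={k: v for k, v in rel.items()},
            contracted_metrics={k: v for k, v in con.items()})

    if cfg.g_mode == "fixed":
        plateau, g = plateau_strain_from_mean(mean_strain, g=cfg.g_value)
    else:
        plateau, g = plateau_strain_from_mean(
            mean_strain, geometry=geo, Ka_pN=cfg.sim.elastic.Ka_pN)
    F = force_from_plateau_strain(plateau, cfg.sim.elastic.Ka_pN)

    est = ForceEstimate(
        mean_force_pN=F,
        tension_kPa=tension_from_actin_force(F, density),
        g=g, mean_strain=mean_strain, plateau_strain=plateau,
        relaxed_metrics={k: v for k, v in rel.items()},
        contracted_metrics={k: v for k, v in con.items()})
    if cfg.g_mode != "simulate":
        return est

    # step iv: titrate k_bind, refine g self-consistently once
    kb, traces = titrate_kbind(F, cfg.sim, cfg.sim_duration_s, cfg.sim_seeds,
                               cfg.titrate_tol, cfg.plateau_window_s)
    snaps = np.concatenate([tr.snapshots for tr in traces], axis=0)
    g_sim = _g_from_ensemble(snaps.reshape(-1, snaps.shape[-1]), geo)
    if abs(g_sim - g) > 0.02 * g:
        plateau, g = plateau_strain_from_mean(mean_strain, g=g_sim)
        F = force_from_plateau_strain(plateau, cfg.sim.elastic.Ka_pN)
        kb, traces = titrate_kbind(F, cfg.sim, cfg.sim_duration_s, cfg.sim_seeds,
                                   cfg.titrate_tol, cfg.plateau_window_s)
        snaps = np.concatenate([tr.snapshots for tr in traces], axis=0)

    forces = np.concatenate(
        [plateau_thin_forces(tr, cfg.plateau_window_s) for tr in traces], axis=0)
    stats_out = force_statistics(forces, density, cfg.hist_bins)

    # step v: matched ensemble must overlay the observed reflections
    overlay = None
    if snaps.size:
        pred = multi_order_profile(
            snaps.reshape(-1, snaps.shape[-1]), s0, orders=(1, 2),
            halfwidth=cfg.window_halfwidth, beam=cfg.beam)
        overlay = max(_overlay_residual(contracted, pred, n, s0, cfg) for n in (1, 2))

    return ForceEstimate(
        mean_force_pN=stats_out.mean_force_pN,
        tension_kPa=tension_from_actin_force(stats_out.mean_force_pN, density),
        g=g, mean_strain=mean_strain, plateau_strain=plateau,
        sd_force_pN=stats_out.sd_force_pN,
        hist_edges_pN=stats_out.hist_edges_pN, hist_counts=stats_out.hist_counts,
        kbind_matched_per_s=kb,
        relaxed_metrics={k: v for k, v in rel.items()},
        contracted_metrics={k: v for k, v in con.items()},
        overlay_residual=overlay)
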
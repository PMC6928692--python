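"""Quasi-static mechanical equilibrium of the filament spring network.

Extensible actin chains (segment stiffness Ka/s0), extensible myosin chains
(Km/crown_spacing, anchored to the M-band through the bare zone) and linear
crossbridge springs (kappa) between them.  The system is linear and SPD
under the stated constraints; the solver performs exact tridiagonal solves
per chain inside a residual-driven relaxation front.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .lattice import LatticeState, overlap_bounds

__all__ = [
    "solve_equilibrium",
    "crossbridge_strains",
    "filament_tension_profile",
    "ensemble_spacing_stats",
    "FilamentProfile",
    "SpacingStats",
    "residual_forces",
]


def _arrays_from_lattice(lattice: LatticeState) -> dict:
    """Flat engine-facing state arrays built from a LatticeState."""
    geo = lattice.geometry
    F, M = lattice.thin_z.shape
    T, C = lattice.thick_z.shape
    hpc = geo.heads_per_crown
    hpt = geo.n_crowns * hpc
    Nh = T * hpt

    z0_thin = np.arange(M) * geo.monomer_spacing_s0_nm
    z0_crown = geo.crown_rest_positions_nm().astype(np.float64)
    u_thin = np.ascontiguousarray(lattice.thin_z - z0_thin[None, :], dtype=np.float64)
    u_thick = np.ascontiguousarray(lattice.thick_z - z0_crown[None, :], dtype=np.float64)

    head_crown = ((np.arange(Nh) % hpt) // hpc).astype(np.int64)
    if lattice.head_target_thin is not None:
        head_target = lattice.head_target_thin.astype(np.int64)
    else:
        head_target = np.zeros(Nh, dtype=np.int64)

    head_state = np.ones(Nh, dtype=np.int64)
    head_f = np.full(Nh, -1, dtype=np.int64)
    head_j = np.full(Nh, -1, dtype=np.int64)
    occ = np.full((F, M), -1, dtype=np.int64)

    # CSR of heads able to bind each thin filament
    counts = np.bincount(head_target, minlength=F)
    hot_idx = np.zeros(F + 1, dtype=np.int64)
    np.cumsum(counts, out=hot_idx[1:])
    hot = np.argsort(head_target, kind="stable").astype(np.int64)

    cap = int(counts.max()) + 2 if Nh else 2
    att_count = np.zeros(F, dtype=np.int64)
    att_heads = np.full((F, cap), -1, dtype=np.int64)
    att_slot = np.full(Nh, -1, dtype=np.int64)

    for a in lattice.attachments:
        hid, f, j = a.head_id, a.filament_id, a.monomer_index
        if occ[f, j] >= 0:
            raise ValueError(f"monomer ({f}, {j}) bound by two heads")
        head_state[hid] = a.state
        head_f[hid] = f
        head_j[hid] = j
        occ[f, j] = hid
        slot = att_count[f]
        if slot >= cap:
            raise ValueError(f"too many attachments on thin filament {f}")
        att_heads[f, slot] = hid
        att_slot[hid] = slot
        att_count[f] = slot + 1

    return dict(
        z0_thin=z0_thin, z0_crown=z0_crown, u_thin=u_thin, u_thick=u_thick,
        head_crown=head_crown, head_target=head_target, head_state=head_state,
        head_f=head_f, head_j=head_j, occ=occ,
        att_count=att_count, att_heads=att_heads, att_slot=att_slot,
        hot_idx=hot_idx, hot=hot,
    )


def _engine_scalars(lattice: LatticeState) -> dict:
    geo, ela = lattice.geometry, lattice.elastic
    return dict(
        ka_seg=ela.Ka_pN / geo.monomer_spacing_s0_nm,
        km_seg=ela.Km_pN / geo.crown_spacing_nm,
        k_anchor=ela.Km_pN / geo.bare_zone_nm,
        titin_k=ela.titin_stiffness_pN_per_nm,
    )


def _stroke_offset(lattice: LatticeState) -> float:
    offs = {a.zero_strain_offset for a in lattice.attachments if a.state == 3}
    if len(offs) > 1:
        raise ValueError("post-stroke attachments must share one stroke offset")
    return offs.pop() if offs else 0.0


def residual_forces(lattice: LatticeState) -> tuple[np.ndarray, np.ndarray]:
    """Net axial force (pN) on every free node; should vanish at equilibrium.

    Returns (thin_residuals (F, M), thick_residuals (T, C)); anchored nodes
    (thin node 0) are reported as zero.
    """
    geo, ela = lattice.geometry, lattice.elastic
    sc = _engine_scalars(lattice)
    ka, km = sc["ka_seg"], sc["km_seg"]
    z0c = geo.crown_rest_positions_nm()
    tz, kz = lattice.thin_z, lattice.thick_z
    F, M = tz.shape
    T, C = kz.shape
    s0 = geo.monomer_spacing_s0_nm
    cs = geo.crown_spacing_nm

    rt = np.zeros((F, M))
    seg = ka * (np.diff(tz, axis=1) - s0)            # tension per segment
    rt[:, 1:] += seg * -1.0
    rt[:, :-1] += seg
    rt[:, 0] = 0.0                                   # Z-disc anchored

    rk = np.zeros((T, C))
    segm = km * (np.diff(kz, axis=1) - cs)
    rk[:, 1:] += segm * -1.0
    rk[:, :-1] += segm
    anchor_rest = geo.half_sarcomere_nm
    rk[:, -1] += sc["k_anchor"] * ((anchor_rest - kz[:, -1]) - geo.bare_zone_nm)
    rk[:, 0] += -sc["titin_k"] * (kz[:, 0] - z0c[0])

    hpt = lattice.heads_per_thick
    hpc = geo.heads_per_crown
    kappa = ela.kappa_xb_pN_per_nm
    for a in lattice.attachments:
        t = a.head_id // hpt
        c = (a.head_id % hpt) // hpc
        strain = (kz[t, c] - tz[a.filament_id, a.monomer_index]) + a.zero_strain_offset
        if a.monomer_index > 0:
            rt[a.filament_id, a.monomer_index] += kappa * strain
        rk[t, c] -= kappa * strain
    return rt, rk


def _residual_from_arrays(lattice: LatticeState, arr: dict, stroke: float) -> float:
    """Max net nodal force computed in displacement coordinates (avoids the
    ~1e-9 pN rounding floor of differencing absolute micron-scale positions)."""
    sc = _engine_scalars(lattice)
    ka, km = sc["ka_seg"], sc["km_seg"]
    ut, uk = arr["u_thin"], arr["u_thick"]
    rt = np.zeros_like(ut)
    seg = ka * np.diff(ut, axis=1)
    rt[:, 1:] -= seg
    rt[:, :-1] += seg
    rt[:, 0] = 0.0
    rk = np.zeros_like(uk)
    segm = km * np.diff(uk, axis=1)
    rk[:, 1:] -= segm
    rk[:, :-1] += segm
    rk[:, -1] -= sc["k_anchor"] * uk[:, -1]
    rk[:, 0] -= sc["titin_k"] * uk[:, 0]
    kappa = lattice.elastic.kappa_xb_pN_per_nm
    z0t, z0c = arr["z0_thin"], arr["z0_crown"]
    hpt = lattice.heads_per_thick
    bound = np.flatnonzero(arr["head_state"] >= 2)
    for hid in bound:
        t = hid // hpt
        c = arr["head_crown"][hid]
        f, j = arr["head_f"][hid], arr["head_j"][hid]
        shift = stroke if arr["head_state"][hid] == 3 else 0.0
        strain = (z0c[c] - z0t[j] + shift) + (uk[t, c] - ut[f, j])
        if j > 0:
            rt[f, j] += kappa * strain
        rk[t, c] -= kappa * strain
    return max(np.abs(rt).max(initial=0.0), np.abs(rk).max(initial=0.0))


def solve_equilibrium(lattice: LatticeState, tol: float = 1.0e-6) -> LatticeState:
    """Relax node positions so the net force on every free node is < tol pN.

    Mutates (and returns) the lattice.  Under isometric boundary conditions
    this needs to run only when the attachment set changed.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    arr = _arrays_from_lattice(lattice)
    sc = _engine_scalars(lattice)
    kappa = lattice.elastic.kappa_xb_pN_per_nm
    stroke = _stroke_offset(lattice)
    ok = _engine.relax_all(
        arr["u_thin"], arr["u_thick"], arr["z0_thin"], arr["z0_crown"],
        arr["att_count"], arr["att_heads"], arr["head_state"], arr["head_f"],
        arr["head_j"], arr["head_crown"], np.int64(lattice.heads_per_thick),
        sc["ka_seg"], sc["km_seg"], sc["k_anchor"], sc["titin_k"], kappa,
        stroke, tol / (kappa * 512.0), np.int64(200_000),
    )
    res = _residual_from_arrays(lattice, arr, stroke)
    lattice.thin_z = arr["z0_thin"][None, :] + arr["u_thin"]
    lattice.thick_z = arr["z0_crown"][None, :] + arr["u_thick"]
    if not ok or res > tol:
        raise RuntimeError(
            f"equilibrium solve did not converge: max residual {res:.3g} pN > {tol:.3g} pN")
    return lattice


def crossbridge_strains(lattice: LatticeState, check_equilibrium: bool = True,
                        tol: float = 1.0e-4):
    """Per-attachment strain (nm) and spring force kappa*strain (pN).

    Positive force pulls the actin site toward the M-band (contractile).
    """
    if check_equilibrium and lattice.attachments:
        rt, rk = residual_forces(lattice)
        res = max(np.abs(rt).max(initial=0.0), np.abs(rk).max(initial=0.0))
        if res > tol:
            raise RuntimeError(
                f"lattice not at equilibrium (residual {res:.3g} pN); "
                "call solve_equilibrium first")
    hpt = lattice.heads_per_thick
    hpc = lattice.geometry.heads_per_crown
    kappa = lattice.elastic.kappa_xb_pN_per_nm
    strains = np.empty(len(lattice.attachments))
    for i, a in enumerate(lattice.attachments):
        t = a.head_id // hpt
        c = (a.head_id % hpt) // hpc
        strains[i] = (lattice.thick_z[t, c]
                      - lattice.thin_z[a.filament_id, a.monomer_index]
                      + a.zero_strain_offset)
    return strains, kappa * strains


@dataclass
class FilamentProfile:
    """Spacing and tension along one thin filament (segment-wise)."""

    position_nm: np.ndarray     # segment midpoints, rest frame, from the Z-disc
    spacing_nm: np.ndarray      # current inter-monomer spacing per segment
    tension_pN: np.ndarray      # axial tension per segment


def filament_tension_profile(lattice: LatticeState, filament_id: int) -> FilamentProfile:
    """Spacing/tension profile of a thin filament from its node positions.

    Tension per segment follows Hooke's law F_j = Ka (s_j - s0)/s0; it equals
    the partial sum of crossbridge forces applied at monomers beyond the
    segment, is constant through the I-band and vanishes past the last
    attachment.
    """
    if not (0 <= filament_id < lattice.n_thin):
        raise ValueError(f"invalid thin filament id {filament_id}")
    geo = lattice.geometry
    s0 = geo.monomer_spacing_s0_nm
    z = lattice.thin_z[filament_id]
    spacing = np.diff(z)
    tension = lattice.elastic.Ka_pN * (spacing - s0) / s0
    mid = 0.5 * (np.arange(len(spacing)) + np.arange(1, len(spacing) + 1)) * s0
    return FilamentProfile(position_nm=mid, spacing_nm=spacing, tension_pN=tension)


@dataclass
class SpacingStats:
    """Ensemble spacing statistics per segment position (mean, SD across
    filaments); used both for the spacing-vs-position profile and for the
    mean-to-plateau strain ratio g."""

    position_nm: np.ndarray
    mean_spacing_nm: np.ndarray
    sd_spacing_nm: np.ndarray
    s0_nm: float

    @property
    def mean_strain(self) -> np.ndarray:
        return (self.mean_spacing_nm - self.s0_nm) / self.s0_nm

    def plateau_strain(self, z_overlap_lo: float) -> float:
        """Mean strain over the I-band (non-overlap) segments near the Z-disc."""
        mask = self.position_nm < z_overlap_lo
        if not np.any(mask):
            raise ValueError("no I-band segments below the overlap start")
        return float(self.mean_strain[mask].mean())

    def mean_to_plateau_ratio(self, z_overlap_lo: float) -> float:
        plateau = self.plateau_strain(z_overlap_lo)
        if plateau == 0:
            raise ValueError("plateau strain is zero; no force on the filaments")
        return float(self.mean_strain.mean() / plateau)


def ensemble_spacing_stats(positions=None, s0_nm: float | None = None,
                           lattice: LatticeState | None = None) -> SpacingStats:
    """Pointwise mean and SD of inter-monomer spacing over an ensemble.

    ``positions`` is (n_filaments, n_monomers) of absolute axial positions —
    a lattice's ``thin_z``, or simulation snapshots stacked over time and
    filaments (incoherent exposure averaging).
    """
    if lattice is not None:
        positions = lattice.thin_z
        s0_nm = lattice.geometry.monomer_spacing_s0_nm
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 3:
        positions = positions.reshape(-1, positions.shape[-1])
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise ValueError("need an ensemble of >= 2 filaments")
    if s0_nm is None:
        raise ValueError("s0_nm required when no lattice is given")
    spacing = np.diff(positions, axis=1)
    n_seg = spacing.shape[1]
    mid = (np.arange(n_seg) + 0.5) * s0_nm
    return SpacingStats(
        position_nm=mid,
        mean_spacing_nm=spacing.mean(axis=0),
        sd_spacing_nm=spacing.std(axis=0, ddof=0),
        s0_nm=s0_nm,
    )
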
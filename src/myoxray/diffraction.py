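"""Meridional X-ray diffraction from ensembles of (possibly nonuniformly
strained) actin filaments.

On the meridian (R = 0) the helical azimuth of a discontinuous helix
contributes only a constant phase, so the axial monomer positions determine
the pattern completely: per filament the amplitude is the coherent sum
A(Z) = sum_j f(Z) exp(2*pi*i Z z_j) over its monomer centres, and filaments
add incoherently (no axial register is assumed between them).  Orders of the
~2.73 nm monomer repeat appear at Z = n/2.73 nm^-1; nonuniform spacings
shift, broaden and attenuate the higher orders.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeridionalProfile",
    "BeamModel",
    "meridional_intensity",
    "peak_order_window",
    "order_window_grid",
    "multi_order_profile",
    "convolve_beam",
    "sphere_form_factor",
]


@dataclass
class MeridionalProfile:
    """1D intensity profile along the meridian.

    ``Z`` is the reciprocal axial coordinate in nm^-1 (strictly increasing);
    intensity is in arbitrary units, non-negative.
    """

    Z: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.Z.shape != self.intensity.shape or self.Z.ndim != 1:
            raise ValueError("Z and intensity must be 1D arrays of equal length")
        if self.Z.size and np.any(np.diff(self.Z) <= 0):
            raise ValueError("Z grid must be strictly increasing")

    def window(self, z_lo: float, z_hi: float) -> "MeridionalProfile":
        m = (self.Z >= z_lo) & (self.Z <= z_hi)
        return MeridionalProfile(self.Z[m], self.intensity[m], dict(self.metadata))


@dataclass(frozen=True)
class BeamModel:
    """Axial beam profile used to smear predicted reflections.

    Only a Gaussian shape is supported; ``fwhm`` is in the reciprocal axial
    coordinate (nm^-1).  The instrument value is a required input when
    emulating camera-recorded profiles (none is universal).
    """

    fwhm: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("beam fwhm must be positive")
        if self.shape != "gaussian":
            raise ValueError(f"unsupported beam shape {self.shape!r}")


def sphere_form_factor(Z, diameter_nm: float) -> np.ndarray:
    """Uniform-sphere form factor for subunits of the given diameter,
    evaluated on the meridian (momentum transfer q = 2 pi Z)."""
    Z = np.asarray(Z, dtype=float)
    qr = 2.0 * np.pi * Z * (diameter_nm / 2.0)
    out = np.ones_like(qr)
    nz = np.abs(qr) > 1e-12
    q = qr[nz]
    out[nz] = 3.0 * (np.sin(q) - q * np.cos(q)) / q**3
    return out


def meridional_intensity(
    position_sets,
    Z_grid,
    mode: str = "incoherent_filaments",
    subunit_diameter_nm: float | None = None,
) -> MeridionalProfile:
    """Ensemble meridional intensity from per-filament monomer z positions.

    ``position_sets``: iterable of 1D arrays (or a 2D array) of axial
    monomer positions in nm.  Each filament diffracts coherently; the
    ensemble intensity is the sum of per-filament intensities.  Subunits are
    point scatterers unless a sphere diameter is given.
    """
    if mode != "incoherent_filaments":
        raise ValueError(f"unknown summation mode {mode!r}")
    Z = np.asarray(Z_grid, dtype=float)
    if Z.ndim != 1 or Z.size == 0:
        raise ValueError("Z grid must be a non-empty 1D array")
    if np.any(np.diff(Z) <= 0):
        raise ValueError("Z grid must be strictly increasing")
    sets = [np.asarray(p, dtype=float) for p in position_sets]
    if len(sets) == 0 or any(p.size == 0 for p in sets):
        raise ValueError("need at least one filament with at least one monomer")

    f = (sphere_form_factor(Z, subunit_diameter_nm)
         if subunit_diameter_nm else np.ones_like(Z))
    dz = np.diff(Z)
    uniform = Z.size > 2 and np.allclose(dz, dz[0], rtol=1e-9, atol=0)
    same_len = len({p.size for p in sets}) == 1
    if uniform and same_len and len(sets) * sets[0].size * Z.size > 200_000:
        from ._engine import intensity_on_uniform_grid

        stacked = np.ascontiguousarray(np.vstack(sets))
        intensity = intensity_on_uniform_grid(
            stacked, float(Z[0]), float(dz[0]), np.int64(Z.size))
    else:
        intensity = np.zeros_like(Z)
        two_pi = 2.0 * np.pi
        for z in sets:
            phase = np.exp(1j * two_pi * Z[:, None] * z[None, :])
            A = phase.sum(axis=1)
            intensity += np.abs(A) ** 2
    intensity *= f**2
    return MeridionalProfile(Z, intensity, {
        "n_filaments": len(sets),
        "coherence": mode,
        "beam_applied": False,
        "form_factor": "sphere" if subunit_diameter_nm else "point",
    })


def peak_order_window(order: int, s0: float, halfwidth: float = 0.02):
    """Search window (Z_lo, Z_hi) around the order-n reflection of the
    monomer repeat s0 (nm); relative halfwidth defaults to 2%."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if s0 <= 0:
        raise ValueError("monomer spacing must be positive")
    center = order / s0
    return center * (1.0 - halfwidth), center * (1.0 + halfwidth)


def order_window_grid(order: int, s0: float, halfwidth: float = 0.02,
                      points_per_percent: int = 2000) -> np.ndarray:
    """Uniform Z grid over the order window, >= ``points_per_percent`` grid
    points per 1% (relative) of window width."""
    z_lo, z_hi = peak_order_window(order, s0, halfwidth)
    center = order / s0
    n = max(int(np.ceil((z_hi - z_lo) / (0.01 * center) * points_per_percent)), 2) + 1
    return np.linspace(z_lo, z_hi, n)


def multi_order_profile(
    position_sets,
    s0: float,
    orders=(1, 2),
    halfwidth: float = 0.02,
    points_per_percent: int = 2000,
    beam: BeamModel | None = None,
    subunit_diameter_nm: float | None = None,
) -> MeridionalProfile:
    """Intensity over the windows of several reflection orders, concatenated
    into one profile (uniform grid within each order segment).

    Beam convolution, when requested, is applied segment-by-segment so each
    window keeps its uniform grid.  Segment boundaries are recorded in
    metadata["segments"] as (start, stop, order) index triples.
    """
    segments = []
    zs = []
    Is = []
    start = 0
    for n in orders:
        grid = order_window_grid(n, s0, halfwidth, points_per_percent)
        prof = meridional_intensity(position_sets, grid,
                                    subunit_diameter_nm=subunit_diameter_nm)
        if beam is not None:
            prof = convolve_beam(prof, beam)
        zs.append(prof.Z)
        Is.append(prof.intensity)
        segments.append((start, start + grid.size, int(n)))
        start += grid.size
    Z = np.concatenate(zs)
    I = np.concatenate(Is)
    meta = {
        "n_filaments": len(position_sets),
        "orders": [int(n) for n in orders],
        "segments": segments,
        "beam_applied": beam is not None,
        "s0_ref_nm": s0,
        "window_halfwidth": halfwidth,
    }
    if beam is not None:
        meta["beam_fwhm_nm_inv"] = beam.fwhm
    return MeridionalProfile(Z, I, meta)


def convolve_beam(profile: MeridionalProfile, beam: BeamModel) -> MeridionalProfile:
    """Smear a profile with the axial beam shape (unit-area kernel).

    Conserves integrated intensity (up to edge truncation of features well
    inside the window); requires a uniform grid finer than fwhm/5.
    """
    Z = profile.Z
    if Z.size < 3:
        raise ValueError("profile too short to convolve")
    dz = np.diff(Z)
    if not np.allclose(dz, dz[0], rtol=1e-6, atol=0):
        raise ValueError("beam convolution requires a uniform Z grid")
    h = float(dz[0])
    if h >= beam.fwhm / 5.0:
        raise ValueError(
            f"grid spacing {h:.3g} nm^-1 too coarse for beam fwhm "
            f"{beam.fwhm:.3g} nm^-1 (need < fwhm/5)")
    sigma = beam.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(4.0 * sigma / h))
    xk = np.arange(-half, half + 1) * h
    kernel = np.exp(-0.5 * (xk / sigma) ** 2)
    kernel /= kernel.sum()
    out = np.convolve(profile.intensity, kernel, mode="same")
    meta = dict(profile.metadata)
    meta["beam_applied"] = True
    meta["beam_fwhm_nm_inv"] = beam.fwhm
    return MeridionalProfile(Z.copy(), out, meta)
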
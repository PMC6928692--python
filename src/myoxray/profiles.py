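"""Metrology on 1D meridional profiles: background subtraction, peak
position by the centroid of the top half, FWHM, and spacing changes.

The top-half centroid weights each grid point above half maximum by its
excess intensity (I - Imax/2), which smooths pixelation and makes the
estimator insensitive to overall intensity scale and to any background
removed beforehand; on noiseless uniform-helix profiles the spacing error
is well below 0.05%.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffraction import MeridionalProfile

__all__ = [
    "PeakMetrics",
    "subtract_background",
    "peak_top_half_centroid",
    "delta_spacing",
]


@dataclass(frozen=True)
class PeakMetrics:
    """Measured properties of one meridional reflection.

    ``spacing`` is the Bragg spacing of the reflection, 1/Z_center — for
    order n of a repeat s0 this reads s0/n (2.73 nm and 1.365 nm for the
    first two actin orders); the underlying monomer repeat is
    ``monomer_spacing`` = order/Z_center.
    """

    order: int
    Z_center: float      # nm^-1
    spacing: float       # nm, = 1 / Z_center
    fwhm_Z: float        # nm^-1
    height: float        # a.u.

    @property
    def monomer_spacing(self) -> float:
        return self.order * self.spacing

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.fwhm_Z <= 0:
            raise ValueError("spacing and FWHM must be positive")


def _window_slice(profile: MeridionalProfile, window) -> tuple[np.ndarray, np.ndarray]:
    if window is None:
        return profile.Z, profile.intensity
    z_lo, z_hi = window
    m = (profile.Z >= z_lo) & (profile.Z <= z_hi)
    if m.sum() < 5:
        raise ValueError("window contains too few grid points")
    return profile.Z[m], profile.intensity[m]


def subtract_background(
    profile: MeridionalProfile,
    method: str = "linear_endpoints",
    window=None,
    degree: int = 3,
    edge_fraction: float = 0.08,
    edge_points: int = 5,
    clip: bool = True,
) -> MeridionalProfile:
    """Remove a smooth background under a reflection window.

    ``linear_endpoints`` draws a straight line through the mean of the first
    and last ``edge_points`` samples (exact for constant and linear
    baselines); ``polynomial_k`` fits a degree-``degree`` polynomial to the
    outer ``edge_fraction`` of the window at each end.  The residual is
    clipped at zero unless ``clip=False`` (clipping biases the mean of pure
    noise upward, so unbiasedness checks should disable it).  Errors if the
    window edges sit inside the peak core (edge intensity above half of the
    window maximum).
    """
    Z, I = _window_slice(profile, window)
    n = Z.size
    k = min(max(edge_points, 1), n // 3)
    imax = float(I.max())
    lo_level = float(I[:k].mean())
    hi_level = float(I[-k:].mean())
    if imax > 0 and max(lo_level, hi_level) > 0.5 * imax:
        raise ValueError(
            "background window endpoints lie inside the peak core; widen the window")
    if method == "linear_endpoints":
        z1, z2 = float(Z[:k].mean()), float(Z[-k:].mean())
        slope = (hi_level - lo_level) / (z2 - z1)
        base = lo_level + slope * (Z - z1)
    elif method == "polynomial_k":
        ne = max(int(np.ceil(edge_fraction * n)), degree + 1)
        idx = np.r_[0:ne, n - ne:n]
        coef = np.polynomial.polynomial.polyfit(Z[idx], I[idx], degree)
        base = np.polynomial.polynomial.polyval(Z, coef)
    else:
        raise ValueError(f"unknown background method {method!r}")
    out = np.clip(I - base, 0.0, None) if clip else I - base
    meta = dict(profile.metadata)
    meta["background"] = {"method": method, "degree": degree if method == "polynomial_k" else 1}
    return MeridionalProfile(Z.copy(), out, meta)


def peak_top_half_centroid(
    profile: MeridionalProfile,
    window=None,
    order: int = 1,
) -> PeakMetrics:
    """Locate a reflection by the centroid of its top half.

    Points with I >= Imax/2 are weighted by (I - Imax/2); the FWHM comes
    from linear interpolation of the half-height crossings.  The window must
    contain a single dominant maximum.
    """
    Z, I = _window_slice(profile, window)
    if not np.any(I > 0):
        raise ValueError("no intensity above zero in the window")
    imax = float(I.max())
    half = imax / 2.0
    above = I >= half
    if above.sum() < 1:
        raise ValueError("no point above half height")
    w = np.where(above, I - half, 0.0)
    wsum = float(w.sum())
    if wsum <= 0:
        # flat-topped plateau exactly at half height: tie broken by midpoint
        idx = np.flatnonzero(above)
        center = float(0.5 * (Z[idx[0]] + Z[idx[-1]]))
    else:
        center = float((w * Z).sum() / wsum)

    # FWHM: outermost half-height crossings around the maximum
    ipk = int(np.argmax(I))
    zl = Z[0]
    for i in range(ipk, 0, -1):
        if I[i - 1] < half <= I[i]:
            frac = (half - I[i - 1]) / (I[i] - I[i - 1])
            zl = Z[i - 1] + frac * (Z[i] - Z[i - 1])
            break
    zr = Z[-1]
    for i in range(ipk, Z.size - 1):
        if I[i] >= half > I[i + 1]:
            frac = (I[i] - half) / (I[i] - I[i + 1])
            zr = Z[i] + frac * (Z[i + 1] - Z[i])
            break
    fwhm = float(zr - zl)
    if window is not None and not (window[0] <= center <= window[1]):
        raise ValueError("peak centroid escaped the search window")
    return PeakMetrics(order=order, Z_center=center, spacing=1.0 / center,
                       fwhm_Z=fwhm, height=imax)


def delta_spacing(relaxed: PeakMetrics, contracted: PeakMetrics):
    """Spacing change Del H = s_contracted - s_relaxed and the mean strain
    in percent, from same-order reflections of the two states."""
    if relaxed.order != contracted.order:
        raise ValueError(
            f"order mismatch: relaxed n={relaxed.order}, contracted n={contracted.order}")
    del_h = contracted.spacing - relaxed.spacing
    strain_percent = 100.0 * del_h / relaxed.spacing
    return del_h, strain_percent
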
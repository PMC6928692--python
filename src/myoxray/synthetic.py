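"""Synthetic filaments, ensembles and pseudo-experimental profile pairs.

Everything a test or a closed-loop recovery needs is generated here from a
seed: uniform (relaxed) filaments, stepwise-strained filaments emulating the
random stepwise tension increments left by bound crossbridges, and full
relaxed/contracted meridional profile pairs with beam smearing, multiplicative
noise and a known per-filament force distribution.

The contracted ensemble places ``n_loads`` equal point loads per filament at
uniform-random monomer indices inside the thick-thin overlap region — the
axial statistics of crossbridge attachment in an isometric half-sarcomere —
with the per-filament total force drawn from a normal distribution truncated
at zero.  Defaults mirror the isometric reference state: 1000 thin
filaments and ~54 attached crossbridges per thin filament (72.5% of the 75
heads that can reach it).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .diffraction import BeamModel, MeridionalProfile, multi_order_profile
from .lattice import overlap_bounds
from .params import ElasticParams, GeometryParams

__all__ = [
    "uniform_filament",
    "stepwise_strained_filament",
    "synthetic_experiment",
    "SyntheticTruth",
]


def uniform_filament(n: int, h: float) -> np.ndarray:
    """Axial positions z_j = j*h of a relaxed filament of n monomers."""
    if n < 2:
        raise ValueError("need at least two monomers")
    if h <= 0:
        raise ValueError("spacing must be positive")
    return np.arange(n) * float(h)


def stepwise_strained_filament(n: int, h0: float, load_points, Ka: float) -> np.ndarray:
    """Positions of a filament loaded by point forces at monomer indices.

    ``load_points`` is a sorted list of (index, force_pN); the tension of
    segment j (between monomers j and j+1) is the sum of forces applied at
    indices > j (the filament hangs from the Z-disc at index 0), and each
    segment stretches to h0*(1 + F_j/Ka).
    """
    base = uniform_filament(n, h0)
    if Ka <= 0:
        raise ValueError("Ka must be positive")
    idx = [int(i) for i, _ in load_points]
    forces = [float(f) for _, f in load_points]
    if any(f < 0 for f in forces):
        raise ValueError("forces must be >= 0")
    if idx != sorted(idx):
        raise ValueError("load indices must be sorted")
    if idx and (idx[0] < 0 or idx[-1] > n - 1):
        raise ValueError("load index out of range")
    if not idx:
        return base
    tension = np.zeros(n - 1)
    for i, f in zip(idx, forces):
        tension[:i] += f      # segments j < i carry the load at i
    # base + cumulative elongation keeps zero-load segments bit-identical
    # to the uniform filament
    elong = h0 * tension / Ka
    out = base.copy()
    out[1:] += np.cumsum(elong)
    return out


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic relaxed/contracted profile pair.

    Synthetic stand-in for the unavailable raw camera profiles of the
    historical experiments: everything regenerates bit-identically from
    (parameters, seed).
    """

    mean_force_pN: float
    sd_force_pN: float
    forces_pN: np.ndarray            # per-filament I-band force
    load_indices: np.ndarray         # (n_filaments, n_loads) monomer indices
    n_monomers: int
    s0_nm: float
    Ka_pN: float
    beam_fwhm_nm_inv: float | None
    noise_rel_sd: float
    seed: int

    def positions(self) -> np.ndarray:
        """Per-filament monomer positions implied by the stored loads."""
        n_fil, n_loads = self.load_indices.shape
        out = np.empty((n_fil, self.n_monomers))
        for i in range(n_fil):
            pts = sorted(
                (int(j), self.forces_pN[i] / n_loads) for j in self.load_indices[i])
            out[i] = stepwise_strained_filament(self.n_monomers, self.s0_nm, pts, self.Ka_pN)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "mean_force_pN": self.mean_force_pN,
            "sd_force_pN": self.sd_force_pN,
            "forces_pN": self.forces_pN.tolist(),
            "load_indices": self.load_indices.tolist(),
            "n_monomers": self.n_monomers,
            "s0_nm": self.s0_nm,
            "Ka_pN": self.Ka_pN,
            "beam_fwhm_nm_inv": self.beam_fwhm_nm_inv,
            "noise_rel_sd": self.noise_rel_sd,
            "seed": self.seed,
        }
        text = json.dumps(d)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["forces_pN"] = np.asarray(d["forces_pN"], dtype=float)
        d["load_indices"] = np.asarray(d["load_indices"], dtype=np.int64)
        return cls(**d)


def synthetic_experiment(
    mean_force_pN: float,
    sd_force_pN: float,
    n_filaments: int = 1000,
    beam: BeamModel | None = None,
    noise_rel_sd: float = 0.0005,
    seed: int = 0,
    geometry: GeometryParams | None = None,
    elastic: ElasticParams | None = None,
    n_loads: int = 54,
    orders=(1, 2),
    halfwidth: float = 0.02,
    points_per_percent: int = 2000,
) -> tuple[MeridionalProfile, MeridionalProfile, SyntheticTruth]:
    """Relaxed/contracted meridional profile pair with known ground truth.

    Per-filament forces ~ Normal(mean, sd) truncated at zero; the noise is
    multiplicative Gaussian on the intensity (relative SD ~5e-4, the scale
    of sub-0.05% spacing metrology).  Returns (relaxed, contracted, truth).
    """
    if mean_force_pN < 0:
        raise ValueError("mean force must be >= 0")
    if sd_force_pN < 0:
        raise ValueError("sd_force must be >= 0")
    geometry = geometry or GeometryParams(n_thick=1)
    elastic = elastic or ElasticParams()
    rng = np.random.default_rng(seed)
    n = geometry.n_monomers
    s0 = geometry.monomer_spacing_s0_nm
    Ka = elastic.Ka_pN

    if sd_force_pN == 0:
        forces = np.full(n_filaments, float(mean_force_pN))
    else:
        a = (0.0 - mean_force_pN) / sd_force_pN
        forces = stats.truncnorm.rvs(
            a, np.inf, loc=mean_force_pN, scale=sd_force_pN,
            size=n_filaments, random_state=rng)

    z_lo, _ = overlap_bounds(geometry)
    j_lo = int(np.ceil(z_lo / s0))
    load_idx = rng.integers(j_lo, n, size=(n_filaments, n_loads))

    relaxed_one = uniform_filament(n, s0)
    contracted = np.empty((n_filaments, n))
    for i in range(n_filaments):
        pts = sorted((int(j), forces[i] / n_loads) for j in load_idx[i])
        contracted[i] = stepwise_strained_filament(n, s0, pts, Ka)

    # relaxed filaments are identical: one coherent sum, scaled incoherently
    relaxed_prof = multi_order_profile([relaxed_one], s0, orders, halfwidth,
                                       points_per_percent, beam=beam)
    relaxed_prof.intensity *= n_filaments
    contracted_prof = multi_order_profile(contracted, s0, orders, halfwidth,
                                          points_per_percent, beam=beam)
    for prof in (relaxed_prof, contracted_prof):
        prof.metadata["n_filaments"] = n_filaments
        prof.metadata["noise_rel_sd"] = noise_rel_sd
    if noise_rel_sd > 0:
        # one noise field per (seed, grid point), shared by the pair: paired
        # relaxed/contracted comparisons stay exact in the zero-force limit
        for prof in (relaxed_prof, contracted_prof):
            noise_rng = np.random.default_rng([seed, 1])
            prof.intensity = np.clip(
                prof.intensity
                * (1.0 + noise_rel_sd * noise_rng.standard_normal(prof.Z.size)),
                0, None)

    truth = SyntheticTruth(
        mean_force_pN=float(mean_force_pN), sd_force_pN=float(sd_force_pN),
        forces_pN=forces, load_indices=load_idx, n_monomers=n, s0_nm=s0,
        Ka_pN=Ka, beam_fwhm_nm_inv=beam.fwhm if beam else None,
        noise_rel_sd=noise_rel_sd, seed=seed)
    return relaxed_prof, contracted_prof, truth
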
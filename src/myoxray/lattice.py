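"""Explicit half-sarcomere lattice construction.

Coordinate frame: z = 0 at the Z-disc, increasing toward the M-band.  The
thin filament occupies [0, n_monomers*s0] with monomer j resting at j*s0;
monomer 0 is anchored in the Z-disc.  Each half-thick filament hangs from the
M-band plane at z = SL/2 and carries ``n_crowns`` crowns of
``heads_per_crown`` heads.

The hexagonal lattice (each thick filament surrounded by six thin, each thin
shared by three thick, n_thin = 2 n_thick) is represented by its adjacency
only: meridional diffraction and the axial mechanics need axial positions and
the head->filament wiring, not transverse coordinates.  Adjacency uses a
periodic circulant rule so the 6:3 degree structure holds for any n_thick.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ElasticParams, GeometryParams

__all__ = [
    "Attachment",
    "LatticeState",
    "build_half_sarcomere",
    "overlap_bounds",
    "candidate_sites",
]

STATE_WEAK = 2
STATE_POST_STROKE = 3


@dataclass
class Attachment:
    """One bound crossbridge.

    ``zero_strain_offset`` enters the spring strain as
    strain = (z_crown - z_site) + offset: it is 0 in the weakly attached
    state and the power-stroke distance d in the post-stroke state, so a
    post-stroke head is unstrained when its site lies a stroke length beyond
    its crown (toward the M-band).
    """

    head_id: int
    filament_id: int
    monomer_index: int
    state: int
    zero_strain_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.state not in (STATE_WEAK, STATE_POST_STROKE):
            raise ValueError(f"attachment state must be 2 or 3, got {self.state}")


@dataclass
class LatticeState:
    """Axial positions of every node plus the current crossbridge set."""

    geometry: GeometryParams
    elastic: ElasticParams
    thin_z: np.ndarray          # (n_thin, n_monomers) absolute z, nm
    thick_z: np.ndarray         # (n_thick, n_crowns) absolute z, nm
    attachments: list[Attachment] = field(default_factory=list)
    neighbors_of_thick: np.ndarray | None = None   # (n_thick, 6) thin ids
    head_target_thin: np.ndarray | None = None     # (n_heads,) thin id per head
    seed: int = 0

    @property
    def n_thin(self) -> int:
        return self.thin_z.shape[0]

    @property
    def n_thick(self) -> int:
        return self.thick_z.shape[0]

    @property
    def heads_per_thick(self) -> int:
        return self.geometry.n_crowns * self.geometry.heads_per_crown

    @property
    def n_heads(self) -> int:
        return self.n_thick * self.heads_per_thick

    def head_thick(self, head_id: int) -> int:
        return head_id // self.heads_per_thick

    def head_crown(self, head_id: int) -> int:
        return (head_id % self.heads_per_thick) // self.geometry.heads_per_crown

    def head_z(self, head_id: int) -> float:
        """Current axial position of the head's crown anchor."""
        return float(self.thick_z[self.head_thick(head_id), self.head_crown(head_id)])

    def validate(self) -> None:
        if not np.all(np.diff(self.thin_z, axis=1) > 0):
            raise ValueError("thin filament nodes must be strictly increasing (segment inversion)")
        if not np.all(np.diff(self.thick_z, axis=1) > 0):
            raise ValueError("thick filament nodes must be strictly increasing")
        for a in self.attachments:
            if not (0 <= a.head_id < self.n_heads):
                raise ValueError(f"attachment references head {a.head_id} outside lattice")
            if not (0 <= a.filament_id < self.n_thin):
                raise ValueError(f"attachment references thin filament {a.filament_id}")
            if not (0 <= a.monomer_index < self.geometry.n_monomers):
                raise ValueError(f"attachment references monomer {a.monomer_index}")


def overlap_bounds(geometry: GeometryParams) -> tuple[float, float]:
    """Axial interval of the thin filament covered by myosin crowns.

    Returns (z_lo, z_hi) in the Z-disc frame; z_hi == z_lo signals zero
    overlap (crowns do not reach the thin filament at this sarcomere length).
    The I-band-side non-overlap length is thin_length - (z_hi - z_lo).
    """
    crowns = geometry.crown_rest_positions_nm()
    lo = max(float(crowns[0]), 0.0)
    hi = min(float(crowns[-1]), geometry.thin_length_nm)
    if hi < lo:
        return (geometry.thin_length_nm, geometry.thin_length_nm)
    return (lo, hi)


def _circulant_adjacency(n_thick: int) -> tuple[np.ndarray, np.ndarray]:
    """Periodic 6:3 bipartite wiring: thick i sees thin (2i..2i+5) mod 2N."""
    n_thin = 2 * n_thick
    neighbors = (2 * np.arange(n_thick)[:, None] + np.arange(6)[None, :]) % n_thin
    return neighbors.astype(np.int64), np.int64(n_thin)


def build_half_sarcomere(
    geometry: GeometryParams | None = None,
    elastic: ElasticParams | None = None,
    n_thick: int | None = None,
    seed: int = 0,
) -> LatticeState:
    """Construct the relaxed half-sarcomere lattice (no attachments).

    Heads are mapped to a single target thin filament each: head h of crown c
    on thick filament i targets neighbour (c + 2h) mod 6, a deterministic
    azimuthal rule that cycles crown orientation along the filament and
    spreads the 150 heads evenly over the six surrounding thin filaments.
    """
    geometry = geometry or GeometryParams()
    elastic = elastic or ElasticParams()
    if n_thick is not None:
        if n_thick < 1:
            raise ValueError("n_thick must be >= 1")
        import dataclasses

        geometry = dataclasses.replace(geometry, n_thick=n_thick, n_thin=2 * n_thick)
    n_thick = geometry.n_thick

    crowns = geometry.crown_rest_positions_nm()
    if crowns[0] < 0:
        raise ValueError(
            f"sarcomere length {geometry.sarcomere_length_um} um too short: "
            "crown region would cross the Z-disc"
        )
    z_lo, z_hi = overlap_bounds(geometry)
    if z_hi - z_lo <= 0:
        raise ValueError(
            f"sarcomere length {geometry.sarcomere_length_um} um gives zero "
            "thick-thin overlap; no crossbridge can form"
        )

    n_thin = 2 * n_thick
    thin_z = np.broadcast_to(
        np.arange(geometry.n_monomers) * geometry.monomer_spacing_s0_nm,
        (n_thin, geometry.n_monomers),
    ).copy()
    thick_z = np.broadcast_to(crowns, (n_thick, geometry.n_crowns)).copy()

    neighbors, _ = _circulant_adjacency(n_thick)
    hpc = geometry.heads_per_crown
    heads_per_thick = geometry.n_crowns * hpc
    head_target = np.empty(n_thick * heads_per_thick, dtype=np.int64)
    for i in range(n_thick):
        for c in range(geometry.n_crowns):
            for h in range(hpc):
                head_target[i * heads_per_thick + c * hpc + h] = neighbors[i, (c + 2 * h) % 6]

    return LatticeState(
        geometry=geometry,
        elastic=elastic,
        thin_z=thin_z,
        thick_z=thick_z,
        attachments=[],
        neighbors_of_thick=neighbors,
        head_target_thin=head_target,
        seed=seed,
    )


def candidate_sites(
    head_id: int, lattice: LatticeState, reach: float = 8.0
) -> list[tuple[int, int, float]]:
    """Unoccupied monomer sites the head can reach on its target filament.

    Returns (filament_id, monomer_index, x) with axial offset
    x = z_crown - z_site computed from the current (deformed) positions;
    |x| <= reach.  Empty when the head faces no part of the thin filament.
    """
    if not (0 <= head_id < lattice.n_heads):
        raise ValueError(f"head {head_id} outside lattice")
    zc = lattice.head_z(head_id)
    f = int(lattice.head_target_thin[head_id])
    occupied = {
        (a.filament_id, a.monomer_index) for a in lattice.attachments
    }
    z = lattice.thin_z[f]
    j_lo = int(np.searchsorted(z, zc - reach, side="left"))
    j_hi = int(np.searchsorted(z, zc + reach, side="right"))
    out = []
    for j in range(j_lo, j_hi):
        if (f, j) in occupied:
            continue
        out.append((f, j, float(zc - z[j])))
    return out
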
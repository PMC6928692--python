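"""Spring-network equilibrium: closed-form oracles, dense-solver agreement,
force balance and profile structure."""
import numpy as np
import pytest

import myoxray as mx
from myoxray.lattice import Attachment
from myoxray.mechanics import _engine_scalars


def _series_case():
    """One post-stroke crossbridge with a 500 nm actin path and a 200 nm
    myosin path to the fixed anchors (the 3-spring hand case)."""
    geo = mx.GeometryParams(
        sarcomere_length_um=1.4, thin_length_um=0.6, n_monomers=240,
        monomer_spacing_s0_nm=2.5, thick_length_um=1.0, n_crowns=20,
        crown_spacing_nm=10.0, bare_zone_nm=10.0, n_thick=1)
    lat = mx.build_half_sarcomere(geo, mx.ElasticParams())
    f = int(lat.head_target_thin[0])
    lat.attachments = [Attachment(head_id=0, filament_id=f, monomer_index=200,
                                  state=3, zero_strain_offset=10.5)]
    return lat, f


def _dense_solve(lat):
    """Brute-force dense linear solve of the same network (oracle)."""
    geo, ela = lat.geometry, lat.elastic
    sc = _engine_scalars(lat)
    F, M = lat.thin_z.shape
    T, C = lat.thick_z.shape
    nt = F * (M - 1)               # thin nodes 1..M-1 free
    n = nt + T * C                 # all crown nodes free

    def ti(f, j):
        return f * (M - 1) + (j - 1)

    def ki(t, c):
        return nt + t * C + c

    K = np.zeros((n, n))
    rhs = np.zeros(n)
    ka, km = sc["ka_seg"], sc["km_seg"]
    for f in range(F):
        for j in range(1, M):
            K[ti(f, j), ti(f, j)] += ka * (2 if j < M - 1 else 1)
            if j > 1:
                K[ti(f, j), ti(f, j - 1)] -= ka
            if j < M - 1:
                K[ti(f, j), ti(f, j + 1)] -= ka
    for t in range(T):
        for c in range(C):
            nb = km * (2 if 0 < c < C - 1 else 1)
            if c == C - 1:
                nb += sc["k_anchor"]
            if c == 0:
                nb += sc["titin_k"]
            K[ki(t, c), ki(t, c)] += nb
            if c > 0:
                K[ki(t, c), ki(t, c - 1)] -= km
            if c < C - 1:
                K[ki(t, c), ki(t, c + 1)] -= km
    kappa = ela.kappa_xb_pN_per_nm
    z0t = np.arange(M) * geo.monomer_spacing_s0_nm
    z0c = geo.crown_rest_positions_nm()
    hpt = lat.heads_per_thick
    hpc = geo.heads_per_crown
    for a in lat.attachments:
        t = a.head_id // hpt
        c = (a.head_id % hpt) // hpc
        b = z0c[c] - z0t[a.monomer_index] + a.zero_strain_offset
        i_a = ti(a.filament_id, a.monomer_index)
        i_m = ki(t, c)
        K[i_a, i_a] += kappa
        K[i_m, i_m] += kappa
        K[i_a, i_m] -= kappa
        K[i_m, i_a] -= kappa
        rhs[i_a] += kappa * b
        rhs[i_m] -= kappa * b
    u = np.linalg.solve(K, rhs)
    thin = np.array([np.r_[0.0, u[ti(f, 1):ti(f, M - 1) + 1]] for f in range(F)])
    thick = u[nt:].reshape(T, C)
    return z0t[None, :] + thin, z0c[None, :] + thick


class TestEquilibrium:
    def test_relaxed_lattice_stays_relaxed(self, small_lattice):
        before = small_lattice.thin_z.copy()
        mx.solve_equilibrium(small_lattice)
        np.testing.assert_allclose(small_lattice.thin_z, before, atol=1e-9)
        prof = mx.filament_tension_profile(small_lattice, 0)
        assert np.allclose(prof.tension_pN, 0.0, atol=1e-6)
        assert np.allclose(prof.spacing_nm, 2.73, atol=1e-9)

    def test_single_crossbridge_series_spring_value(self):
        lat, f = _series_case()
        mx.solve_equilibrium(lat)
        _, forces = mx.crossbridge_strains(lat)
        expect = 10.5 / (1 / 1.3 + 500 / 65000 + 200 / 132000)  # 13.49 pN
        assert forces[0] == pytest.approx(expect, rel=1e-6)

    def test_tension_profile_partial_sum_structure(self):
        lat, f = _series_case()
        mx.solve_equilibrium(lat)
        _, forces = mx.crossbridge_strains(lat)
        prof = mx.filament_tension_profile(lat, f)
        np.testing.assert_allclose(prof.tension_pN[:200], forces[0], rtol=1e-9)
        np.testing.assert_allclose(prof.tension_pN[200:], 0.0, atol=1e-9)

    def test_stiffer_filaments_transmit_more_force(self):
        forces = []
        for mult in (1.0, 2.0):
            lat, _ = _series_case()
            lat.elastic = mx.ElasticParams(Ka_pN=0.65e5 * mult, Km_pN=1.32e5 * mult)
            mx.solve_equilibrium(lat)
            _, fr = mx.crossbridge_strains(lat)
            forces.append(fr[0])
        assert forces[1] > forces[0]

    def test_sparse_matches_dense_oracle(self):
        """<=5 attachments, chain solver vs dense linear solve to 1e-10."""
        lat = mx.build_half_sarcomere(
            mx.GeometryParams(
                sarcomere_length_um=1.4, thin_length_um=0.6, n_monomers=60,
                monomer_spacing_s0_nm=10.0, thick_length_um=1.0, n_crowns=10,
                crown_spacing_nm=20.0, bare_zone_nm=20.0, n_thick=1),
            mx.ElasticParams())
        rng = np.random.default_rng(3)
        sites = rng.choice(np.arange(40, 60), size=5, replace=False)
        for i, j in enumerate(sorted(sites)):
            lat.attachments.append(Attachment(
                head_id=int(i * 3), filament_id=int(lat.head_target_thin[i * 3]),
                monomer_index=int(j), state=3, zero_strain_offset=10.5))
        thin_ref, thick_ref = _dense_solve(lat)
        mx.solve_equilibrium(lat, tol=1e-9)
        np.testing.assert_allclose(lat.thin_z, thin_ref, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(lat.thick_z, thick_ref, rtol=1e-10, atol=1e-10)

    def test_global_force_balance(self):
        lat, f = _series_case()
        mx.solve_equilibrium(lat)
        _, forces = mx.crossbridge_strains(lat)
        geo = lat.geometry
        sc = _engine_scalars(lat)
        # Z-disc reaction on each thin filament = tension of first segment
        zdisc = sc["ka_seg"] * (np.diff(lat.thin_z[:, :2], axis=1).ravel()
                                - geo.monomer_spacing_s0_nm)
        # M-band reaction = stretch of the bare-zone anchor segment
        anchor = sc["k_anchor"] * (
            (geo.half_sarcomere_nm - lat.thick_z[:, -1]) - geo.bare_zone_nm)
        assert zdisc.sum() == pytest.approx(forces.sum(), abs=1e-6)
        assert anchor.sum() == pytest.approx(forces.sum(), abs=1e-6)

    def test_displacements_linear_in_stroke_offset(self):
        """Scaling every zero-strain offset scales all displacements."""
        disps = []
        for alpha in (1.0, 0.5):
            lat, _ = _series_case()
            for a in lat.attachments:
                a.zero_strain_offset *= alpha
            z0 = lat.thin_z.copy()
            mx.solve_equilibrium(lat)
            disps.append(lat.thin_z - z0)
        np.testing.assert_allclose(disps[1], 0.5 * disps[0], rtol=1e-8, atol=1e-12)

    def test_thin_filament_reaction_equals_attached_force_sum(self):
        """Z-disc reaction of each thin filament = sum of the crossbridge
        forces applied to it, within solver tolerance."""
        lat, f = _series_case()
        a1 = lat.attachments[0]
        lat.attachments = [
            Attachment(head_id=0, filament_id=a1.filament_id, monomer_index=196,
                       state=3, zero_strain_offset=10.5),
            Attachment(head_id=3, filament_id=a1.filament_id, monomer_index=204,
                       state=2, zero_strain_offset=0.0),
            Attachment(head_id=6, filament_id=a1.filament_id, monomer_index=150,
                       state=3, zero_strain_offset=10.5),
        ]
        lat.head_target_thin[3] = a1.filament_id
        lat.head_target_thin[6] = a1.filament_id
        mx.solve_equilibrium(lat)
        _, forces = mx.crossbridge_strains(lat)
        sc = _engine_scalars(lat)
        zdisc = sc["ka_seg"] * (lat.thin_z[a1.filament_id, 1]
                                - lat.thin_z[a1.filament_id, 0]
                                - lat.geometry.monomer_spacing_s0_nm)
        assert zdisc == pytest.approx(forces.sum(), abs=1e-6)

    def test_unsolved_lattice_rejected_by_strain_query(self):
        lat, _ = _series_case()
        with pytest.raises(RuntimeError, match="equilibrium"):
            mx.crossbridge_strains(lat)

    def test_invalid_filament_id(self, small_lattice):
        with pytest.raises(ValueError):
            mx.filament_tension_profile(small_lattice, 99)


class TestEnsembleStats:
    def test_identical_filaments_zero_sd(self, small_lattice):
        stats = mx.ensemble_spacing_stats(lattice=small_lattice)
        assert np.allclose(stats.sd_spacing_nm, 0.0)
        assert np.allclose(stats.mean_spacing_nm, 2.73)

    def test_single_filament_rejected(self):
        with pytest.raises(ValueError):
            mx.ensemble_spacing_stats(np.arange(10)[None, :] * 2.73, s0_nm=2.73)

    def test_iband_plateau_spacing_value(self):
        """A 312.8 pN plateau stretches I-band spacing to 2.74314 nm; the
        whole-filament mean change is ~0.65-0.7 of the plateau change for
        overlap-distributed loads."""
        rng = np.random.default_rng(0)
        geo = mx.GeometryParams(n_thick=1)
        z_lo, _ = mx.overlap_bounds(geo)
        j_lo = int(np.ceil(z_lo / 2.73))
        ens = []
        for i in range(64):
            idx = np.sort(rng.integers(j_lo, 364, size=50))
            pts = [(int(j), 312.8 / 50) for j in idx]
            ens.append(mx.stepwise_strained_filament(364, 2.73, pts, 65000.0))
        stats = mx.ensemble_spacing_stats(np.array(ens), s0_nm=2.73)
        plateau = stats.mean_spacing_nm[stats.position_nm < z_lo].mean()
        assert plateau == pytest.approx(2.73 * (1 + 312.8 / 65000), abs=2e-5)
        g = stats.mean_to_plateau_ratio(z_lo)
        assert 0.6 <= g <= 0.7

    def test_mean_spacing_decreases_toward_tip(self):
        rng = np.random.default_rng(1)
        ens = []
        for i in range(32):
            idx = np.sort(rng.integers(120, 364, size=40))
            ens.append(mx.stepwise_strained_filament(
                364, 2.73, [(int(j), 6.0) for j in idx], 65000.0))
        stats = mx.ensemble_spacing_stats(np.array(ens), s0_nm=2.73)
        sm = np.convolve(stats.mean_spacing_nm, np.ones(20) / 20, mode="valid")
        assert np.all(np.diff(sm) <= 1e-6)
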
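import numpy as np
import pytest

from gnpcell.distribution import ClusterSet, DistributionSpec, pack_cluster, place_clusters
from gnpcell.geometry import CellModel, Compartment
from gnpcell.ranges import electron_range_um
from gnpcell.source import (
    DEFAULT_STOPPING_POWER_KEV_UM,
    BeamSpec,
    EmissionModel,
    ProtonTracks,
    _gold_path_lengths,
    emit_electrons,
    kinematic_tmax,
    primary_proton_dose,
    sample_proton_tracks,
)


class TestKinematics:
    def test_delta_ray_maximum_energies(self):
        # closed-form 2 m_e c² β²γ², cross-checked against published
        # delta-ray maximum-energy values for protons
        assert kinematic_tmax(5.0) == pytest.approx(10.9, abs=0.05)
        assert kinematic_tmax(2.0) == pytest.approx(4.4, abs=0.05)

    def test_tmax_vanishes_with_energy(self):
        assert kinematic_tmax(1e-6) < 1e-5
        with pytest.raises(ValueError):
            kinematic_tmax(0.0)


class TestBeam:
    def test_entry_points_fill_the_disc_uniformly(self):
        beam = BeamSpec(n_protons=100_000, seed=3)
        tracks = sample_proton_tracks(beam)
        r = np.linalg.norm(tracks.entry_xy, axis=1)
        assert r.max() <= 8.5
        # area ratio: fraction within half the radius is 1/4
        frac = np.mean(r <= 4.25)
        assert frac == pytest.approx(0.25, abs=0.01)

    def test_single_track_within_radius_and_deterministic(self):
        beam = BeamSpec(n_protons=1, seed=11)
        a = sample_proton_tracks(beam)
        b = sample_proton_tracks(beam)
        assert np.linalg.norm(a.entry_xy[0]) <= 8.5
        assert np.array_equal(a.entry_xy, b.entry_xy)

    def test_invalid_beam_rejected(self):
        with pytest.raises(ValueError):
            BeamSpec(n_protons=0)
        with pytest.raises(ValueError):
            BeamSpec(diameter_um=0.0)


@pytest.fixture(scope="module")
def beam_and_clusters():
    cell = CellModel()
    spec = DistributionSpec(50, 0.2, 100, "perinuclear", 1.0, seed=42)
    clusters = place_clusters(spec, cell)
    beam = BeamSpec(n_protons=20_000, seed=7)
    tracks = sample_proton_tracks(beam)
    return tracks, clusters


class TestEmission:
    def test_energy_bookkeeping_is_exact(self, beam_and_clusters):
        tracks, clusters = beam_and_clusters
        ps = emit_electrons(tracks, clusters, EmissionModel(), seed=1)
        emitted = ps.emitted_kev_per_proton
        absorbed = ps.absorbed_kev_per_proton
        escaped = ps.escaped_kev_per_proton
        np.testing.assert_allclose(emitted, escaped + absorbed, rtol=1e-12, atol=1e-12)

    def test_energies_and_directions_are_valid(self, beam_and_clusters):
        tracks, clusters = beam_and_clusters
        model = EmissionModel()
        ps = emit_electrons(tracks, clusters, model, seed=1)
        assert ps.n > 0
        assert np.all(ps.energy_kev > model.cutoff_energy_kev)
        assert np.all(ps.energy_kev <= model.tmax_kev)
        np.testing.assert_allclose(
            np.linalg.norm(ps.directions, axis=1), 1.0, rtol=1e-12
        )

    def test_forward_bias(self, beam_and_clusters):
        tracks, clusters = beam_and_clusters
        ps = emit_electrons(tracks, clusters, EmissionModel(), seed=1)
        assert ps.directions[:, 2].mean() > 0.05
        # energetic delta rays are kinematically forward-focused
        hi = ps.energy_kev > 0.5 * kinematic_tmax(5.0)
        assert ps.directions[hi, 2].mean() > ps.directions[:, 2].mean()

    def test_isotropic_when_bias_disabled(self, beam_and_clusters):
        tracks, clusters = beam_and_clusters
        ps = emit_electrons(
            tracks, clusters, EmissionModel(forward_bias_kappa=0.0), seed=1
        )
        assert abs(ps.directions[:, 2].mean()) < 0.05

    def test_identical_materials_give_identical_phase_space(self, beam_and_clusters):
        """With equal coefficients the gold/water contrast vanishes, so the
        water baseline reproduces the gold run exactly (same seed) and all
        enhancement ratios downstream are 1."""
        tracks, clusters = beam_and_clusters
        model = EmissionModel(
            emission_coeff_gold=5.0,
            emission_coeff_water=5.0,
            attenuation_gold=50.0,
            attenuation_water=49.999999,
        )
        import dataclasses

        water = dataclasses.replace(clusters, material="water")
        a = emit_electrons(tracks, clusters, model, seed=4)
        b = emit_electrons(tracks, water, model, seed=4)
        assert np.array_equal(a.proton_id, b.proton_id)
        np.testing.assert_allclose(a.energy_kev, b.energy_kev, rtol=1e-6)

    def test_water_nanoparticles_absorb_less(self, beam_and_clusters):
        tracks, clusters = beam_and_clusters
        import dataclasses

        water = dataclasses.replace(clusters, material="water")
        model = EmissionModel(emission_coeff_gold=5.0, emission_coeff_water=5.0)
        g = emit_electrons(tracks, clusters, model, seed=4)
        w = emit_electrons(tracks, water, model, seed=4)
        g_frac = g.absorbed_kev_per_proton.sum() / g.emitted_kev_per_proton.sum()
        w_frac = w.absorbed_kev_per_proton.sum() / w.emitted_kev_per_proton.sum()
        assert g_frac > w_frac

    def test_phase_space_scales_with_protons(self, beam_and_clusters):
        _, clusters = beam_and_clusters
        sizes = []
        for n in (10_000, 20_000):
            tracks = sample_proton_tracks(BeamSpec(n_protons=n, seed=5))
            sizes.append(emit_electrons(tracks, clusters, EmissionModel(), seed=6).n)
        ratio = sizes[1] / sizes[0]
        assert ratio == pytest.approx(2.0, abs=4 * 2 / np.sqrt(sizes[0]))

    def test_empty_cluster_set_gives_empty_phase_space(self):
        tracks = sample_proton_tracks(BeamSpec(n_protons=10, seed=0))
        empty = ClusterSet(
            np.empty((0, 3)), 0.2, np.empty((0, 3)), np.empty(0, dtype=np.int64)
        )
        ps = emit_electrons(tracks, empty, EmissionModel(), seed=0)
        assert ps.n == 0


class TestAttenuationGeometry:
    def _brute_force_paths(self, origins, dirs, clusters, reach):
        """Independent oracle: ray-sphere chords against every nanoparticle."""
        out = np.zeros(len(origins))
        r2 = clusters.np_radius**2
        for e in range(len(origins)):
            p, d, cap = origins[e], dirs[e], reach[e]
            oc = clusters.np_positions - p
            t = oc @ d
            b2 = np.einsum("ij,ij->i", oc, oc) - t**2
            h2 = r2 - b2
            ok = h2 > 0
            h = np.sqrt(h2[ok])
            t_in = np.clip(t[ok] - h, 0.0, cap)
            t_out = np.clip(t[ok] + h, 0.0, cap)
            out[e] = np.sum(t_out - t_in)
        return out

    def test_production_paths_match_brute_force(self, beam_and_clusters, rng):
        _, clusters = beam_and_clusters
        n = 300
        origins = clusters.np_positions[rng.integers(0, clusters.n_np, n)]
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        origins = origins + clusters.np_radius * dirs
        reach = rng.uniform(0.01, 3.0, n)
        fast = _gold_path_lengths(origins, dirs, clusters, reach)
        slow = self._brute_force_paths(origins, dirs, clusters, reach)
        np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)

    def test_mean_escape_energy_drops_for_large_clusters(self):
        """Bigger clusters self-absorb more: mean escaping electron energy
        for a 500 nm cluster is below the 100 and 200 nm cases."""
        means = {}
        for diameter, n_np in [(0.1, 34), (0.2, 100), (0.5, 1298)]:
            cl = pack_cluster(diameter, n_np, seed=3)
            cs = ClusterSet(
                np.zeros((1, 3)),
                diameter,
                cl.positions,
                np.zeros(cl.n_np, dtype=np.int64),
            )
            tracks = ProtonTracks(
                np.random.default_rng(8).uniform(
                    -diameter / 2, diameter / 2, (4000, 2)
                ),
                -12.0,
                5.0,
            )
            ps = emit_electrons(tracks, cs, EmissionModel(), seed=9)
            means[diameter] = ps.energy_kev.sum() / max(ps.n, 1)
        assert means[0.5] < means[0.2]
        assert means[0.5] < means[0.1]


class TestPrimaryProtonDose:
    def test_central_track_nucleus_chord(self, cell):
        # straight through the centre: nucleus 10 µm, plus 2 x 20 nm membrane
        tracks = ProtonTracks(np.zeros((1, 2)), -12.0, 5.0)
        dose = primary_proton_dose(tracks, cell, stopping_power_kev_um=8.0)
        nucleus_plus_membrane = (
            dose[Compartment.NUCLEUS] + dose[Compartment.NUCLEAR_MEMBRANE]
        )
        assert nucleus_plus_membrane == pytest.approx(8.0e3 * 10.04, rel=1e-9)
        assert dose[Compartment.NUCLEUS] == pytest.approx(8.0e3 * 10.0, rel=1e-9)

    def test_track_missing_the_cell(self, cell):
        tracks = ProtonTracks(np.array([[9.0, 0.0]]), -12.0, 5.0)
        dose = primary_proton_dose(tracks, cell)
        assert all(v == 0.0 for v in dose.values())

    def test_default_stopping_power_matches_tabulation(self):
        # published 5 MeV proton electronic stopping power in water:
        # 7.91 keV/µm
        assert DEFAULT_STOPPING_POWER_KEV_UM == pytest.approx(7.91, rel=0.05)

    def test_dose_respects_planar_cut(self):
        from gnpcell.geometry import build_layout

        layout = build_layout("compressed", "z")
        tracks = ProtonTracks(np.zeros((1, 2)), -12.0, 5.0)
        full = primary_proton_dose(tracks, CellModel())
        cut = primary_proton_dose(tracks, layout.primary)
        # cut removes the far cap of the cytoplasm along +z
        assert cut[Compartment.CYTOPLASM] < full[Compartment.CYTOPLASM]
        assert cut[Compartment.NUCLEUS] == pytest.approx(full[Compartment.NUCLEUS])
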
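import numpy as np
import pytest

from gnpcell.chemistry import (
    DEFAULT_G_VALUES,
    SPECIES,
    ChemistryParams,
    MembranePolicy,
    SpeciesPopulation,
    Status,
    diffuse,
    generate_species,
    gini_index,
    membrane_hotspot_map,
)
from gnpcell.geometry import CellModel, Compartment
from gnpcell.transport import Deposits


def _deposits(positions, energies):
    positions = np.atleast_2d(np.asarray(positions, float))
    energies = np.asarray(energies, float)
    return Deposits(
        positions, energies, np.zeros(len(energies), dtype=np.int64), 1
    )


def _population(n, position, species_idx=0):
    return SpeciesPopulation(
        np.full(n, species_idx, dtype=np.int8),
        np.tile(np.asarray(position, float), (n, 1)),
        np.zeros(n, dtype=np.int8),
        np.zeros(n, dtype=np.int64),
    )


class TestGeneration:
    def test_zero_energy_produces_nothing(self, rng):
        pop = generate_species(_deposits([[0, 0, 0]], [0.0]), ChemistryParams(), rng)
        assert pop.n == 0

    def test_total_count_follows_total_g_value(self, rng):
        """1e5 deposits of 100 eV with ΣG per 100 eV: count = ΣG·1e5 ± 3√N."""
        g_total = sum(DEFAULT_G_VALUES.values())
        n_dep = 100_000
        dep = _deposits(np.zeros((n_dep, 3)), np.full(n_dep, 100.0))
        pop = generate_species(dep, ChemistryParams(), rng)
        expected = g_total * n_dep
        assert abs(pop.n - expected) < 3 * np.sqrt(expected)

    def test_species_proportions_match_g_values(self, rng):
        n_dep = 50_000
        dep = _deposits(np.zeros((n_dep, 3)), np.full(n_dep, 100.0))
        pop = generate_species(dep, ChemistryParams(), rng)
        g_total = sum(DEFAULT_G_VALUES.values())
        for i, name in enumerate(SPECIES):
            frac = np.mean(pop.species == i)
            expect = DEFAULT_G_VALUES[name] / g_total
            assert frac == pytest.approx(expect, abs=4 * np.sqrt(expect / pop.n) + 1e-3)

    def test_positions_blurred_around_deposits(self, rng):
        dep = _deposits([[1.0, 2.0, 3.0]], [1e5])
        params = ChemistryParams(placement_blur_sigma_nm=3.0)
        pop = generate_species(dep, params, rng)
        d = pop.positions - [1.0, 2.0, 3.0]
        assert np.std(d) == pytest.approx(3e-3, rel=0.1)


class TestDiffusion:
    def test_zero_diffusivity_is_identity(self, cell):
        params = ChemistryParams(
            diffusion_1e9_m2_s={k: 0.0 for k in SPECIES}, n_steps=5
        )
        pop = _population(100, (2.0, 0.0, 0.0))
        out, _ = diffuse(pop, cell, MembranePolicy(), params, seed=1)
        np.testing.assert_array_equal(out.positions, pop.positions)

    def test_rms_displacement_matches_brownian_theory(self, cell):
        """Free diffusion: RMS displacement = √(6 D t) within 2% at N = 1e5."""
        d9 = 2.2
        params = ChemistryParams(
            diffusion_1e9_m2_s={k: d9 for k in SPECIES}, n_steps=30
        )
        pop = _population(100_000, (0.0, 0.0, 0.0))
        out, _ = diffuse(pop, cell, MembranePolicy(), params, seed=2, record=False)
        rms = np.sqrt(np.mean(np.sum(out.positions**2, axis=1)))
        expected = np.sqrt(6 * d9 * 1e3 * 1e-6)  # 115 nm
        assert rms == pytest.approx(expected, rel=0.02)

    def test_no_drift(self, cell):
        pop = _population(50_000, (0.0, 0.0, 0.0))
        out, _ = diffuse(
            pop, cell, MembranePolicy(), ChemistryParams(n_steps=20), seed=3,
            record=False,
        )
        sigma = np.sqrt(6 * 2.2e3 * 1e-6)
        assert np.all(np.abs(out.positions.mean(axis=0)) < 4 * sigma / np.sqrt(50_000))

    def test_deep_nucleus_species_survive_absorptive_membrane(self, cell):
        """4 µm of nucleus between species and membrane dwarfs the ~0.1 µm
        diffusion length: essentially everything stays alive inside."""
        pop = _population(20_000, (0.0, 0.0, 1.0))  # 4 µm from membrane
        out, _ = diffuse(
            pop,
            cell,
            MembranePolicy(nuclear_permeability=0),
            ChemistryParams(),
            seed=4,
            record=False,
        )
        alive = out.status == int(Status.ALIVE)
        assert np.mean(alive) > 0.9999
        labels = cell.classify(out.positions[alive])
        assert np.all(labels == int(Compartment.NUCLEUS))

    def test_count_conservation_is_exact(self, cell, rng):
        dep = _deposits(
            rng.uniform(-6, 6, (2000, 3)), np.full(2000, 200.0)
        )
        pop = generate_species(dep, ChemistryParams(), rng)
        out, ts = diffuse(
            pop,
            cell,
            MembranePolicy(nuclear_permeability=0, cell_permeability=0),
            ChemistryParams(),
            seed=5,
        )
        counts = out.status_counts()
        assert sum(counts.values()) == pop.n

    def test_absorptive_membrane_only_reduces_compartment_counts(self, cell, rng):
        """Matched seeds: permeable alive counts ≥ absorptive alive counts
        in every compartment."""
        dep = _deposits(rng.uniform(-5.8, 5.8, (3000, 3)), np.full(3000, 150.0))
        params = ChemistryParams()
        pop = generate_species(dep, params, np.random.default_rng(6))
        perm, ts_p = diffuse(pop, cell, MembranePolicy(), params, seed=7)
        absb, ts_a = diffuse(
            pop, cell, MembranePolicy(nuclear_permeability=0), params, seed=7
        )
        t_end = ts_p.t_s.max()
        for comp in ("nucleus", "cytoplasm", "nuclear_membrane", "cell_membrane"):
            p = ts_p[(ts_p.t_s == t_end) & (ts_p.compartment == comp)]["count"].sum()
            a = ts_a[(ts_a.t_s == t_end) & (ts_a.compartment == comp)]["count"].sum()
            assert p >= a

    def test_absorbed_positions_lie_in_the_membrane(self, cell, rng):
        dep = _deposits(rng.uniform(4.5, 5.5, (500, 3)) * [[1, 0, 0]], np.full(500, 500.0))
        pop = generate_species(dep, ChemistryParams(), rng)
        out, _ = diffuse(
            pop,
            cell,
            MembranePolicy(nuclear_permeability=0),
            ChemistryParams(),
            seed=8,
            record=False,
        )
        absorbed = out.status == int(Status.ABSORBED_NUCLEAR_MEMBRANE)
        assert absorbed.sum() > 0
        labels = cell.classify(out.positions[absorbed])
        assert np.all(labels == int(Compartment.NUCLEAR_MEMBRANE))

    def test_recombination_removes_partner_pairs(self, cell):
        params = ChemistryParams(
            recombination_enabled=True,
            reaction_radius_nm=50.0,
            n_steps=3,
            diffusion_1e9_m2_s={k: 1e-6 for k in SPECIES},
        )
        oh = _population(50, (2.0, 0, 0), species_idx=0)
        e = _population(50, (2.0, 0, 0), species_idx=1)
        pop = SpeciesPopulation(
            np.concatenate([oh.species, e.species]),
            np.concatenate([oh.positions, e.positions]),
            np.concatenate([oh.status, e.status]),
            np.concatenate([oh.proton_id, e.proton_id]),
        )
        out, _ = diffuse(pop, cell, MembranePolicy(), params, seed=9, record=False)
        rec = out.status == int(Status.RECOMBINED)
        assert rec.sum() == 100  # every hydroxyl finds a solvated electron


class TestHotspotMap:
    def test_empty_map_for_permeable_run(self, cell):
        pop = _population(10, (0, 0, 0))
        counts, _, _ = membrane_hotspot_map(pop, cell)
        assert counts.sum() == 0

    def test_total_count_matches_absorbed(self, cell, rng):
        n = 500
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pop = SpeciesPopulation(
            np.zeros(n, dtype=np.int8),
            u * 5.01,
            np.full(n, int(Status.ABSORBED_NUCLEAR_MEMBRANE), dtype=np.int8),
            np.zeros(n, dtype=np.int64),
        )
        counts, _, _ = membrane_hotspot_map(pop, cell)
        assert counts.sum() == n

    def test_clustered_absorption_is_more_concentrated_than_uniform(self, cell):
        """Hotspots from localised sources beat uniform resamples of the
        same total (permutation-style oracle over 10 seeds)."""
        n = 400
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            # clustered: absorptions near two points on the shell
            centre = rng.normal(size=(2, 3))
            centre /= np.linalg.norm(centre, axis=1, keepdims=True)
            pts = np.repeat(centre, n // 2, axis=0) + rng.normal(0, 0.1, (n, 3))
            pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 5.01
            clustered = SpeciesPopulation(
                np.zeros(n, dtype=np.int8),
                pts,
                np.full(n, int(Status.ABSORBED_NUCLEAR_MEMBRANE), dtype=np.int8),
                np.zeros(n, dtype=np.int64),
            )
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            uniform = SpeciesPopulation(
                np.zeros(n, dtype=np.int8),
                u * 5.01,
                np.full(n, int(Status.ABSORBED_NUCLEAR_MEMBRANE), dtype=np.int8),
                np.zeros(n, dtype=np.int64),
            )
            gc = gini_index(membrane_hotspot_map(clustered, cell)[0])
            gu = gini_index(membrane_hotspot_map(uniform, cell)[0])
            wins += gc > gu
        assert wins == 10

    def test_gini_limits(self):
        assert gini_index(np.ones(100)) == pytest.approx(0.0, abs=1e-12)
        one_bin = np.zeros(100)
        one_bin[0] = 50
        assert gini_index(one_bin) > 0.95


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ChemistryParams(t_end_s=0.0)
    with pytest.raises(ValueError):
        ChemistryParams(g_values={"hydroxyl": -1.0})
    with pytest.raises(ValueError):
        MembranePolicy(nuclear_permeability=50)
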
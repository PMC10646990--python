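import numpy as np
import pytest

from conftest import brute_force_rdf
from stackmap.hydration_analysis import (
    DeltaRecord,
    HydrophobicityScale,
    R_ACCEPTOR,
    R_DONOR,
    compute_rdf,
    delta_surface_map,
    first_shell_peak,
    hbond_delta,
    normalize_hydrophobicity,
)
from stackmap.io_formats import AtomicConfiguration
from stackmap.scattering_theory import RDF
from stackmap.synthetic_data import ShellSpec, synth_hydration_shell


def random_config(n, box, seed, label="A"):
    rng = np.random.default_rng(seed)
    return AtomicConfiguration(
        box_side=box,
        site_labels=np.array([label] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        positions=rng.uniform(0, box, size=(n, 3)),
        charges=np.zeros(n),
        exchangeable=np.zeros(n, dtype=bool),
        molecule_ids=np.arange(n),
    )


class TestComputeRDF:
    def test_ideal_gas_is_flat(self):
        frames = [random_config(150, 20.0, seed) for seed in range(50)]
        rdf = compute_rdf(frames, ("A", "A"), bin_width=0.25, r_max=9.0)
        sel = rdf.r > 1.0
        # per-bin standard error of the frame-averaged ideal-gas estimate
        rho = 149 / 20.0**3
        expected_counts = 150 * rho * 4 * np.pi * rdf.r[sel] ** 2 * 0.25
        # same-species histograms hold each unordered pair twice -> 2x Poisson variance
        se = np.sqrt(2.0 / (expected_counts * 50))
        assert np.all(np.abs(rdf.g[sel] - 1.0) < 3.5 * se)
        assert abs(rdf.g[sel].mean() - 1.0) < 0.01

    def test_matches_brute_force_exactly(self):
        frames = [random_config(100, 12.0, 3), random_config(100, 12.0, 4)]
        mine = compute_rdf(frames, ("A", "A"), bin_width=0.2, r_max=6.0)
        r_ref, g_ref = brute_force_rdf(frames, ("A", "A"), 0.2, 6.0)
        np.testing.assert_array_equal(mine.r, r_ref)
        np.testing.assert_allclose(mine.g, g_ref, rtol=1e-12)

    def test_cross_pair_matches_brute_force(self):
        rng = np.random.default_rng(9)
        n = 120
        labels = np.array(["A"] * 40 + ["B"] * 80, dtype=object)
        cfg = AtomicConfiguration(
            box_side=15.0,
            site_labels=labels,
            elements=np.array(["C"] * n, dtype=object),
            positions=rng.uniform(0, 15, size=(n, 3)),
            charges=np.zeros(n),
            exchangeable=np.zeros(n, dtype=bool),
            molecule_ids=np.arange(n),
        )
        mine = compute_rdf(cfg, ("A", "B"), bin_width=0.25, r_max=7.0)
        r_ref, g_ref = brute_force_rdf([cfg], ("A", "B"), 0.25, 7.0)
        np.testing.assert_allclose(mine.g, g_ref, rtol=1e-12)

    def test_single_pair_occupies_one_bin(self):
        cfg = AtomicConfiguration(
            box_side=50.0,
            site_labels=np.array(["A", "B"], dtype=object),
            elements=np.array(["C", "N"], dtype=object),
            positions=np.array([[10.0, 10.0, 10.0], [13.0, 10.0, 10.0]]),
            charges=np.zeros(2),
            exchangeable=np.zeros(2, dtype=bool),
            molecule_ids=np.array([0, 1]),
        )
        rdf = compute_rdf(cfg, ("A", "B"), bin_width=0.1, r_max=10.0)
        occupied = np.flatnonzero(rdf.g > 0)
        assert len(occupied) == 1
        assert rdf.r[occupied[0]] == pytest.approx(3.05, abs=0.051)

    def test_r_max_beyond_half_box_rejected(self):
        with pytest.raises(ValueError, match="half the box"):
            compute_rdf(random_config(10, 10.0, 0), ("A", "A"), r_max=6.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty site"):
            compute_rdf(random_config(10, 10.0, 0), ("A", "ZZ"))


class TestFirstShellPeak:
    def grid(self, g):
        r = np.arange(0.025, 8.0, 0.05)
        return RDF(r=r, g=g(r), pair=("X", "OW"))

    def test_constructed_gaussian_peak(self):
        rdf = self.grid(lambda r: 1 + 2 * np.exp(-((r - 1.8) ** 2) / 0.02))
        assert first_shell_peak(rdf) == pytest.approx(1.8, abs=0.025)

    def test_flat_rdf_has_no_shell(self):
        rdf = self.grid(lambda r: np.ones_like(r))
        assert first_shell_peak(rdf) is None

    def test_first_peak_wins_over_highest(self):
        rdf = self.grid(
            lambda r: 1
            + 2 * np.exp(-((r - 1.8) ** 2) / 0.02)
            + 5 * np.exp(-((r - 3.2) ** 2) / 0.02)
        )
        assert first_shell_peak(rdf) == pytest.approx(1.8, abs=0.05)

    def test_window_outside_grid_rejected(self):
        rdf = self.grid(lambda r: np.ones_like(r))
        with pytest.raises(ValueError, match="window"):
            first_shell_peak(rdf, search_window=(0.0, 20.0))


class TestHbondDelta:
    def test_glu_like_worked_example(self):
        # carboxylate oxygen: peak shift +0.95 Å over R_donor = 0.96 Å
        delta, klass = hbond_delta(2.75, 1.80)
        assert delta == pytest.approx(0.95 / 0.96, abs=1e-12)
        assert round(delta, 3) == 0.990
        assert klass == "acceptor"

    def test_zero_shift_is_neutral(self):
        delta, klass = hbond_delta(2.8, 2.8)
        assert delta == 0.0
        assert klass == "neutral"

    def test_perfect_donor_endpoint(self):
        delta, klass = hbond_delta(2.8, 2.8 + R_ACCEPTOR)
        assert delta == pytest.approx(-1.0)
        assert klass == "donor"

    def test_clamped_beyond_endpoints(self):
        # the Tyr hydroxyl shift of −0.63 Å exceeds the geometric endpoint
        delta, klass = hbond_delta(2.8, 3.43)
        assert delta == -1.0
        assert klass == "donor"
        delta, _ = hbond_delta(3.0, 1.8)
        assert delta == 1.0

    def test_missing_peak_is_buried(self):
        delta, klass = hbond_delta(None, 2.8)
        assert delta is None and klass == "buried"


class TestDeltaSurfaceMap:
    def test_bias_signs_recovered(self):
        donor = synth_hydration_shell(ShellSpec(site_label="D", bias=-0.7, seed=1))
        acceptor = synth_hydration_shell(ShellSpec(site_label="A", bias=+0.7, seed=2))
        rec_d = delta_surface_map(donor, ["D"], r_max=10.0)[0]
        rec_a = delta_surface_map(acceptor, ["A"], r_max=10.0)[0]
        assert rec_d.delta < 0 and rec_d.klass == "donor"
        assert rec_a.delta > 0 and rec_a.klass == "acceptor"

    def test_dry_site_is_buried(self):
        cfg = synth_hydration_shell(ShellSpec(site_label="X", n_waters=400, seed=3))
        # a second site label with no water anywhere near it
        far = AtomicConfiguration(
            box_side=cfg.box_side,
            site_labels=np.append(cfg.site_labels, "DRY"),
            elements=np.append(cfg.elements, "C"),
            positions=np.vstack([cfg.positions, [1.0, 1.0, 1.0]]),
            charges=np.append(cfg.charges, 0.0),
            exchangeable=np.append(cfg.exchangeable, False),
            molecule_ids=np.append(cfg.molecule_ids, cfg.molecule_ids.max() + 1),
        )
        rec = delta_surface_map(far, ["DRY"], r_max=10.0)[0]
        assert rec.klass == "buried"
        assert rec.delta is None

    def test_pooling_matches_per_copy_average(self):
        """Pooled equivalent sites classify like the average of per-copy maps."""
        shells = [
            synth_hydration_shell(ShellSpec(site_label="X", bias=0.0, seed=s, n_waters=700))
            for s in (11, 12, 13)
        ]
        pooled = delta_surface_map(shells, ["X"], r_max=10.0)[0]
        singles = [delta_surface_map(c, ["X"], r_max=10.0)[0] for c in shells]
        assert pooled.klass == "neutral"
        assert all(s.klass == "neutral" for s in singles)
        mean_delta = np.mean([s.delta for s in singles])
        assert pooled.delta == pytest.approx(mean_delta, abs=0.05)


class TestDeltaRecordInvariants:
    def test_acceptor_sign_enforced(self):
        with pytest.raises(ValueError):
            DeltaRecord("X", 2.8, 2.9, R_DONOR, R_ACCEPTOR, 0.5, "donor")

    def test_buried_has_no_delta(self):
        with pytest.raises(ValueError):
            DeltaRecord("X", None, None, R_DONOR, R_ACCEPTOR, 0.0, "buried")


class TestHydrophobicity:
    def test_min_max_normalisation(self):
        scale = HydrophobicityScale({"A": 0.0, "B": 5.0, "C": 10.0})
        out = normalize_hydrophobicity(scale)
        assert out.values == {"A": 0.0, "B": 0.5, "C": 1.0}

    def test_unit_interval_scale_unchanged(self):
        scale = HydrophobicityScale({"A": 0.0, "B": 0.5, "C": 1.0})
        assert normalize_hydrophobicity(scale).values == scale.values

    def test_polarity_flag_reverses(self):
        scale = HydrophobicityScale(
            {"A": 0.0, "B": 0.5, "C": 1.0}, hydrophilic_positive=False
        )
        assert normalize_hydrophobicity(scale).values == {"A": 1.0, "B": 0.5, "C": 0.0}

    def test_constant_scale_rejected(self):
        with pytest.raises(ValueError):
            HydrophobicityScale({"A": 1.0, "B": 1.0})
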
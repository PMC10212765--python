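"""Generator contracts: determinism, ground-truth bookkeeping, placement."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from imcspatial import synth
from imcspatial.exceptions import ConfigurationError


def small_config(**kw):
    defaults = dict(field_size_px=(256, 256), n_cells=50, seed=7,
                    noise_model="none", psf_sigma_px=0.0)
    defaults.update(kw)
    return synth.SimulationConfig(**defaults)


class TestSimulateImage:
    def test_empty_field(self):
        img, truth = synth.simulate_image(small_config(n_cells=0))
        assert truth.n_cells == 0
        assert truth.true_mask.labels.max() == 0
        # pure background draws: every channel near its bg mean
        for m in small_config().markers:
            mix = small_config().mixture_params[m]
            assert abs(img.channel(m).mean() - mix.bg_mean) < 5 * mix.bg_sd

    def test_determinism(self):
        cfg = small_config(n_cells=200, field_size_px=(512, 512), seed=7,
                           noise_model="poisson", psf_sigma_px=1.0)
        img1, t1 = synth.simulate_image(cfg)
        img2, t2 = synth.simulate_image(cfg)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(t1.true_mask.labels, t2.true_mask.labels)
        assert t1.true_lineage == t2.true_lineage
        assert t1.true_positivity == t2.true_positivity

    def test_foreground_mean_recovered_by_direct_averaging(self):
        mixtures = {"M1": synth.MixtureParams(bg_mean=1.0, bg_sd=0.2,
                                              fg_mean=100.0, fg_sd=1.0)}
        profiles = {"cancer": {"M1": 1.0}}
        cfg = small_config(
            lineage_proportions={"cancer": 1.0},
            marker_profiles=profiles,
            mixture_params=mixtures,
        )
        img, truth = synth.simulate_image(cfg)
        nuc = truth.true_mask.labels > 0
        mean_in = img.channel("M1")[nuc].mean()
        assert abs(mean_in - 100.0) / 100.0 < 0.05

    def test_panel_has_nuclear_plus_markers(self):
        cfg = small_config()
        img, _ = synth.simulate_image(cfg)
        assert img.panel == [synth.NUCLEAR_MARKER] + cfg.markers

    def test_every_label_has_lineage_and_interior_centroid(self):
        img, truth = synth.simulate_image(small_config(n_cells=80))
        labels = truth.true_mask.labels
        present = set(np.unique(labels)) - {0}
        assert present == set(truth.true_lineage) == set(truth.true_centroids)
        for cid, (x, y) in truth.true_centroids.items():
            assert labels[int(round(y)), int(round(x))] == cid

    def test_min_separation_respected(self):
        cfg = small_config(n_cells=60, min_separation_px=12.0)
        centers, _ = synth.simulate_points(cfg)
        d = cKDTree(centers).query(centers, k=2)[0][:, 1]
        assert d.min() >= 12.0


class TestConfigValidation:
    def test_bad_proportions(self):
        with pytest.raises(ConfigurationError, match="lineage_proportions"):
            synth.simulate_image(small_config(
                lineage_proportions={"cancer": 0.7, "B cell": 0.7}))

    def test_bad_mixture_ordering(self):
        with pytest.raises(ConfigurationError, match="fg_mean"):
            synth.MixtureParams(bg_mean=5.0, fg_mean=2.0).validate("M")

    def test_bad_noise_model(self):
        with pytest.raises(ConfigurationError, match="noise_model"):
            synth.simulate_image(small_config(noise_model="salt"))


class TestApportionment:
    def test_exact_when_integral(self):
        counts = synth.apportion_lineages({"a": 0.4, "b": 0.35, "c": 0.25}, 100)
        assert counts == {"a": 40, "b": 35, "c": 25}

    @pytest.mark.parametrize("n", [1, 7, 53, 1000])
    def test_total_conserved(self, n):
        counts = synth.apportion_lineages(
            {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, n)
        assert sum(counts.values()) == n


class TestCohort:
    def test_zero_shift_identity(self):
        base = small_config(n_cells=40)
        samples = synth.simulate_cohort(base, n_pairs=2, seed=1)
        by_pair = {}
        for s in samples:
            by_pair.setdefault(s.pair_id, {})[s.condition] = s
        for pair in by_pair.values():
            fp = pair["primary"].truth.lineage_fractions()
            fr = pair["recurrent"].truth.lineage_fractions()
            for lin in fp:
                assert fp[lin] == pytest.approx(fr.get(lin, 0.0), abs=1e-12)

    def test_abundance_shift_exact_in_truth(self):
        base = small_config(n_cells=200)
        samples = synth.simulate_cohort(
            base, n_pairs=4,
            recurrent_shift={"cytotoxic T cell": 0.10}, seed=2)
        diffs = []
        by_pair = {}
        for s in samples:
            by_pair.setdefault(s.pair_id, {})[s.condition] = s
        for pair in by_pair.values():
            fp = pair["primary"].truth.lineage_fractions()
            fr = pair["recurrent"].truth.lineage_fractions()
            diffs.append(fr["cytotoxic T cell"] - fp["cytotoxic T cell"])
        assert np.mean(diffs) == pytest.approx(0.10, abs=1e-12)

    def test_mfi_shift_doubles_generating_mean(self):
        base = small_config(n_cells=100)
        samples = synth.simulate_cohort(
            base, n_pairs=1, mfi_shift={("Treg", "PD-1"): 1.0}, seed=3)
        rec = [s for s in samples if s.condition == "recurrent"][0]
        prim = [s for s in samples if s.condition == "primary"][0]
        fg_prim = prim.config.fg_mean_overrides.get(
            ("Treg", "PD-1"), prim.config.mixture_params["PD-1"].fg_mean)
        fg_rec = rec.config.fg_mean_overrides[("Treg", "PD-1")]
        assert fg_rec / fg_prim == pytest.approx(2.0)

    def test_shift_out_of_range_rejected(self):
        base = small_config()
        with pytest.raises(ConfigurationError, match="outside"):
            synth.simulate_cohort(base, 1, recurrent_shift={"cancer": 0.9})

    def test_shifted_proportions_keep_unit_sum(self):
        props = dict(synth.DEFAULT_LINEAGE_PROPORTIONS)
        out = synth.shift_proportions(props, {"Treg": 0.07, "B cell": -0.02})
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
        assert out["Treg"] == pytest.approx(props["Treg"] + 0.07, abs=1e-12)
        assert out["B cell"] == pytest.approx(props["B cell"] - 0.02, abs=1e-12)


class TestPlacementStatistics:
    def test_csr_nearest_neighbor_distance(self):
        """Mean NN distance under CSR matches the Poisson closed form.

        For a binomial process of n points in area A the edge-corrected
        expectation (Donnelly) is 0.5*sqrt(A/n) + (0.0514 + 0.041/sqrt(n))
        * P/n with P the field perimeter.
        """
        n, side, reps = 500, 1000, 20
        dists = []
        for s in range(reps):
            cfg = synth.SimulationConfig(
                field_size_px=(side, side), n_cells=n, seed=s,
                min_separation_px=0.0)
            centers, _ = synth.simulate_points(cfg)
            dists.append(cKDTree(centers).query(centers, k=2)[0][:, 1])
        observed = np.concatenate(dists)
        expected = 0.5 * np.sqrt(side * side / n) + (
            0.0514 + 0.041 / np.sqrt(n)) * (4 * side) / n
        se = observed.std() / np.sqrt(len(observed))
        assert abs(observed.mean() - expected) < 4 * se + 0.05

    def test_attraction_raises_cross_neighbor_count(self):
        """A->B neighbor count at r exceeds the CSR value under attraction."""
        def mean_ab_neighbors(placement, pairs, seed):
            cfg = synth.SimulationConfig(
                field_size_px=(600, 600), n_cells=300, seed=seed,
                placement=placement, attraction_pairs=pairs,
                min_separation_px=5.0)
            centers, lin = synth.simulate_points(cfg)
            a_idx = np.flatnonzero(lin == "macrophage")
            b_idx = np.flatnonzero(lin == "cytotoxic T cell")
            tree = cKDTree(centers[b_idx])
            counts = tree.query_ball_point(centers[a_idx], 20.0,
                                           return_length=True)
            return counts.mean()

        pairs = [("macrophage", "cytotoxic T cell", 0.8)]
        attracted = [mean_ab_neighbors("paired_attraction", pairs, s)
                     for s in range(20)]
        csr = [mean_ab_neighbors("csr", [], s) for s in range(20)]
        assert np.mean(attracted) > np.mean(csr)

    def test_thomas_is_clustered(self):
        """Thomas placement has smaller mean NN distance than CSR."""
        def mean_nn(placement, seed):
            cfg = synth.SimulationConfig(
                field_size_px=(600, 600), n_cells=200, seed=seed,
                placement=placement, min_separation_px=0.0,
                thomas_n_parents=10, thomas_offspring_sd_px=20.0)
            centers, _ = synth.simulate_points(cfg)
            return cKDTree(centers).query(centers, k=2)[0][:, 1].mean()

        thomas = np.mean([mean_nn("thomas", s) for s in range(5)])
        csr = np.mean([mean_nn("csr", s) for s in range(5)])
        assert thomas < csr
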
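"""Ground-truth recovery contracts of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from fermentome.kinetics import five_param_model
from fermentome.synthetic import (
    DEFAULT_CURVES,
    GroundTruth,
    NetworkSpec,
    SimConfig,
    _shape_curve,
    gen_fermentation,
    gen_marker_coefficients,
    gen_networks,
    gen_sensory,
    gen_taxa_trajectories,
)
from oracles import minimal_communities_powerset


class TestGenFermentation:
    def test_zero_noise_equals_model_exactly(self):
        cfg = SimConfig(seed=1, noise_sd=0.0)
        series, truth = gen_fermentation(cfg)
        for s in series:
            params = truth.true_curve_params[(s.variable, s.compartment, s.replicate)]
            assert np.allclose(s.values, five_param_model(s.times, *params))

    def test_same_seed_identical_output(self):
        a, _ = gen_fermentation(SimConfig(seed=42))
        b, _ = gen_fermentation(SimConfig(seed=42))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.values, sb.values)
            assert sa.replicate == sb.replicate and sa.variable == sb.variable

    def test_different_seed_differs(self):
        a, _ = gen_fermentation(SimConfig(seed=1))
        b, _ = gen_fermentation(SimConfig(seed=2))
        assert not np.array_equal(a[0].values, b[0].values)

    def test_residual_sd_matches_noise_level(self):
        # 100 replicates at sd 0.5: empirical residual sd within 10%
        cfg = SimConfig(seed=3, noise_sd=0.5, n_replicates=100)
        series, truth = gen_fermentation(cfg)
        resid = np.concatenate([
            s.values - five_param_model(
                s.times, *truth.true_curve_params[(s.variable, s.compartment, s.replicate)])
            for s in series
        ])
        assert np.std(resid) == pytest.approx(0.5, rel=0.10)

    def test_shapes_follow_study_design(self):
        cfg = SimConfig(seed=0, noise_sd=0.0)
        series, _ = gen_fermentation(cfg)
        by_key = {(s.variable, s.compartment): s for s in series if s.replicate == "r1"}
        temp = by_key[("temperature", "mid-box")]
        assert temp.values[-1] > temp.values[0]  # temperature rises
        pulp = by_key[("pH", "testa_pulp")]
        assert pulp.values[-1] > pulp.values[0]  # pulp pH rises
        coty = by_key[("pH", "cotyledon")]
        assert coty.values[-1] < coty.values[0]  # cotyledon pH falls

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_timepoints"):
            SimConfig(n_timepoints=2)
        with pytest.raises(ValueError, match="noise_sd"):
            SimConfig(noise_sd=-1.0)


class TestGenTaxa:
    def test_closure_sums_to_one(self):
        for traj_seed in (0, 7):
            cfg = SimConfig(seed=traj_seed)
            trajs = gen_taxa_trajectories(cfg)
            for rep in {t.replicate for t in trajs}:
                rows = np.array([t.abundances for t in trajs if t.replicate == rep])
                assert np.allclose(rows.sum(axis=0), 1.0, atol=1e-12)

    def test_single_taxon_is_identically_one(self):
        cfg = SimConfig(
            seed=0,
            taxa_spec=(("solo", "bacteria", "flat", {"level": 0.4}),),
            taxa_noise_sd=0.0,
        )
        (traj,) = [t for t in gen_taxa_trajectories(cfg) if t.replicate == "r1"]
        assert np.allclose(traj.abundances, 1.0)

    def test_rise_shape_monotone_before_normalization(self):
        t = np.linspace(0, 168, 30)
        y = _shape_curve(t, "rise", {"amplitude": 0.9, "rate": 0.1,
                                     "midpoint": 70.0, "baseline": 0.02})
        assert np.all(np.diff(y) >= 0)

    def test_rise_fall_has_interior_peak(self):
        t = np.linspace(0, 168, 100)
        y = _shape_curve(t, "rise-fall", {"amplitude": 0.9, "rate": 0.12,
                                          "midpoint": 40.0, "rate2": 0.1,
                                          "midpoint2": 110.0, "baseline": 0.0})
        i = np.argmax(y)
        assert 0 < i < 99

    def test_all_flat_zero_total_rejected(self):
        cfg = SimConfig(seed=0, taxa_spec=(("x", "bacteria", "flat", {"level": 0.0}),),
                        taxa_noise_sd=0.0)
        with pytest.raises(ValueError, match="zero total"):
            gen_taxa_trajectories(cfg)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            gen_taxa_trajectories(SimConfig(seed=0, taxa_spec=()))

    def test_determinism(self):
        a = gen_taxa_trajectories(SimConfig(seed=5))
        b = gen_taxa_trajectories(SimConfig(seed=5))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.abundances, tb.abundances)


class TestGenSensory:
    def features(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"f1": rng.uniform(size=n), "f2": rng.uniform(size=n)})

    def test_single_coefficient_direct_evaluation(self):
        X = self.features()
        cfg = SimConfig(seed=0, sensory_spec=(("attr", {"f1": 10.0}, 0.0),))
        scores = gen_sensory(X, cfg)
        assert np.allclose(scores["attr"], 10.0 * X["f1"])

    def test_zero_coefficients_zero_scores(self):
        X = self.features()
        cfg = SimConfig(seed=0, sensory_spec=(("attr", {}, 0.0),))
        assert np.allclose(gen_sensory(X, cfg)["attr"], 0.0)

    def test_noise_sd_matches_spec(self):
        X = self.features(n=1000, seed=1)
        cfg = SimConfig(seed=2, sensory_spec=(("attr", {"f1": 5.0}, 0.7),))
        scores = gen_sensory(X, cfg)
        resid = scores["attr"] - 5.0 * X["f1"]
        # no clipping bites here (5*f1 in [0,5], noise small)
        assert resid.std() == pytest.approx(0.7, rel=0.1)

    def test_vector_length_mismatch_rejected(self):
        X = self.features()
        cfg = SimConfig(seed=0, sensory_spec=(("attr", [1.0, 2.0, 3.0], 0.0),))
        with pytest.raises(ValueError, match="length"):
            gen_sensory(X, cfg)

    def test_unnormalized_features_rejected(self):
        X = self.features() * 30
        cfg = SimConfig(seed=0, sensory_spec=(("attr", {}, 0.0),))
        with pytest.raises(ValueError, match="normalized"):
            gen_sensory(X, cfg)

    def test_informative_ids_recorded(self):
        X = self.features()
        truth = GroundTruth()
        cfg = SimConfig(seed=0, sensory_spec=(("attr", {"f2": 4.0}, 0.1),))
        gen_sensory(X, cfg, truth)
        assert truth.informative_feature_ids["attr"] == ("f2",)

    def test_scores_bounded(self):
        X = self.features()
        cfg = SimConfig(seed=0, sensory_spec=(("attr", {"f1": 50.0}, 3.0),))
        s = gen_sensory(X, cfg)["attr"]
        assert s.min() >= 0.0 and s.max() <= 10.0


class TestMarkerCoefficients:
    def test_dynamic_taxa_pass_threshold_flat_do_not(self):
        df = gen_marker_coefficients(SimConfig(seed=0))
        by_taxon = df.set_index("taxon")
        assert by_taxon.loc["Acetobacteraceae", "coefficient"] >= 10
        assert by_taxon.loc["Saccharomyces", "coefficient"] >= 5
        assert by_taxon.loc["other_bacteria", "coefficient"] < 10
        assert by_taxon.loc["other_fungi", "coefficient"] < 5


class TestGenNetworks:
    def test_single_organism_chain(self):
        cfg = SimConfig(seed=0, network_spec=NetworkSpec(
            n_organisms=4, planted_community_size=1))
        nets, seeds, truth = gen_networks(cfg)
        assert len(truth.planted_community) == 1

    def test_determinism(self):
        cfg = SimConfig(seed=11)
        a = gen_networks(cfg)
        b = gen_networks(cfg)
        from fermentome.metnet import networks_to_json

        assert networks_to_json(a[0]) == networks_to_json(b[0])
        assert a[2].planted_community == b[2].planted_community

    def test_planted_community_is_exact_minimal_set(self):
        cfg = SimConfig(seed=4, network_spec=NetworkSpec(
            n_organisms=8, planted_community_size=3))
        nets, seeds, truth = gen_networks(cfg)
        size, sols = minimal_communities_powerset(
            nets, seeds.metabolites, truth.planted_targets)
        assert size == 3
        assert truth.planted_community in sols

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="planted_community_size"):
            NetworkSpec(n_organisms=2, planted_community_size=5)
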
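"""Synthetic-study generator: design, dynamics, noise model, recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from xtalk.errors import DesignError
from xtalk.simulate import SimulationTruth, score_recovery, simulate_study


class TestDesign:
    def test_default_shapes(self):
        study = simulate_study(seed=1)
        # 50 planted + 100 background genes; 4 timepoints x (6 chow + 15 HFD)
        assert study.liver.shape == (150, 84)
        assert study.aorta.shape == (120, 84)
        sheet = study.sheet.frame
        for t in (6, 12, 18, 24):
            cell = sheet[(sheet["tissue"] == "liver") & (sheet["time_weeks"] == t)]
            assert (cell["diet"] == "chow").sum() == 6
            assert (cell["diet"] == "HFD").sum() == 15

    def test_tissues_share_animals(self, small_study):
        sheet = small_study.sheet.frame
        liver_animals = set(sheet.loc[sheet["tissue"] == "liver", "animal_id"])
        aorta_animals = set(sheet.loc[sheet["tissue"] == "aorta", "animal_id"])
        assert liver_animals == aorta_animals

    def test_same_seed_identical(self):
        kw = dict(n_source=6, n_target=4, n_background=10, edges_per_target=2)
        a = simulate_study(seed=5, **kw)
        b = simulate_study(seed=5, **kw)
        pd.testing.assert_frame_equal(a.liver.frame, b.liver.frame)
        pd.testing.assert_frame_equal(a.aorta.frame, b.aorta.frame)
        pd.testing.assert_frame_equal(
            a.phenotype.frame, b.phenotype.frame
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(edges_per_target=20, n_source=5),
            dict(timepoints=(6, 12)),
            dict(n_chow=1),
            dict(dispersion=0.0),
            dict(dispersion=-1.0),
        ],
    )
    def test_infeasible_designs_rejected(self, kwargs):
        base = dict(n_source=5, n_target=4, n_background=5, edges_per_target=2)
        base.update(kwargs)
        with pytest.raises(DesignError):
            simulate_study(seed=0, **base)

    def test_truth_reuse_gives_same_network(self):
        kw = dict(n_source=6, n_target=4, n_background=5, edges_per_target=2)
        a = simulate_study(seed=5, **kw)
        b = simulate_study(seed=99, truth=a.truth, **kw)
        pd.testing.assert_frame_equal(a.truth.adjacency, b.truth.adjacency)
        # different noise draws
        assert not a.liver.frame.equals(b.liver.frame)


class TestDynamics:
    def test_counts_match_latent_in_low_noise_limit(self):
        """Replicate means approach exp(latent) as noise vanishes."""
        study = simulate_study(
            n_source=5,
            n_target=5,
            n_background=5,
            edges_per_target=1,
            n_chow=2000,
            n_hfd=2000,
            dispersion=1e-6,
            seed=2,
        )
        sheet = study.sheet.frame
        for diet in ("chow", "HFD"):
            for t in (6, 24):
                cols = sheet[
                    (sheet["tissue"] == "liver")
                    & (sheet["diet"] == diet)
                    & (sheet["time_weeks"] == t)
                ]["sample_id"]
                observed = study.liver.frame[cols].mean(axis=1)
                expected = np.exp(study.latent[("liver", diet)][t])
                ratio = observed / expected
                assert np.abs(ratio - 1).max() < 0.01

    def test_zero_adjacency_targets_flat(self):
        """Without edges, targets sit at their baseline under both diets."""
        study = simulate_study(
            n_source=5,
            n_target=5,
            n_background=5,
            edges_per_target=0,
            seed=3,
        )
        for diet in ("chow", "HFD"):
            lat = study.latent[("aorta", diet)].loc[study.truth.target_genes]
            assert np.allclose(lat.std(axis=1), 0.0)
            assert np.allclose(
                lat.iloc[:, 0], study.truth.target_baseline, atol=1e-12
            )

    def test_chow_sources_flat_hfd_monotone(self, small_study):
        truth = small_study.truth
        chow = small_study.latent[("liver", "chow")].loc[truth.source_genes]
        assert np.allclose(chow.std(axis=1), 0.0)
        hfd = small_study.latent[("liver", "HFD")].loc[truth.source_genes]
        dev = hfd.sub(truth.source_baseline, axis=0).mul(
            np.sign(truth.diet_effect), axis=0
        )
        diffs = dev.diff(axis=1).iloc[:, 1:].to_numpy()
        assert (diffs >= -1e-12).all()

    def test_target_dynamics_satisfy_decay_model(self, small_study):
        """The planted ODE holds exactly on the latent grid."""
        truth = small_study.truth
        W = (truth.effect_weight * truth.effect_sign).to_numpy()
        alpha = truth.decay_alpha.to_numpy()
        latA = small_study.latent[("aorta", "HFD")].loc[truth.target_genes].to_numpy()
        latL = small_study.latent[("liver", "HFD")].loc[truth.source_genes].to_numpy()
        u = latL - truth.source_baseline.to_numpy()[:, None]
        z = latA - truth.target_baseline.to_numpy()[:, None]
        times = np.array([6.0, 12.0, 18.0, 24.0])
        for k in range(3):
            dt = times[k + 1] - times[k]
            lhs = (z[:, k + 1] - z[:, k]) / dt + alpha * z[:, k]
            assert np.allclose(lhs, W.T @ u[:, k], atol=1e-10)


class TestGeneSets:
    def test_categories_match_truth(self, small_study):
        sets = small_study.gene_sets()
        truth = small_study.truth
        for s in sets.by_category("lipid", "inflammation", "fibrosis"):
            if s.name.startswith("liver_"):
                planted = set(s.genes) & set(truth.source_genes)
                assert planted
                assert all(truth.source_category[g] == s.category for g in planted)

    def test_expected_directions_match_diet_effect(self, small_study):
        sets = small_study.gene_sets()
        truth = small_study.truth
        for s in sets:
            if not s.name.startswith("liver_"):
                continue
            for g, d in s.expected_direction.items():
                assert d == int(np.sign(truth.diet_effect[g]))


class TestScoreRecovery:
    def _truth(self, adj):
        adj = pd.DataFrame(
            adj,
            index=[f"L{i}" for i in range(adj.shape[0])],
            columns=[f"A{j}" for j in range(adj.shape[1])],
        )
        sign = adj.copy()
        weight = adj.astype(float) * 0.1
        return SimulationTruth(
            source_genes=list(adj.index),
            target_genes=list(adj.columns),
            adjacency=adj,
            effect_sign=sign,
            effect_weight=weight,
            decay_alpha=pd.Series(0.1, index=adj.columns),
            diet_effect=pd.Series(1.0, index=adj.index),
            seed=0,
        )

    def test_perfect_ranking(self):
        adj = np.eye(3, dtype=int)
        truth = self._truth(adj)
        vim = truth.adjacency.astype(float)
        assert score_recovery(vim, truth)["auroc"] == 1.0

    def test_constant_vim_is_chance(self):
        adj = np.eye(3, dtype=int)
        truth = self._truth(adj)
        vim = truth.adjacency.astype(float) * 0 + 0.5
        assert score_recovery(vim, truth)["auroc"] == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        adj = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0]])
        truth = self._truth(adj)
        rng = np.random.default_rng(4)
        vim = pd.DataFrame(
            rng.random((3, 3)), index=truth.adjacency.index, columns=truth.adjacency.columns
        )
        scores = vim.to_numpy().ravel()
        labels = adj.ravel()
        wins = 0.0
        pairs = 0
        for i, li in enumerate(labels):
            if li != 1:
                continue
            for j, lj in enumerate(labels):
                if lj != 0:
                    continue
                pairs += 1
                if scores[i] > scores[j]:
                    wins += 1.0
                elif scores[i] == scores[j]:
                    wins += 0.5
        assert score_recovery(vim, truth)["auroc"] == pytest.approx(wins / pairs)

    def test_no_positives_rejected(self):
        truth = self._truth(np.eye(3, dtype=int))
        truth.adjacency.iloc[:, :] = 0
        truth.effect_sign.iloc[:, :] = 0
        truth.effect_weight.iloc[:, :] = 0.0
        with pytest.raises(DesignError):
            score_recovery(truth.adjacency.astype(float), truth)
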
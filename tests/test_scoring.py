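"""Lagged edge scoring, external tables and held-out evaluation."""

import numpy as np
import pandas as pd
import pytest

from regennet import preprocess as pp
from regennet import scoring
from regennet import simulate as sim
from regennet.scoring import EdgeScoreTable, GroundTruth
from regennet.simulate import GrnEdge, PlantedGrn

from conftest import scored_study


def _true_time_trajectory(pt):
    cells = list(pt.index)
    return pp.Trajectory("SC", cells, pp.TRAJECTORY_SPECS["SC"],
                         pd.Series(pt.values, index=cells))


class TestScorePairs:
    def test_noise_free_planted_edge_scores_one(self):
        grn = PlantedGrn(edges=[GrnEdge("tf001", "g0000", 1, 1.0)],
                         hub_tf="tf000", tfs=["tf000", "tf001"],
                         targets=["g0000"])
        adata, pt = sim.simulate_expression(grn, 60, noise_sd=0.0, seed=2,
                                            n_bins=20)
        # isolate the scorer from library-size effects: the lag structure
        # lives in the log expression itself
        adata.layers[pp.LOGNORM_LAYER] = np.log1p(np.asarray(adata.X))
        tbl = scoring.score_pairs(_true_time_trajectory(pt), adata,
                                  ["tf001"], n_bins=20, max_lag=3)
        score = tbl.df.set_index("target").loc["g0000", "score"]
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_constant_target_scores_zero(self):
        grn = sim.simulate_grn(4, 6, 0.8, seed=0)
        adata, pt = sim.simulate_expression(grn, 20, seed=0)
        pp.normalize(adata)
        # force one gene's normalized series exactly constant
        adata.layers[pp.LOGNORM_LAYER][:, -1] = 7.0
        flat_gene = adata.var_names[-1]
        tbl = scoring.score_pairs(_true_time_trajectory(pt), adata,
                                  grn.tfs[:2])
        assert (tbl.df.set_index("target")
                .loc[flat_gene, "score"] == 0.0).all()

    def test_rank_based_scores_invariant_to_monotone_transform(self):
        # with one cell per bin, bin means are cell values and the rank
        # correlation is exactly invariant to monotone warps
        grn = sim.simulate_grn(4, 10, 0.8, seed=6)
        adata, pt = sim.simulate_expression(grn, 4, seed=6)
        pp.normalize(adata)
        traj = _true_time_trajectory(pt)
        n_cells = adata.n_obs
        base = scoring.score_pairs(traj, adata, grn.tfs, n_bins=n_cells)
        warped = adata.copy()
        warped.layers[pp.LOGNORM_LAYER] = \
            np.expm1(warped.layers[pp.LOGNORM_LAYER]) ** 3
        after = scoring.score_pairs(traj, warped, grn.tfs, n_bins=n_cells)
        assert np.allclose(base.df["score"], after.df["score"])

    def test_missing_tf_and_missing_pseudotime_rejected(self):
        grn = sim.simulate_grn(4, 6, 0.8, seed=0)
        adata, pt = sim.simulate_expression(grn, 20, seed=0)
        pp.normalize(adata)
        with pytest.raises(ValueError, match="absent"):
            scoring.score_pairs(_true_time_trajectory(pt), adata, ["nope"])
        bare = pp.Trajectory("SC", list(adata.obs_names),
                             pp.TRAJECTORY_SPECS["SC"])
        with pytest.raises(ValueError, match="pseudotime"):
            scoring.score_pairs(bare, adata, grn.tfs[:1])
        with pytest.raises(ValueError, match="n_bins"):
            scoring.score_pairs(_true_time_trajectory(pt), adata,
                                grn.tfs[:1], n_bins=5, max_lag=5)

    def test_direction_preferred_on_lagged_edge(self):
        wins = 0
        for seed in range(20):
            grn = PlantedGrn(edges=[GrnEdge("tf001", "g0000", 1, 1.0)],
                             hub_tf="tf000", tfs=["tf000", "tf001"],
                             targets=["g0000"])
            adata, pt = sim.simulate_expression(grn, 90, noise_sd=0.5,
                                                seed=seed)
            pp.normalize(adata)
            traj = pp.assign_pseudotime(adata,
                                        pp.subset_trajectory(adata, "SC"))
            tbl = scoring.score_pairs(traj, adata, ["tf001", "g0000"])
            df = tbl.df.set_index(["tf", "target"])["score"]
            wins += df[("tf001", "g0000")] > df[("g0000", "tf001")]
        assert wins >= 18


class TestEdgeScoreTable:
    def test_duplicate_pair_rejected(self):
        df = pd.DataFrame({"tf": ["a", "a"], "target": ["b", "b"],
                           "score": [0.5, 0.6]})
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            EdgeScoreTable(df=df, trajectory="SC", provenance="external")

    def test_score_out_of_range_rejected(self):
        df = pd.DataFrame({"tf": ["a"], "target": ["b"], "score": [1.2]})
        with pytest.raises(ValueError, match="score"):
            EdgeScoreTable(df=df, trajectory="SC", provenance="external")

    def test_missing_column_rejected(self):
        df = pd.DataFrame({"tf": ["a"], "score": [0.2]})
        with pytest.raises(ValueError, match="target"):
            EdgeScoreTable(df=df, trajectory="SC", provenance="external")

    def test_load_external_roundtrip(self, tmp_path):
        df = pd.DataFrame({"tf": ["a", "a", "b"],
                           "target": ["x", "y", "x"],
                           "score": [0.1, 0.9, 0.5]})
        path = tmp_path / "scores.tsv"
        df.to_csv(path, sep="\t", index=False)
        tbl = scoring.load_external_scores(path, "SC")
        assert len(tbl.df) == 3 and tbl.provenance == "external"


class TestEvaluateHoldout:
    def test_perfect_ranking_gives_auprc_one(self):
        df = pd.DataFrame({"tf": ["v"] * 4,
                           "target": list("abcd"),
                           "score": [1.0, 1.0, 0.0, 0.0]})
        tbl = EdgeScoreTable(df=df, trajectory="SC", provenance="external")
        truth = GroundTruth(targets={"v": {"a", "b"}}, split={"v": "validation"})
        out = scoring.evaluate_holdout(tbl, truth)
        assert out["auprc"].iloc[0] == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        # permutation expectation: AUPRC of a random ranking ~ prevalence
        rng = np.random.default_rng(5)
        targets = [f"t{i}" for i in range(200)]
        true = set(targets[:20])
        aps = []
        for _ in range(100):
            df = pd.DataFrame({"tf": "v", "target": targets,
                               "score": rng.random(200)})
            tbl = EdgeScoreTable(df=df, trajectory="SC",
                                 provenance="external")
            truth = GroundTruth(targets={"v": true},
                                split={"v": "validation"})
            aps.append(scoring.evaluate_holdout(tbl, truth)["auprc"].iloc[0])
        mean = np.mean(aps)
        se = np.std(aps, ddof=1) / np.sqrt(len(aps))
        assert abs(mean - 0.1) <= 3 * se + 0.01

    def test_train_split_excluded_and_empty_validation_rejected(self):
        df = pd.DataFrame({"tf": ["t", "v"], "target": ["x", "x"],
                           "score": [0.5, 0.5]})
        tbl = EdgeScoreTable(df=df, trajectory="SC", provenance="external")
        out = scoring.evaluate_holdout(
            tbl, GroundTruth(targets={"t": {"x"}, "v": {"x"}},
                             split={"t": "train", "v": "validation"}))
        assert list(out["tf"]) == ["v"]
        with pytest.raises(ValueError, match="empty validation"):
            scoring.evaluate_holdout(
                tbl, GroundTruth(targets={"t": {"x"}}, split={"t": "train"}))

    def test_validation_tf_without_scored_true_target_rejected(self):
        df = pd.DataFrame({"tf": ["v"], "target": ["x"], "score": [0.5]})
        tbl = EdgeScoreTable(df=df, trajectory="SC", provenance="external")
        truth = GroundTruth(targets={"v": {"zzz"}}, split={"v": "validation"})
        with pytest.raises(ValueError, match="v"):
            scoring.evaluate_holdout(tbl, truth)

    def test_builtin_scorer_beats_permutation_null_on_planted_truth(self):
        gaps = []
        for seed in range(5):
            study, _, tbl = scored_study(seed, n_tfs=50, n_targets=200)
            truth = GroundTruth(targets=study.ground_truth,
                                split=study.split)
            res = scoring.evaluate_holdout(tbl, truth)
            rng = np.random.default_rng(seed)
            nulls = []
            for tf in truth.validation_tfs():
                sub = tbl.df[tbl.df.tf == tf]
                y = sub.target.isin(truth.targets[tf]).to_numpy()
                for _ in range(10):
                    nulls.append(scoring.auprc_step(
                        y, rng.permutation(sub.score.to_numpy())))
            gaps.append(res["auprc"].mean() - np.mean(nulls))
        assert np.mean(gaps) >= 0.3
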
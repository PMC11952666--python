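"""Kinase-substrate scoring, PU prediction and activity inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosnet import kinases as kin
from phosnet.diffabund import InputError
from phosnet.simdata import (
    AMINO_ACIDS,
    SimConfig,
    pssm_for,
    simulate_dataset,
    simulate_kinase_models,
)


def _matrix(rows, columns=None):
    rows = np.asarray(rows, float)
    cols = columns or [f"s{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"site{i}" for i in range(rows.shape[0])],
                        columns=cols)


class TestStableSites:
    def test_constant_sites_rank_first(self, rng):
        x = rng.normal(0, 1, size=(120, 6))
        x[:5] = 3.0  # exactly constant rows
        m = _matrix(x)
        stable = kin.select_stable_sites(m, fraction=5 / 120)
        assert set(stable) == {f"site{i}" for i in range(5)}

    def test_fraction_one_returns_all(self, rng):
        m = _matrix(rng.normal(size=(150, 6)))
        assert len(kin.select_stable_sites(m, fraction=1.0)) == 150

    def test_planted_low_variance_block_recovered(self, rng):
        x = rng.normal(0, 1, size=(1000, 8))
        x[:100] = rng.normal(0, 0.01, size=(100, 8)) + 5.0
        m = _matrix(x)
        stable = kin.select_stable_sites(m, fraction=0.1)
        assert set(stable) == {f"site{i}" for i in range(100)}

    def test_invalid_fraction_rejected(self, rng):
        m = _matrix(rng.normal(size=(120, 6)))
        with pytest.raises(InputError):
            kin.select_stable_sites(m, fraction=0.0)


class TestBatchCorrect:
    def test_single_batch_is_identity(self, rng):
        m = _matrix(rng.normal(size=(30, 6)))
        out = kin.batch_correct(m, [1] * 6, m.index[:10].tolist())
        pd.testing.assert_frame_equal(out, m)

    def test_additive_offset_removed(self, rng):
        clean = rng.normal(size=(60, 8))
        x = clean.copy()
        x[:, 4:] += 1.0  # batch 2 offset
        m = _matrix(x)
        stable = m.index[:20].tolist()
        out = kin.batch_correct(m, [1] * 4 + [2] * 4, stable)
        assert np.abs(out.to_numpy() - clean).max() < 0.05

    def test_idempotent(self, rng):
        x = rng.normal(size=(60, 8))
        x[:, 4:] += 0.7
        m = _matrix(x)
        stable = m.index[:20].tolist()
        once = kin.batch_correct(m, [1] * 4 + [2] * 4, stable)
        twice = kin.batch_correct(once, [1] * 4 + [2] * 4, stable)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-9

    def test_empty_stable_set_rejected(self, rng):
        m = _matrix(rng.normal(size=(10, 4)))
        with pytest.raises(InputError):
            kin.batch_correct(m, [1, 1, 2, 2], ["nope"])


class TestNormalizeSiteByProtein:
    @pytest.fixture()
    def linked(self):
        cfg = SimConfig(seed=31, n_proteins=150, n_phosphosites=120,
                        module_sizes=(40, 40, 40), substrates_per_kinase=10,
                        kinase_shifts={})
        return simulate_dataset(cfg)

    def test_protein_driven_change_cancels(self, linked):
        ds = linked
        out = kin.normalize_site_by_protein(
            ds.phospho_matrix, ds.protein_matrix, ds.site_table,
            ds.meta["group"])
        trait = ds.meta["trait"].to_numpy()
        site_fc = (ds.phospho_matrix.loc[:, trait == 1].mean(axis=1)
                   - ds.phospho_matrix.loc[:, trait == 0].mean(axis=1))
        parent_fc = (ds.protein_matrix.loc[:, trait == 1].mean(axis=1)
                     - ds.protein_matrix.loc[:, trait == 0].mean(axis=1))
        expected = site_fc - parent_fc.loc[
            ds.site_table.loc[site_fc.index, "protein_id"]].to_numpy()
        assert np.allclose(out["fc_norm"], expected)

    def test_missing_parent_passes_through(self, linked):
        ds = linked
        protein = ds.protein_matrix.drop(
            index=ds.site_table["protein_id"].iloc[0])
        out = kin.normalize_site_by_protein(
            ds.phospho_matrix, protein, ds.site_table, ds.meta["group"])
        orphans = ~out["normalized"]
        assert orphans.any()
        trait = ds.meta["trait"].to_numpy()
        site_fc = (ds.phospho_matrix.loc[:, trait == 1].mean(axis=1)
                   - ds.phospho_matrix.loc[:, trait == 0].mean(axis=1))
        assert np.allclose(out.loc[orphans, "fc_norm"],
                           site_fc[orphans.to_numpy()])


class TestMotifScore:
    def test_consensus_window_scores_one(self):
        pssms = simulate_kinase_models(SimConfig(n_kinases=1, seed=41))
        m = pssm_for(pssms, "KIN1")
        consensus = kin.consensus_window(m)
        rng = np.random.default_rng(0)
        others = ["".join(rng.choice(list(AMINO_ACIDS), 15)) for _ in range(30)]
        scores = kin.motif_score([consensus] + others, m)
        assert scores.iloc[0] == pytest.approx(1.0)
        assert scores.iloc[0] == scores.max()

    def test_uniform_pssm_ties_at_half(self):
        m = np.full((15, 20), 1 / 20)
        rng = np.random.default_rng(1)
        windows = ["".join(rng.choice(list(AMINO_ACIDS), 15)) for _ in range(40)]
        scores = kin.motif_score(windows, m)
        # all-ties average rank / n = (n + 1) / (2n)
        assert np.allclose(scores, 0.5, atol=1 / (2 * 40) + 1e-12)

    def test_hand_computed_log_odds_ordering(self):
        m = np.full((15, 20), 1 / 20)
        m[0] = 0.0
        m[0, 0] = 0.81  # A strongly preferred at position 1
        m[0, 1:] = 0.01
        windows = ["A" + "C" * 14, "C" * 15, "D" + "C" * 14]
        scores = kin.motif_score(windows, m)
        # log(0.81/0.05) > log(0.01/0.05) = log(0.01/0.05): A-window first,
        # the two non-A windows tie
        assert scores.iloc[0] == pytest.approx(1.0)
        assert scores.iloc[1] == scores.iloc[2]

    def test_unknown_residue_scored_at_background(self):
        m = np.full((15, 20), 1 / 20)
        scores = kin.motif_score(["X" * 15, "A" * 15], m)
        assert scores.iloc[0] == scores.iloc[1]


class TestProfileScore:
    def test_identical_profile_scores_one(self, rng):
        c = rng.normal(size=8)
        c = (c - c.mean()) / c.std(ddof=1)
        m = _matrix(c[None, :])
        assert kin.profile_score(m, c).iloc[0] == pytest.approx(1.0)

    def test_negated_profile_scores_zero(self, rng):
        c = rng.normal(size=8)
        m = _matrix(-c[None, :])
        assert kin.profile_score(m, c).iloc[0] == pytest.approx(0.0)

    def test_orthogonal_profile_scores_half(self, rng):
        c = rng.normal(size=8)
        c = c - c.mean()
        x = rng.normal(size=8)
        x = x - x.mean()
        x = x - (x @ c) / (c @ c) * c  # exact residual, r = 0
        m = _matrix(x[None, :])
        assert kin.profile_score(m, c).iloc[0] == pytest.approx(0.5, abs=1e-10)

    def test_flat_profile_scores_half(self, rng):
        m = _matrix(np.ones((1, 8)))
        c = rng.normal(size=8)
        assert kin.profile_score(m, c).iloc[0] == pytest.approx(0.5)


class TestCombinedScore:
    def test_unit_fixed_point(self):
        assert kin.combined_substrate_score(1.0, 1.0) == pytest.approx(1.0)

    def test_zero_annihilates(self):
        assert kin.combined_substrate_score(0.0, 0.9) == pytest.approx(0.0)

    def test_geometric_mean_value(self):
        assert kin.combined_substrate_score(0.64, 0.25) == pytest.approx(0.4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0.001, 0.2),
           st.floats(0, 1))
    def test_monotone_in_both_arguments(self, m, p, delta, w):
        base = kin.combined_substrate_score(m, p, w)
        assert kin.combined_substrate_score(min(m + delta, 1), p, w) >= base
        assert kin.combined_substrate_score(m, min(p + delta, 1), w) >= base


@pytest.fixture(scope="module")
def scored():
    ds = simulate_dataset(SimConfig(seed=51, n_proteins=300,
                                    n_phosphosites=300, n_kinases=2,
                                    module_sizes=(80, 80, 80),
                                    substrates_per_kinase=30))
    scores = kin.score_substrates(ds.phospho_matrix, ds.site_table,
                                  ds.pssms, ds.annotation)
    return ds, scores


class TestPuPredict:

    def test_annotated_positive_dominates_unlabeled_median(self, scored):
        _, scores = scored
        out = kin.pu_predict(scores, n_rounds=20, seed=1)
        for _, sub in out.groupby("kinase"):
            pos_med = sub.loc[sub["annotated"], "pu_probability"].median()
            unl_med = sub.loc[~sub["annotated"], "pu_probability"].median()
            assert pos_med >= unl_med

    def test_seeded_determinism(self, scored):
        _, scores = scored
        a = kin.pu_predict(scores, n_rounds=10, seed=4)
        b = kin.pu_predict(scores, n_rounds=10, seed=4)
        assert np.allclose(a["pu_probability"], b["pu_probability"])

    def test_true_substrates_ranked_high(self, scored):
        from sklearn.metrics import roc_auc_score
        ds, scores = scored
        out = kin.pu_predict(scores, n_rounds=20, seed=2)
        for k in ("KIN1", "KIN2"):
            sub = out[out["kinase"] == k]
            y = sub.index.isin(ds.ground_truth.substrate_map[k])
            assert roc_auc_score(y, sub["pu_probability"]) >= 0.8

    def test_too_few_positives_falls_back_to_combined(self, scored):
        _, scores = scored
        starved = scores.copy()
        mask = starved["kinase"] == "KIN1"
        pos_sites = starved.index[mask & starved["annotated"]][:8]
        starved.loc[mask, "annotated"] = False
        starved.loc[starved.index.isin(pos_sites[:2]) & mask, "annotated"] = True
        with pytest.warns(UserWarning, match="falling back"):
            out = kin.pu_predict(starved, n_rounds=5, seed=0)
        sub = out[out["kinase"] == "KIN1"]
        assert np.allclose(sub["pu_probability"], sub["combined"])


class TestRankTopSubstrates:
    def _scores(self, pu, motif=None, kinase="K"):
        n = len(pu)
        return pd.DataFrame({
            "kinase": kinase,
            "motif_score": motif if motif is not None else np.linspace(1, 0, n),
            "profile_score": 0.5,
            "combined": pu,
            "pu_probability": pu,
        }, index=pd.Index([f"s{i:02d}" for i in range(n)], name="site_id"))

    def test_full_ranking_is_permutation(self, rng):
        s = self._scores(rng.uniform(size=20))
        top = kin.rank_top_substrates(s, "K", 20)
        assert sorted(top) == sorted(s.index)

    def test_tie_break_by_motif_then_id(self):
        s = self._scores([0.5, 0.5, 0.5], motif=[0.1, 0.9, 0.9])
        assert kin.rank_top_substrates(s, "K", 3) == ["s01", "s02", "s00"]

    def test_hand_sorted_top_five(self):
        pu = [0.1, 0.9, 0.3, 0.8, 0.2, 0.95, 0.05, 0.5, 0.6, 0.7]
        top = kin.rank_top_substrates(self._scores(pu), "K", 5)
        assert top == ["s05", "s01", "s03", "s09", "s08"]

    def test_invalid_n_rejected(self):
        s = self._scores([0.5])
        with pytest.raises(InputError):
            kin.rank_top_substrates(s, "K", 0)
        with pytest.raises(InputError):
            kin.rank_top_substrates(s, "K", 5)


class TestKinaseActivity:
    def _norm_stats(self, fc):
        return pd.DataFrame({"fc_norm": fc},
                            index=[f"s{i}" for i in range(len(fc))])

    def test_all_zero_substrates_unchanged(self, rng):
        stats_df = self._norm_stats(np.r_[np.zeros(10), rng.normal(size=50)])
        act = kin.kinase_activity(stats_df, [f"s{i}" for i in range(10)])
        assert act.activity_score == 0
        assert act.direction == "unchanged"

    def test_symmetric_fold_changes_cancel(self, rng):
        fc = np.r_[np.tile([1.0, -1.0], 5), rng.normal(size=50)]
        act = kin.kinase_activity(self._norm_stats(fc),
                                  [f"s{i}" for i in range(10)])
        assert act.activity_score == pytest.approx(0.0)

    def test_tiny_substrate_set_has_na_p(self, rng):
        fc = rng.normal(size=20)
        act = kin.kinase_activity(self._norm_stats(fc), ["s0", "s1"])
        assert np.isnan(act.p)

    def test_shifted_kinases_recovered(self):
        # default generator: KIN1 +1 SD, KIN2 -1 SD on their substrates
        ok = 0
        for seed in range(4):
            ds = simulate_dataset(SimConfig(seed=100 + seed))
            norm = kin.normalize_site_by_protein(
                ds.phospho_matrix, ds.protein_matrix, ds.site_table,
                ds.meta["group"])
            prof, _ = kin.site_minus_protein_profiles(
                ds.phospho_matrix, ds.protein_matrix, ds.site_table)
            scores = kin.score_substrates(ds.phospho_matrix, ds.site_table,
                                          ds.pssms, ds.annotation)
            scores = kin.pu_predict(scores, n_rounds=20, seed=seed)
            acts = kin.infer_kinase_activities(
                norm, scores, norm_profiles=prof, groups=ds.meta["group"])
            d = acts["direction"]
            ok += (d["KIN1"] == "up") and (d["KIN2"] == "down")
        assert ok >= 3


class TestConsensusMapping:
    def _stats(self):
        fc = [1.0, -1.0, 0.1, 0.6, -0.6, 2.0, -2.0, 0.0, 0.45, -0.45]
        q = [0.01, 0.01, 0.01, 0.1, 0.1, 0.5, 0.01, 0.01, 0.15, 0.25]
        return pd.DataFrame({"fc_norm": fc, "q_bh": q},
                            index=[f"s{i}" for i in range(10)])

    def test_disjoint_annotation_yields_empty(self):
        ann = pd.DataFrame({"kinase": ["K"], "site_id": ["absent"]})
        sub, counts = kin.map_consensus_substrates(self._stats(), ann, "K",
                                                   sd_hat=0.4)
        assert counts["n_matched"] == 0
        assert len(sub) == 0

    def test_counts_match_brute_force(self):
        stats_df = self._stats()
        ann = pd.DataFrame({"kinase": "K", "site_id": stats_df.index})
        sub, counts = kin.map_consensus_substrates(stats_df, ann, "K",
                                                   sd_hat=0.4, fdr_cut=0.2,
                                                   sd_multiple=1.0)
        up = down = flat = 0
        for fc, q in zip(stats_df["fc_norm"], stats_df["q_bh"]):
            if q < 0.2 and fc > 0.4:
                up += 1
            elif q < 0.2 and fc < -0.4:
                down += 1
            else:
                flat += 1
        assert counts["n_trend_up"] == up
        assert counts["n_trend_down"] == down
        assert counts["n_flat"] == flat

    def test_zero_sd_multiple_classifies_by_sign(self):
        stats_df = self._stats()
        ann = pd.DataFrame({"kinase": "K", "site_id": stats_df.index})
        sub, counts = kin.map_consensus_substrates(stats_df, ann, "K",
                                                   sd_hat=0.4, sd_multiple=0.0)
        gate = stats_df["q_bh"] < 0.2
        assert counts["n_trend_up"] == int((gate & (stats_df["fc_norm"] > 0)).sum())
        assert counts["n_trend_down"] == int((gate & (stats_df["fc_norm"] < 0)).sum())


class TestOrderingInvariance:
    def test_scores_invariant_to_site_and_sample_order(self, small_dataset):
        ds = small_dataset
        scores = kin.score_substrates(ds.phospho_matrix, ds.site_table,
                                      ds.pssms, ds.annotation)
        rng = np.random.default_rng(3)
        site_perm = rng.permutation(ds.phospho_matrix.index)
        col_perm = rng.permutation(ds.phospho_matrix.columns)
        shuffled = ds.phospho_matrix.loc[site_perm, col_perm]
        scores2 = kin.score_substrates(shuffled, ds.site_table,
                                       ds.pssms, ds.annotation)
        for k in scores["kinase"].unique():
            a = scores[scores["kinase"] == k]["combined"]
            b = scores2[scores2["kinase"] == k]["combined"]
            assert np.allclose(a.sort_index(), b.sort_index())
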
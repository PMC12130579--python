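import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from agingatlas import AnalysisConfig, FeatureMatrix, make_sample_meta
from agingatlas.network import (ModuleSet, _scale_free_fit, adjacency,
                                detect_modules, edge_network, kmeans_modules,
                                me_cross_correlate, module_eigenfeature,
                                organ_communities, pick_soft_threshold,
                                tissue_coupling, topological_overlap)


def block_matrix(sizes, within_rho, n_samples=60, seed=0, n_noise=0):
    """Equicorrelated feature blocks plus optional independent noise features."""
    rng = np.random.default_rng(seed)
    rows, names = [], []
    a = np.sqrt(within_rho)
    b = np.sqrt(1 - within_rho)
    for bi, size in enumerate(sizes):
        g = rng.normal(size=n_samples)
        for i in range(size):
            rows.append(a * g + b * rng.normal(size=n_samples))
            names.append(f"b{bi}_f{i}")
    for i in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        names.append(f"noise_{i}")
    return pd.DataFrame(rows, index=names,
                        columns=[f"s{j}" for j in range(n_samples)])


class TestOrganCommunities:
    def _mats(self, corr_pairs, n_feat=300, seed=0):
        """Tissues whose mean profiles share a latent pattern per cluster."""
        rng = np.random.default_rng(seed)
        tissues = sorted({t for pair in corr_pairs for t in pair})
        latents = {}
        mats = {}
        for t in tissues:
            cluster = next((i for i, pair in enumerate(corr_pairs)
                            if t in pair), None)
            if cluster not in latents:
                latents[cluster] = rng.normal(size=n_feat)
            profile = 2.0 * latents[cluster] + 0.3 * rng.normal(size=n_feat)
            vals = profile[:, None] + rng.normal(0, 0.05, (n_feat, 2))
            mats[t] = FeatureMatrix(pd.DataFrame(
                vals, index=[f"f{i}" for i in range(n_feat)],
                columns=[f"{t}_a", f"{t}_b"]))
        return mats

    def test_single_pair_community(self, cfg):
        mats = self._mats([("T1", "T2"), ("T3",), ("T4",)])
        comms, coexpr, corr = organ_communities(mats, cfg)
        assert comms == [["T1", "T2"]]
        assert corr.loc["T1", "T2"] > 0.6
        assert set(coexpr[0]) == set(mats["T1"].feature_ids)

    def test_two_planted_clusters_recovered_exactly(self, cfg):
        mats = self._mats([("A1", "A2", "A3"), ("B1", "B2"), ("C1",)])
        comms, _, _ = organ_communities(mats, cfg)
        assert comms == [["A1", "A2", "A3"], ["B1", "B2"]]

    def test_edge_exactly_at_cutoff_excluded(self, cfg):
        # rho == 0.60 must not create an edge ("greater than 0.60" strict)
        tissues = ["X", "Y", "Z"]
        corr = pd.DataFrame(np.eye(3), index=tissues, columns=tissues)

        # construct three tiny profiles whose pairwise Spearman hits 0.60
        # exactly for (X,Y): n=5, sum d^2 = 8 -> rho = 1 - 48/120 = 0.6
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 5.0, 3.0, 4.0]
        z = [5.0, 1.0, 2.0, 4.0, 3.0]
        mats = {t: FeatureMatrix(pd.DataFrame(
            {f"{t}_s": v}, index=[f"f{i}" for i in range(5)]))
            for t, v in zip(tissues, (x, y, z))}
        from agingatlas.stats import spearman
        assert spearman(x, y)[0] == pytest.approx(0.6)
        comms, _, _ = organ_communities(mats, cfg)
        assert comms == []


class TestKmeansModules:
    def test_planted_centroids_perfect_ari(self):
        mat = block_matrix([25, 25, 25, 25], within_rho=0.95, seed=1)
        out = kmeans_modules(mat, 4, seed=0)
        truth = [n.split("_")[0] for n in mat.index]
        assert adjusted_rand_score(truth, out) == 1.0

    def test_k_one_single_module(self):
        mat = block_matrix([10], within_rho=0.5)
        out = kmeans_modules(mat, 1, seed=0)
        assert set(out) == {1}

    def test_deterministic_given_seed(self):
        mat = block_matrix([20, 20], within_rho=0.7, seed=2)
        a = kmeans_modules(mat, 2, seed=5)
        b = kmeans_modules(mat, 2, seed=5)
        assert (a == b).all()

    def test_age_delta_ordering(self):
        rng = np.random.default_rng(3)
        young = [f"y{i}" for i in range(4)]
        aged = [f"a{i}" for i in range(4)]
        down = rng.normal(0, 0.1, (20, 8)) + np.r_[np.ones(4), np.zeros(4)]
        up = rng.normal(0, 0.1, (20, 8)) + np.r_[np.zeros(4), np.ones(4)]
        mat = pd.DataFrame(np.vstack([up, down]),
                           index=[f"f{i}" for i in range(40)],
                           columns=young + aged)
        out = kmeans_modules(mat, 2, seed=0, aged_cols=aged, young_cols=young)
        # decreasing-with-age module comes first
        assert set(out.iloc[20:]) == {1} and set(out.iloc[:20]) == {2}

    def test_k_above_feature_count_rejected(self):
        with pytest.raises(ValueError):
            kmeans_modules(block_matrix([5], 0.5), 10, seed=0)


class TestSoftThreshold:
    def test_exact_power_law_fit_near_one(self):
        # degree sequence k ~ pareto => binned log-log regression ~ linear
        rng = np.random.default_rng(4)
        k = (1 + rng.pareto(2.0, 4000)) * 5
        assert _scale_free_fit(k) > 0.95

    def test_positive_slope_returns_zero(self):
        k = np.linspace(1, 10, 200)  # uniform: rising frequency with k bins?
        # force positive slope: many high-k values
        k = np.concatenate([np.full(20, 1.0), np.full(400, 10.0)]) \
            + np.random.default_rng(0).uniform(0, 0.5, 420)
        assert _scale_free_fit(k) == 0.0

    def test_matches_brute_force_adjacency(self, cfg):
        """Scan agrees with an independent brute-force recomputation."""
        mat = block_matrix([30, 30], within_rho=0.8, n_noise=40, seed=5)
        scan = pick_soft_threshold(mat, powers=range(1, 13), cfg=cfg)
        X = mat.to_numpy()
        for b, fit, kmean in zip(scan.powers, scan.fit_index,
                                 scan.mean_connectivity):
            # brute force: explicit double loop over feature pairs
            n = X.shape[0]
            A = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    r = np.corrcoef(X[i], X[j])[0, 1]
                    A[i, j] = A[j, i] = abs(r) ** b
            k = A.sum(axis=1)
            assert kmean == pytest.approx(k.mean(), abs=1e-10)
            assert fit == pytest.approx(_scale_free_fit(k), abs=1e-10)
        if scan.reached_target:
            first = min(b for b, f in zip(scan.powers, scan.fit_index)
                        if f >= cfg.wgcna_r2_target)
            assert scan.chosen_beta == first

    def test_constant_feature_excluded_with_warning(self, cfg):
        mat = block_matrix([30], within_rho=0.8, seed=6)
        mat.iloc[0] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            scan = pick_soft_threshold(mat, powers=[1, 2], cfg=cfg)
        assert np.isfinite(scan.fit_index).all()


class TestTom:
    def test_bounds_unit_interval(self):
        mat = block_matrix([20, 20], within_rho=0.6, n_noise=20, seed=7)
        A = adjacency(mat, 6)
        W = topological_overlap(A)
        assert (W >= -1e-12).all() and (W <= 1 + 1e-12).all()
        assert np.allclose(np.diag(W), 1.0)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, cfg):
        mat = block_matrix([40, 40], within_rho=0.8, n_noise=0, seed=8)
        mods = detect_modules(mat, beta=6, cfg=cfg)
        truth = [n.split("_")[0] for n in mat.index]
        keep = mods.assignment > 0
        assert keep.all()
        assert adjusted_rand_score(np.array(truth), mods.assignment) == 1.0
        assert mods.labels == {1: "PM1", 2: "PM2"}

    def test_block_below_min_size_unassigned(self, cfg):
        mat = block_matrix([40, 20], within_rho=0.85, n_noise=100, seed=9)
        mods = detect_modules(mat, beta=6, cfg=cfg)
        small = [f for f in mat.index if f.startswith("b1_")]
        big = [f for f in mat.index if f.startswith("b0_")]
        # the 20-feature block cannot form a labelled module (min size 30)
        assert set(mods.assignment[small]) != {1} or len(set(
            mods.assignment[big])) == 1
        sizes = mods.module_sizes
        assert (sizes >= cfg.wgcna_min_module).all()

    def test_identical_features_me_is_shared_profile(self):
        rng = np.random.default_rng(10)
        profile = rng.normal(size=30)
        sub = pd.DataFrame([profile] * 5, index=[f"f{i}" for i in range(5)],
                           columns=[f"s{j}" for j in range(30)])
        me = module_eigenfeature(sub)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(me.to_numpy(), z, atol=1e-9)

    def test_me_sign_flips_with_module_values(self):
        mat = block_matrix([40], within_rho=0.8, seed=11)
        m1 = detect_modules(mat, beta=6)
        m2 = detect_modules(-mat, beta=6)
        me1 = m1.eigenfeatures["PM1"]
        me2 = m2.eigenfeatures["PM1"]
        assert np.allclose(me1, -me2, atol=1e-9)

    def test_invariant_to_feature_and_sample_order(self, cfg):
        mat = block_matrix([35, 35], within_rho=0.8, n_noise=10, seed=12)
        rng = np.random.default_rng(0)
        perm_f = rng.permutation(mat.index)
        perm_s = rng.permutation(mat.columns)
        m1 = detect_modules(mat, beta=6, cfg=cfg)
        m2 = detect_modules(mat.loc[perm_f, perm_s], beta=6, cfg=cfg)
        a1 = m1.assignment.sort_index()
        a2 = m2.assignment.sort_index()
        assert adjusted_rand_score(a1, a2) == 1.0

    def test_too_few_features_single_module_zero(self, cfg):
        mat = block_matrix([10], within_rho=0.8)
        with pytest.warns(UserWarning):
            mods = detect_modules(mat, beta=6, cfg=cfg)
        assert set(mods.assignment) == {0}


def _module_set(me_frame, tag="PM"):
    return ModuleSet(omics_tag=tag,
                     assignment=pd.Series(dtype=int),
                     labels={i + 1: f"{tag}{i + 1}"
                             for i in range(me_frame.shape[1])},
                     eigenfeatures=me_frame)


class TestMeCrossCorrelate:
    def _meta(self, samples):
        half = len(samples) // 2
        return make_sample_meta([
            dict(sample_id=s, tissue="liver",
                 age_group="young" if i < half else "aged",
                 subject_id=f"m{i}", role="biological")
            for i, s in enumerate(samples)])

    def test_identical_me_gives_rho_one(self):
        rng = np.random.default_rng(16)
        samples = [f"s{i}" for i in range(20)]
        me = pd.Series(rng.normal(size=20), index=samples)
        pm = _module_set(pd.DataFrame({"PM1": me}))
        mm = _module_set(pd.DataFrame({"MM1": me}), tag="MM")
        edges, _ = me_cross_correlate(pm, mm, self._meta(samples))
        assert edges.loc[0, "rho"] == pytest.approx(1.0)
        assert edges.loc[0, "p"] < 1e-10

    def test_null_me_rho_below_045(self):
        """Independent MEs at n=40: |rho| < 0.45 in >=95% of 1000 draws."""
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(1000):
            x, y = rng.normal(size=(2, 40))
            rho = np.corrcoef(np.argsort(np.argsort(x)),
                              np.argsort(np.argsort(y)))[0, 1]
            hits += abs(rho) < 0.45
        assert hits / 1000 >= 0.95

    def test_bh_q_matches_brute_force(self):
        from agingatlas.stats import bh_adjust
        rng = np.random.default_rng(18)
        samples = [f"s{i}" for i in range(16)]
        pm = _module_set(pd.DataFrame(rng.normal(size=(16, 3)),
                                      index=samples,
                                      columns=["PM1", "PM2", "PM3"]))
        mm = _module_set(pd.DataFrame(rng.normal(size=(16, 2)),
                                      index=samples, columns=["MM1", "MM2"]),
                         tag="MM")
        edges, _ = me_cross_correlate(pm, mm, self._meta(samples))
        assert np.allclose(edges["q"], bh_adjust(edges["p"]), atol=1e-12)

    def test_too_few_shared_samples_errors(self):
        pm = _module_set(pd.DataFrame({"PM1": [1.0, 2, 3]},
                                      index=["a", "b", "c"]))
        mm = _module_set(pd.DataFrame({"MM1": [1.0, 2, 3]},
                                      index=["a", "b", "x"]), tag="MM")
        with pytest.raises(ValueError, match="shared"):
            me_cross_correlate(pm, mm, self._meta(["a", "b", "c"]))


class TestTissueCoupling:
    def _mats_meta(self, profiles, n_rep=2):
        meta_rows, mats = [], {}
        for t, prof in profiles.items():
            cols = []
            for g in ("young", "aged"):
                for r in range(n_rep):
                    sid = f"{t}_{g}{r}"
                    cols.append(sid)
                    meta_rows.append(dict(sample_id=sid, tissue=t,
                                          age_group=g, subject_id=f"{g}{r}",
                                          role="biological"))
            vals = np.tile(np.asarray(prof)[:, None], (1, len(cols)))
            mats[t] = FeatureMatrix(pd.DataFrame(
                vals, index=[f"m{i}" for i in range(len(prof))], columns=cols))
        return mats, make_sample_meta(meta_rows)

    def test_identical_profiles_off_diagonal_one(self):
        prof = list(np.random.default_rng(19).normal(size=50))
        mats, meta = self._mats_meta({"liver": prof, "heart": prof})
        out = tissue_coupling(mats, meta)
        assert out["young"].loc["liver", "heart"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(20)
        mats, meta = self._mats_meta(
            {t: list(rng.normal(size=50)) for t in ("a", "b", "c")})
        for g, mat in tissue_coupling(mats, meta).items():
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 1.0)

    def test_independent_profiles_low_rho(self):
        rng = np.random.default_rng(21)
        hits, runs = 0, 40
        for _ in range(runs):
            mats, meta = self._mats_meta(
                {"a": list(rng.normal(size=500)),
                 "b": list(rng.normal(size=500))})
            rho = tissue_coupling(mats, meta)["young"].loc["a", "b"]
            hits += abs(rho) < 0.15
        assert hits / runs >= 0.95


class TestEdgeNetwork:
    def test_feature_copy_gives_rho_one_edge(self, cfg):
        rng = np.random.default_rng(22)
        v = rng.normal(size=12)
        vals = pd.DataFrame([v, v, rng.normal(size=12)],
                            index=["orig", "copy", "other"],
                            columns=[f"s{i}" for i in range(12)])
        m = FeatureMatrix(vals)
        edges = edge_network(m, m, cfg, context="species_feature")
        hit = edges[(edges.a_id == "orig") & (edges.b_id == "copy")]
        assert len(hit) == 1 and hit.iloc[0]["rho"] == pytest.approx(1.0)

    def test_antagonist_pair_negative_edge(self, default_study, cfg):
        from agingatlas.microbiome import to_relative
        rel = to_relative(default_study.taxa_counts)
        edges = edge_network(rel, rel, cfg, context="species_feature")
        up, down = default_study.truth.antagonist_pair
        cross = edges[(edges.a_id.isin(up) & edges.b_id.isin(down))
                      | (edges.a_id.isin(down) & edges.b_id.isin(up))]
        assert (cross["rho"] < 0).any()

    def test_coupling_signs_recovered(self, cfg):
        from agingatlas import SimConfig, generate_study
        st = generate_study(SimConfig(seed=23, couple_kappa=3.0))
        taxon_t, metab_t, signs = zip(*st.truth.coupling_signs)
        tissue = st.meta.loc[st.metabolome[list(st.metabolome)[0]]
                             .sample_ids[0], "tissue"]
        metab = st.metabolome[tissue]
        from agingatlas.microbiome import to_relative
        rel = to_relative(st.taxa_counts)
        sub_rel = FeatureMatrix(rel.values.loc[list(set(taxon_t))], "log_intensity")
        sub_met = metab.copy(values=metab.values.loc[list(set(metab_t))])
        loose = AnalysisConfig(rho_cutoff=0.6)
        edges = edge_network(sub_rel, sub_met, loose,
                             context="species_feature", meta=st.meta)
        got = {(r.a_id, r.b_id): r.rho for r in edges.itertuples()}
        found_ok = 0
        for taxon, metab_id, sign in st.truth.coupling_signs:
            rho = got.get((taxon, metab_id))
            if rho is not None:
                found_ok += (rho > 0) == (sign == "positive")
        assert found_ok >= len(st.truth.coupling_signs) - 1

    def test_no_shared_samples_errors(self, cfg):
        a = FeatureMatrix(pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["f"],
                                       columns=list("abcd")))
        b = FeatureMatrix(pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                                       columns=list("wxyz")))
        with pytest.raises(ValueError, match="shared"):
            edge_network(a, b, cfg)
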
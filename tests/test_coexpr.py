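import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from paneldx import coexpr, simulate
from paneldx.coexpr import (adjacency_matrix, detect_modules, merge_modules,
                            module_eigengenes, module_trait_correlation,
                            scan_soft_threshold, topological_overlap)
from paneldx.io import ExpressionStudy


def naive_tom(a):
    """O(n^3) triple-loop oracle."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def _study(matrix, prefix="g"):
    n, s = matrix.shape
    return ExpressionStudy(
        matrix=matrix,
        feature_ids=tuple(f"{prefix}{i:03d}" for i in range(n)),
        sample_ids=tuple(f"s{i}" for i in range(s)),
        groups={f"s{i}": "A" if i < s // 2 else "B" for i in range(s)},
    )


class TestTom:
    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        np.testing.assert_allclose(topological_overlap(a), naive_tom(a),
                                   atol=1e-12)

    def test_complete_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        tom = topological_overlap(a)
        assert tom[0, 2] == 0.0

    def test_random_matrix_properties(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            topological_overlap(a)


class TestSoftThreshold:
    def test_power_law_degrees_fit_high(self):
        # inverse-CDF sample from a truncated p(k) ~ k^-3 on [1, 10]; the
        # binned density is then an almost exact power law.  The residual
        # ~1e-3 deviation comes from bin-mean abscissas, so exact 1.0 is not
        # attainable from raw connectivities.
        n = 20000
        u = (np.arange(n) + 0.5) / n
        c = 1 - 10.0**-2
        k = (1 - u * c) ** (-0.5)
        fit = coexpr._scale_free_fit(k)
        assert fit > 0.998

    def test_mean_connectivity_monotone(self, module_sim):
        scan = scan_soft_threshold(module_sim.study, powers=range(1, 10))
        assert all(np.diff(scan.mean_connectivity) <= 1e-9)

    def test_degenerate_input_safe(self):
        # all genes identical up to vanishing noise: adjacency ~ 1
        rng = np.random.default_rng(2)
        base = rng.normal(size=20)
        m = np.tile(base, (10, 1)) + 1e-13 * rng.normal(size=(10, 20))
        with pytest.warns(UserWarning):
            scan = scan_soft_threshold(_study(m[:, :6]), powers=[1, 2])
        assert all(np.isfinite(f) for f in scan.r_squared)

    def test_too_few_genes_errors(self):
        m = np.random.default_rng(0).normal(size=(2, 10))
        with pytest.raises(ValueError):
            scan_soft_threshold(_study(m))


class TestDetectModules:
    def test_planted_modules_recovered(self, module_sim):
        decomp = detect_modules(module_sim.study, power=6,
                                min_module_size=10, cut_height=0.97)
        for truth in module_sim.truth_modules.values():
            jaccards = [
                len(truth & set(decomp.genes_of(m)))
                / len(truth | set(decomp.genes_of(m)))
                for m in decomp.modules
            ]
            assert max(jaccards, default=0.0) >= 0.8

    def test_no_structure_mostly_grey(self):
        rng = np.random.default_rng(3)
        study = _study(rng.normal(size=(100, 30)))
        decomp = detect_modules(study, power=6, min_module_size=10,
                                cut_height=0.97)
        grey = sum(1 for m in decomp.assignment.values() if m == "grey")
        assert grey >= 90

    def test_gene_order_invariance(self, module_sim):
        study = module_sim.study
        rng = np.random.default_rng(4)
        perm = rng.permutation(study.n_features)
        shuffled = ExpressionStudy(
            matrix=study.matrix[perm],
            feature_ids=tuple(study.feature_ids[i] for i in perm),
            sample_ids=study.sample_ids,
            groups=dict(study.groups),
        )
        a = detect_modules(study, 6, 10, 0.97)
        b = detect_modules(shuffled, 6, 10, 0.97)
        assert a.assignment == b.assignment

    def test_adjusted_rand_recovery_over_seeds(self):
        scores = []
        for seed in range(10):
            cfg = simulate.SimConfig(
                n_genes=90, group_sizes={"A": 30, "B": 30}, n_de_genes=0,
                n_modules=3, module_size=20, module_loading=0.8,
                noise_sd=0.5, seed=seed)
            sim = simulate.simulate_study(cfg)
            decomp = detect_modules(sim.study, power=6, min_module_size=10,
                                    cut_height=0.97)
            truth_label = {}
            for m, members in sim.truth_modules.items():
                for g in members:
                    truth_label[g] = m
            genes = list(sim.study.feature_ids)
            t = [truth_label.get(g, "grey") for g in genes]
            p = [decomp.assignment[g] for g in genes]
            scores.append(adjusted_rand_score(t, p))
        assert np.mean(scores) >= 0.7


class TestEigengenes:
    def test_identical_genes_module(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(size=12)
        m = np.tile(profile, (5, 1))
        study = _study(m)
        eig = module_eigengenes(study, {f: "M1" for f in study.feature_ids})
        standardized = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(eig.loc["M1"], standardized)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_unit_variance(self, module_sim):
        decomp = detect_modules(module_sim.study, 6, 10, 0.97)
        for m in decomp.modules:
            assert decomp.eigengenes.loc[m].std(ddof=0) == pytest.approx(
                1.0, abs=1e-12)

    def test_recovers_latent_factor(self):
        cfg = simulate.SimConfig(
            n_genes=60, group_sizes={"A": 25, "B": 25}, n_de_genes=0,
            n_modules=1, module_size=30, module_loading=0.9, noise_sd=0.5,
            seed=6)
        sim = simulate.simulate_study(cfg)
        assignment = {
            g: ("M1" if g in sim.truth_modules["M1"] else "grey")
            for g in sim.study.feature_ids
        }
        eig = module_eigengenes(sim.study, assignment)
        # reconstruct the factor from the module mean (loading model)
        members = sorted(sim.truth_modules["M1"])
        idx = [sim.study.feature_ids.index(g) for g in members]
        factor_proxy = sim.study.matrix[idx].mean(axis=0)
        r = np.corrcoef(eig.loc["M1"], factor_proxy)[0, 1]
        assert abs(r) >= 0.95

    def test_single_gene_module(self):
        rng = np.random.default_rng(7)
        study = _study(rng.normal(size=(3, 10)))
        eig = module_eigengenes(study, {study.feature_ids[0]: "M1",
                                        study.feature_ids[1]: "grey",
                                        study.feature_ids[2]: "grey"})
        x = study.matrix[0]
        np.testing.assert_allclose(eig.loc["M1"],
                                   (x - x.mean()) / x.std(), atol=1e-12)


class TestMerge:
    def test_shared_factor_modules_merge(self):
        # split one planted module in half: halves share the latent factor
        cfg = simulate.SimConfig(
            n_genes=50, group_sizes={"A": 25, "B": 25}, n_de_genes=0,
            n_modules=1, module_size=40, module_loading=0.9, noise_sd=0.5,
            seed=8)
        sim = simulate.simulate_study(cfg)
        members = sorted(sim.truth_modules["M1"])
        assignment = {g: "grey" for g in sim.study.feature_ids}
        for g in members[:20]:
            assignment[g] = "Ma"
        for g in members[20:]:
            assignment[g] = "Mb"
        decomp = coexpr.ModuleDecomposition(
            assignment=assignment,
            eigengenes=module_eigengenes(sim.study, assignment),
            merged_from={"Ma": ("Ma",), "Mb": ("Mb",)},
        )
        merged = merge_modules(sim.study, decomp, 0.25)
        non_grey = {m for m in merged.assignment.values() if m != "grey"}
        assert len(non_grey) == 1
        assert merged.merged_from["M1"] == ("Ma", "Mb")

    def test_zero_cut_no_merges(self, module_sim):
        decomp = detect_modules(module_sim.study, 6, 10, 0.97)
        merged = merge_modules(module_sim.study, decomp, 0.0)
        n_before = len(decomp.modules)
        assert len(merged.modules) == n_before


class TestTraitCorrelation:
    def test_eigengene_equals_trait(self):
        y = np.array([0.0] * 6 + [1.0] * 6)
        rng = np.random.default_rng(9)
        m = np.vstack([y + 1e-9 * rng.normal(size=12) for _ in range(5)])
        study = ExpressionStudy(
            matrix=m,
            feature_ids=tuple(f"g{i}" for i in range(5)),
            sample_ids=tuple(f"s{i}" for i in range(12)),
            groups={f"s{i}": ("N" if i < 6 else "P") for i in range(12)},
        )
        decomp = coexpr.ModuleDecomposition(
            assignment={f: "M1" for f in study.feature_ids},
            eigengenes=module_eigengenes(study,
                                         {f: "M1" for f in study.feature_ids}),
        )
        table = module_trait_correlation(decomp, study.groups,
                                         {"status": {"P": 1, "N": 0}})
        row = table.iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-6)
        assert row["p"] < 1e-6

    def test_trait_flip_negates_r(self, module_sim):
        decomp = detect_modules(module_sim.study, 6, 10, 0.97)
        t1 = module_trait_correlation(decomp, module_sim.study.groups,
                                      {"t": {"A": 1, "B": 0}})
        t2 = module_trait_correlation(decomp, module_sim.study.groups,
                                      {"t": {"A": 0, "B": 1}})
        np.testing.assert_allclose(t1["r"], -t2["r"], atol=1e-12)
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-12)

    def test_planted_de_module_correlates(self):
        # module genes also shifted in the case group: eigengene tracks trait
        cfg = simulate.SimConfig(
            n_genes=40, group_sizes={"Ctl": 8, "Case": 8}, n_de_genes=40,
            effect_size_log2=3.0, n_modules=1, module_size=30,
            module_loading=0.6, noise_sd=0.5, seed=10)
        sim = simulate.simulate_study(cfg)
        assignment = {
            g: ("M1" if g in sim.truth_modules["M1"] else "grey")
            for g in sim.study.feature_ids
        }
        decomp = coexpr.ModuleDecomposition(
            assignment=assignment,
            eigengenes=module_eigengenes(sim.study, assignment),
        )
        table = module_trait_correlation(decomp, sim.study.groups,
                                         {"t": {"Case": 1, "Ctl": 0}})
        assert abs(table.iloc[0]["r"]) > 0.7
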
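import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import haplodyn as hd
from haplodyn.structure_stats import DistanceMatrix, _one_level_components
from conftest import make_haplotype_table, random_symmetric_distances


def coordinate_anova_oracle(points: np.ndarray, codes: np.ndarray):
    """Independent variance decomposition from embedded coordinates.

    For points in Euclidean space (so that squared pairwise distances are
    squared Euclidean distances), the AMOVA sums of squares must equal the
    classical centroid-based multivariate ANOVA decomposition.
    """
    N = len(points)
    pops = np.unique(codes)
    grand = points.mean(axis=0)
    ss_within = sum(
        np.sum((points[codes == p] - points[codes == p].mean(axis=0)) ** 2)
        for p in pops
    )
    ss_among = sum(
        (codes == p).sum() * np.sum((points[codes == p].mean(axis=0) - grand) ** 2)
        for p in pops
    )
    sizes = np.array([(codes == p).sum() for p in pops], dtype=float)
    df_a, df_w = len(pops) - 1, N - len(pops)
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n_prime = (N - np.sum(sizes ** 2) / N) / df_a
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_prime
    return ss_among, ss_within, sigma_a, sigma_w


def euclidean_distance_matrix(points: np.ndarray) -> DistanceMatrix:
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix([f"s{i}" for i in range(len(points))], d)


class TestPairwiseDistances:
    def test_identical_haplotypes_zero(self):
        dm = hd.pairwise_distances({"a": "ACGT", "b": "ACGT"})
        assert dm.loc("a", "b") == 0

    def test_two_substitutions(self):
        dm = hd.pairwise_distances({"a": "ACGT", "b": "TCGA"})
        assert dm.loc("a", "b") == 2

    def test_star_fixture_max_distance_two(self, study_table, study_distances):
        """Within population 1's star the leaves sit 2 steps apart (via the
        central haplotype), never more."""
        hap, _ = study_distances
        p1 = study_table.counts.loc["P1"]
        present = [h for h in p1.index if p1[h] > 0]
        center = max(present, key=lambda h: p1[h])
        leaves = [h for h in present if h != center]
        frame = hap.to_frame()
        for leaf in leaves:
            assert frame.loc[center, leaf] == 1
        for a in leaves:
            for b in leaves:
                if a != b:
                    assert frame.loc[a, b] == 2

    def test_indel_character_counts_as_fifth_state(self):
        dm = hd.pairwise_distances({"a": "ACG1", "b": "ACG0"})
        assert dm.loc("a", "b") == 1


class TestAmova:
    def test_fixed_populations_phi_one(self):
        seqs = {"a": "AAAA", "b": "AAAT"}
        dm = hd.pairwise_distances(seqs)
        labels = [f"x{i}" for i in range(8)]
        mat = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                mat[i, j] = dm.matrix[i // 4, j // 4]
        ind = DistanceMatrix(labels, mat)
        pops = {l: ("A" if i < 4 else "B") for i, l in enumerate(labels)}
        res = hd.amova(ind, pops)
        assert res.phi["phi_st"] == pytest.approx(1.0)
        assert res.table.set_index("source").loc["among_populations", "percent"] \
            == pytest.approx(100.0)

    @pytest.mark.parametrize("P,m", [(2, 2), (2, 4), (2, 6), (3, 2), (3, 4),
                                     (4, 3), (5, 2), (6, 2)])
    def test_balanced_designs_match_coordinate_oracle(self, P, m):
        """On every balanced design with <= 12 individuals the components
        equal the independent centroid-based decomposition."""
        rng = np.random.default_rng(P * 100 + m)
        points = rng.normal(size=(P * m, 3))
        codes = np.repeat(np.arange(P), m)
        ind = euclidean_distance_matrix(points)
        pops = {f"s{i}": f"P{codes[i]}" for i in range(P * m)}
        res = hd.amova(ind, pops)
        ss_among, ss_within, sigma_a, sigma_w = coordinate_anova_oracle(
            points, codes)
        table = res.table.set_index("source")
        assert table.loc["among_populations", "SSD"] == pytest.approx(ss_among)
        assert table.loc["within_populations", "SSD"] == pytest.approx(ss_within)
        assert table.loc["among_populations", "variance"] == pytest.approx(sigma_a)
        assert table.loc["within_populations", "variance"] == pytest.approx(sigma_w)

    def test_unbalanced_design_matches_coordinate_oracle(self):
        rng = np.random.default_rng(77)
        sizes = [3, 5, 4]
        codes = np.repeat(np.arange(3), sizes)
        points = rng.normal(size=(12, 2)) + codes[:, None] * 2.0
        ind = euclidean_distance_matrix(points)
        pops = {f"s{i}": f"P{codes[i]}" for i in range(12)}
        res = hd.amova(ind, pops)
        _, _, sigma_a, sigma_w = coordinate_anova_oracle(points, codes)
        assert res.phi["phi_st"] == pytest.approx(sigma_a / (sigma_a + sigma_w))

    def test_null_split_mean_phi_near_zero(self):
        """Splitting one panmictic sample at random gives Phi_ST ~ 0 on
        average."""
        rng = np.random.default_rng(0)
        phis = []
        for _ in range(1000):
            haps = rng.integers(0, 4, size=16)
            hap_d = random_symmetric_distances(4, rng)
            mat = hap_d[np.ix_(haps, haps)]
            ind = DistanceMatrix([f"s{i}" for i in range(16)], mat)
            split = rng.permutation(16)
            pops = {f"s{i}": ("A" if np.where(split == i)[0][0] < 8 else "B")
                    for i in range(16)}
            phis.append(hd.amova(ind, pops).phi["phi_st"])
        assert abs(np.mean(phis)) < 0.02

    def test_two_population_amova_equals_pairwise_fst_entry(self, study,
                                                            study_distances):
        _, pops, _ = study
        _, ind = study_distances
        pop_of = dict(zip(pops["sequence_id"], pops["population"]))
        fst = hd.pairwise_fst(ind, pop_of)
        ids = [l for l in ind.labels if pop_of[l] in ("P1", "P4")]
        sub = ind.reorder(ids)
        res = hd.amova(sub, {l: pop_of[l] for l in ids})
        assert fst.loc["P1", "P4"] == pytest.approx(res.phi["phi_st"])

    def test_two_level_design_percentages_sum(self, study, study_distances):
        _, pops, truth = study
        _, ind = study_distances
        pop_of = dict(zip(pops["sequence_id"], pops["population"]))
        groups = {p: f"g{g}" for p, g in truth.partition.items()}
        res = hd.amova(ind, pop_of, groups=groups)
        assert res.table["percent"].iloc[:3].sum() == pytest.approx(100.0)
        assert res.table["df"].iloc[:3].sum() == 127
        assert res.phi["f_ct"] > 0.9

    def test_empty_population_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            hd.amova(dm, {"a": "A", "b": "A"})


class TestPairwiseFst:
    def test_identical_compositions_zero(self):
        mat = np.ones((8, 8)) - np.eye(8)
        ind = DistanceMatrix([f"s{i}" for i in range(8)], mat)
        # both populations have the same mix of two haplotypes
        pops = {f"s{i}": ("A" if i % 2 == 0 else "B") for i in range(8)}
        fst = hd.pairwise_fst(ind, pops)
        assert fst.loc["A", "B"] <= 0.0 + 1e-9

    def test_planted_divergence_order(self):
        """F_ST ordering reflects the planted divergence order.

        Populations share haplotypes with their neighbor in the divergence
        series but not with distant populations, so Phi_ST must increase
        with planted divergence.
        """
        hap_seqs = {"h0": "AAAAAA", "h1": "AAAAAT", "h2": "TTTTTT"}
        dm = hd.pairwise_distances(hap_seqs)
        # P0 and P1 are mixtures of the same two close haplotypes;
        # P2 is fixed for the distant one
        assign = (["h0"] * 3 + ["h1"] * 2) + (["h0"] * 1 + ["h1"] * 4) + ["h2"] * 5
        labels = [f"s{i}" for i in range(15)]
        idx = {h: i for i, h in enumerate(dm.labels)}
        mat = np.array([[dm.matrix[idx[assign[i]], idx[assign[j]]]
                         for j in range(15)] for i in range(15)])
        ind = DistanceMatrix(labels, mat)
        pops = {labels[i]: f"P{i // 5}" for i in range(15)}
        fst = hd.pairwise_fst(ind, pops)
        assert fst.loc["P0", "P2"] > fst.loc["P0", "P1"]
        assert fst.loc["P1", "P2"] > fst.loc["P0", "P1"]


class TestGstNst:
    def test_equal_distances_collapse_to_gst(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(1, 8, size=(4, 3)),
            index=[f"P{i}" for i in range(4)], columns=["h1", "h2", "h3"])
        table = make_haplotype_table(counts)
        d = 3.0 * (np.ones((3, 3)) - np.eye(3))
        res = hd.gst_nst_permut(table, DistanceMatrix(["h1", "h2", "h3"], d),
                                n_perm=10, seed=0)
        assert res.n_st == pytest.approx(res.g_st, abs=1e-12)

    def test_identical_compositions_gst_near_zero(self):
        """Identical haplotype compositions carry no differentiation; the
        unbiased estimators leave a small-sample remainder of order 1/n
        around zero (they treat the observed counts as one sampling draw)."""
        counts = pd.DataFrame(
            [[6, 2], [6, 2], [6, 2]],
            index=["P1", "P2", "P3"], columns=["h1", "h2"])
        table = make_haplotype_table(counts)
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = hd.gst_nst_permut(table, DistanceMatrix(["h1", "h2"], d),
                                n_perm=10, seed=0)
        assert abs(res.g_st) <= 1.0 / 8 + 1e-9
        # with larger samples the remainder shrinks
        big = make_haplotype_table(counts * 20)
        res_big = hd.gst_nst_permut(big, DistanceMatrix(["h1", "h2"], d),
                                    n_perm=10, seed=0)
        assert abs(res_big.g_st) < abs(res.g_st)

    def test_study_fixture_strong_structure(self, study_table,
                                            study_distances):
        hap, _ = study_distances
        res = hd.gst_nst_permut(study_table, hap, n_perm=199, seed=1)
        assert res.g_st > 0.8
        assert 0.0 <= res.g_st <= 1.0 and 0.0 <= res.n_st <= 1.0

    def test_monomorphic_rejected(self):
        counts = pd.DataFrame([[5], [5]], index=["A", "B"], columns=["h1"])
        with pytest.raises(ValueError):
            hd.gst_nst_permut(make_haplotype_table(counts),
                              DistanceMatrix(["h1"], np.zeros((1, 1))))


class TestSamova:
    def _planted_two_clusters(self):
        """Two spatial clusters fixed for haplotypes 5 steps apart."""
        rng = np.random.default_rng(3)
        coords, pops, labels = {}, {}, []
        mat_size = 24
        hap = []
        for p in range(8):
            cluster = 0 if p < 4 else 1
            coords[f"P{p}"] = (17.0 + cluster * 2.0 + 0.3 * (p % 4),
                               -97.0 + 0.25 * (p % 4))
            for i in range(3):
                lab = f"P{p}_{i}"
                labels.append(lab)
                pops[lab] = f"P{p}"
                hap.append(cluster)
        d = np.zeros((mat_size, mat_size))
        for i in range(mat_size):
            for j in range(mat_size):
                d[i, j] = 0.0 if hap[i] == hap[j] else 5.0
        return DistanceMatrix(labels, d), pops, coords

    def test_recovers_planted_partition(self):
        ind, pops, coords = self._planted_two_clusters()
        res = hd.samova(ind, pops, coords, K=2, n_starts=10, seed=4)
        groups = {}
        for p, g in res.partition.items():
            groups.setdefault(g, set()).add(p)
        assert sorted(map(sorted, groups.values())) == [
            ["P0", "P1", "P2", "P3"], ["P4", "P5", "P6", "P7"]]
        assert res.f_ct > 0.95

    def test_identical_populations_low_fct(self):
        """Populations with identical haplotype compositions leave no
        among-group variance to maximize."""
        rng = np.random.default_rng(5)
        labels = [f"P{p}_{i}" for p in range(6) for i in range(4)]
        hap = np.tile([0, 0, 1, 2], 6)  # every population: same composition
        base = random_symmetric_distances(3, rng)
        mat = base[np.ix_(hap, hap)]
        ind = DistanceMatrix(labels, mat)
        pops = {l: l.split("_")[0] for l in labels}
        coords = {f"P{p}": (17.0 + p * 0.5, -97.0 + (p % 2) * 0.5)
                  for p in range(6)}
        res = hd.samova(ind, pops, coords, K=2, n_starts=5, seed=6)
        assert abs(res.f_ct) < 0.05

    def test_partition_groups_are_contiguous(self, study, study_distances):
        from haplodyn.structure_stats import delaunay_adjacency
        from haplodyn.synthetic_data import STUDY_COORDS

        _, pops, _ = study
        _, ind = study_distances
        pop_of = dict(zip(pops["sequence_id"], pops["population"]))
        res = hd.samova(ind, pop_of, STUDY_COORDS, K=4, n_starts=5, seed=7)
        adj = delaunay_adjacency(STUDY_COORDS)
        for g in set(res.partition.values()):
            members = {p for p, gg in res.partition.items() if gg == g}
            # BFS within group
            start = next(iter(members))
            seen, stack = {start}, [start]
            while stack:
                x = stack.pop()
                for y in adj[x] & members:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            assert seen == members

    def test_k_out_of_range_rejected(self, study, study_distances):
        _, pops, _ = study
        _, ind = study_distances
        pop_of = dict(zip(pops["sequence_id"], pops["population"]))
        from haplodyn.synthetic_data import STUDY_COORDS
        with pytest.raises(ValueError, match="K must be"):
            hd.samova(ind, pop_of, STUDY_COORDS, K=8, n_starts=1, seed=0)

    def test_best_fct_monotone_in_restarts(self):
        ind, pops, coords = self._planted_two_clusters()
        f = [hd.samova(ind, pops, coords, K=2, n_starts=n, seed=11).f_ct
             for n in (1, 3, 6)]
        assert f[0] <= f[1] + 1e-12 <= f[2] + 2e-12


class TestMantel:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(2)
        d = random_symmetric_distances(6, rng)
        dm = DistanceMatrix([f"P{i}" for i in range(6)], d)
        res = hd.mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(8)
        a = random_symmetric_distances(7, rng)
        b = random_symmetric_distances(7, rng)
        labels = [f"P{i}" for i in range(7)]
        mine = hd.mantel(DistanceMatrix(labels, a), DistanceMatrix(labels, b),
                         n_perm=999, seed=1)
        r_ref, p_ref, _ = skbio_mantel(SkbioDM(a, labels), SkbioDM(b, labels),
                                       permutations=999, alternative="greater")
        assert mine.r == pytest.approx(float(r_ref), abs=1e-12)
        assert mine.p_value == pytest.approx(float(p_ref), abs=0.05)

    def test_planted_isolation_by_distance_detected(self):
        rng = np.random.default_rng(12)
        coords = {f"P{i}": (17.0 + rng.uniform(0, 3), -97.0 + rng.uniform(0, 3))
                  for i in range(10)}
        geo = hd.great_circle_matrix(coords)
        noise = random_symmetric_distances(10, rng) * 0.02
        gen = DistanceMatrix(geo.labels, 0.01 * geo.matrix + noise)
        res = hd.mantel(gen, geo, n_perm=999, seed=3)
        assert res.r > 0
        assert res.p_value < 0.05

    def test_constant_matrix_flagged(self):
        labels = ["a", "b", "c"]
        const = DistanceMatrix(labels, np.ones((3, 3)) - np.eye(3))
        var = DistanceMatrix(labels, np.array([[0., 1, 2], [1, 0, 3], [2, 3, 0.]]))
        res = hd.mantel(const, var, n_perm=9)
        assert res.flagged and np.isnan(res.r)


class TestGreatCircle:
    def test_identical_points_zero(self):
        dm = hd.great_circle_matrix({"a": (17.0, -97.0), "b": (17.0, -97.0)})
        assert dm.loc("a", "b") == 0.0

    def test_one_degree_latitude(self):
        dm = hd.great_circle_matrix({"a": (17.0, -97.0), "b": (18.0, -97.0)})
        assert dm.loc("a", "b") == pytest.approx(111.2, abs=0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hd.great_circle_matrix({"a": (95.0, 0.0), "b": (0.0, 0.0)})
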
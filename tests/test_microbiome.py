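import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

import neurogut as ng
from neurogut.microbiome import collapse_rank, relative_abundance


def make_table(counts_dict, lineages, manifest_rows):
    counts = pd.DataFrame(counts_dict, index=list(lineages.keys()), dtype=float)
    manifest = pd.DataFrame(manifest_rows).set_index("sample")
    return ng.TaxaTable(counts=counts, lineages=pd.Series(lineages), manifest=manifest)


@pytest.fixture
def paired_table():
    lineages = {
        f"t{i}": f"P{i % 2};C{i % 2};O{i % 2};F{i % 2};G{i};S{i}" for i in range(4)
    }
    rng = np.random.default_rng(0)
    counts = {}
    manifest = []
    for s in range(6):
        counts[f"S{s}_pre"] = rng.integers(10, 200, 4)
        counts[f"S{s}_post"] = rng.integers(10, 200, 4)
        manifest.append({"sample": f"S{s}_pre", "subject": f"S{s}", "condition": "pre"})
        manifest.append({"sample": f"S{s}_post", "subject": f"S{s}", "condition": "post"})
    return make_table(counts, lineages, manifest)


class TestAlphaDiversity:
    def test_single_taxon_sample(self):
        df = pd.DataFrame({"s": [500, 0, 0]}, index=["a", "b", "c"])
        a = ng.alpha_diversity(df)
        assert a.loc["s", "shannon"] == 0.0
        assert a.loc["s", "simpson"] == 0.0
        assert a.loc["s", "chao1"] == 1.0

    def test_two_even_taxa(self):
        df = pd.DataFrame({"s": [50, 50]}, index=["a", "b"])
        a = ng.alpha_diversity(df)
        assert a.loc["s", "simpson"] == pytest.approx(0.5)
        assert a.loc["s", "shannon"] == pytest.approx(np.log(2))

    def test_chao1_bias_corrected_hand_example(self):
        # 5 observed taxa, F1=2 singletons, F2=0 doubletons -> 5 + 2*1/2 = 6
        df = pd.DataFrame({"s": [10, 10, 10, 1, 1]}, index=list("abcde"))
        assert ng.alpha_diversity(df).loc["s", "chao1"] == pytest.approx(6.0)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"s": [5, -1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            ng.alpha_diversity(df)


class TestBetaDiversity:
    def test_identical_samples_zero(self):
        df = pd.DataFrame({"u": [1, 2, 3], "v": [1, 2, 3]}, index=list("abc"))
        assert ng.beta_diversity(df, "braycurtis")["u", "v"] == pytest.approx(0.0)
        assert ng.beta_diversity(df, "jaccard")["u", "v"] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        df = pd.DataFrame({"u": [1, 1, 0, 0], "v": [0, 0, 2, 5]}, index=list("abcd"))
        assert ng.beta_diversity(df, "braycurtis")["u", "v"] == pytest.approx(1.0)
        assert ng.beta_diversity(df, "jaccard")["u", "v"] == pytest.approx(1.0)

    def test_hand_computed_bray_curtis(self):
        # proportions (0.25, 0.75) vs (0.75, 0.25) -> BC = 0.5
        df = pd.DataFrame({"u": [1, 3], "v": [3, 1]}, index=["a", "b"])
        assert ng.beta_diversity(df, "braycurtis")["u", "v"] == pytest.approx(0.5)

    def test_distances_symmetric_zero_diagonal(self, paired_table):
        dm = ng.beta_diversity(paired_table, "braycurtis")
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert dm.data.max() <= 1.0


class TestPCoA:
    def test_euclidean_roundtrip(self):
        pts = np.array([[0, 0], [1, 0], [0, 2], [3, 1]], float)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = ng.pcoa(dm)
        emb = res.samples.to_numpy()
        assert np.allclose(squareform(pdist(emb)), dm.data, atol=1e-8)

    def test_equilateral_triangle_equal_eigenvalues(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), ids=list("abc"))
        res = ng.pcoa(dm)
        eig = np.sort(res.eigvals.to_numpy())[::-1]
        assert eig[0] == pytest.approx(eig[1])
        emb = res.samples.to_numpy()
        assert np.allclose(pdist(emb), 1.0, atol=1e-8)

    def test_duplicate_sample_coincident(self):
        D = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], float)
        res = ng.pcoa(DistanceMatrix(D, ids=list("abc")))
        emb = res.samples.to_numpy()
        assert np.allclose(emb[0], emb[1], atol=1e-8)


class TestKruskalWallis:
    def test_identical_groups_null(self):
        H, p = ng.kruskal_wallis([2.0, 2.0, 2.0], [2.0, 2.0])
        assert H == 0.0 and p == 1.0

    def test_separated_groups_hand_value(self):
        H, p = ng.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert H == pytest.approx(3.857142857, abs=1e-6)

    def test_tie_correction_formula(self):
        # groups with ties: H = (12/(N(N+1)) sum R_g^2/n_g - 3(N+1)) / (1 - sum(t^3-t)/(N^3-N))
        g1, g2 = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        from scipy.stats import rankdata

        allv = np.array(g1 + g2)
        ranks = rankdata(allv)
        N = len(allv)
        R1, R2 = ranks[:3].sum(), ranks[3:].sum()
        H_raw = 12 / (N * (N + 1)) * (R1**2 / 3 + R2**2 / 3) - 3 * (N + 1)
        _, t = np.unique(allv, return_counts=True)
        H_exp = H_raw / (1 - ((t**3 - t).sum()) / (N**3 - N))
        H, _ = ng.kruskal_wallis(g1, g2)
        assert H == pytest.approx(H_exp, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ng.kruskal_wallis([1.0, 2.0], [])


class TestPermanova:
    def test_separated_clusters_minimal_p(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (13, 2)), rng.normal(5, 0.05, (13, 2))])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i:02d}" for i in range(26)])
        _, p = ng.permanova(dm, ["a"] * 13 + ["b"] * 13, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_pseudo_f_matches_direct_partition(self):
        rng = np.random.default_rng(1)
        D = squareform(pdist(rng.standard_normal((6, 2))))
        lab = np.array(["a"] * 3 + ["b"] * 3)
        N, k = 6, 2
        sst = (D**2)[np.triu_indices(N, 1)].sum() / N
        ssw = sum(
            (D[np.ix_(np.where(lab == g)[0], np.where(lab == g)[0])] ** 2)[
                np.triu_indices(3, 1)].sum() / 3
            for g in "ab")
        f_expected = ((sst - ssw) / (k - 1)) / (ssw / (N - k))
        f, _ = ng.permanova(D, lab, n_perm=9, seed=0)
        assert f == pytest.approx(f_expected, rel=1e-12)

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((12, 3))
        pts[6:] += 0.5
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        f, _ = ng.permanova(dm, ["a"] * 6 + ["b"] * 6, n_perm=9, seed=0)
        sk = skbio_permanova(dm, list(["a"] * 6 + ["b"] * 6), permutations=9)
        assert f == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_seed_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(3)
        D = squareform(pdist(rng.standard_normal((10, 2))))
        ids = [f"s{i}" for i in range(10)]
        lab = np.array(["a"] * 5 + ["b"] * 5)
        dm = DistanceMatrix(D, ids=ids)
        r1 = ng.permanova(dm, lab, n_perm=99, seed=11)
        r2 = ng.permanova(dm, lab, n_perm=99, seed=11)
        assert r1 == r2
        perm = rng.permutation(10)
        dm2 = DistanceMatrix(D[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
        r3 = ng.permanova(dm2, lab[perm], n_perm=99, seed=11)
        assert r3 == r1

    def test_small_group_rejected(self):
        D = squareform(pdist(np.random.default_rng(0).standard_normal((4, 2))))
        with pytest.raises(ValueError, match="fewer than 2"):
            ng.permanova(D, ["a", "a", "a", "b"], n_perm=9)


class TestTaxonShifts:
    def test_percent_change_convention(self, paired_table):
        shifts = ng.taxon_shifts(paired_table, "species")
        rel = relative_abundance(collapse_rank(paired_table, "species"))
        pre_cols = [c for c in rel.columns if c.endswith("_pre")]
        post_cols = [c for c in rel.columns if c.endswith("_post")]
        for _, row in shifts.iterrows():
            mp = rel.loc[row["taxon"], pre_cols].mean()
            mq = rel.loc[row["taxon"], post_cols].mean()
            assert row["pct_change"] == pytest.approx(100 * (mq - mp) / mp)

    def test_248_percent_arithmetic(self):
        # mean relative abundance 0.01 -> 0.0348 is the +248% convention
        lineages = {"t0": "P;C;O;F;G;S", "t1": "P;C;O;F;G;S2"}
        counts = {}
        manifest = []
        for s in range(5):
            counts[f"S{s}_pre"] = [100, 9900]
            counts[f"S{s}_post"] = [348, 9652]
            manifest.append({"sample": f"S{s}_pre", "subject": f"S{s}", "condition": "pre"})
            manifest.append({"sample": f"S{s}_post", "subject": f"S{s}", "condition": "post"})
        table = make_table(counts, lineages, manifest)
        shifts = ng.taxon_shifts(table, "species")
        assert shifts.loc[shifts.taxon == "P;C;O;F;G;S", "pct_change"].iloc[0] == pytest.approx(248.0)

    def test_emergent_taxon_flagged(self):
        lineages = {"t0": "P;C;O;F;G;S", "t1": "P;C;O;F;G;S2"}
        counts = {}
        manifest = []
        for s in range(5):
            counts[f"S{s}_pre"] = [0, 100]
            counts[f"S{s}_post"] = [10, 90]
            manifest.append({"sample": f"S{s}_pre", "subject": f"S{s}", "condition": "pre"})
            manifest.append({"sample": f"S{s}_post", "subject": f"S{s}", "condition": "post"})
        shifts = ng.taxon_shifts(make_table(counts, lineages, manifest), "species")
        row = shifts[shifts.taxon == "P;C;O;F;G;S"].iloc[0]
        assert bool(row["emergent"]) and np.isnan(row["pct_change"])

    def test_halving_fold_recovered(self):
        base = np.concatenate([[0.02], np.full(20, 0.98 / 20)])
        fc = np.ones(21)
        fc[0] = 0.51
        spec = ng.MicrobiomeSimSpec(n_subjects=13, n_taxa=21, depth=100_000,
                                    base_proportions=base / base.sum(), fold_changes=fc,
                                    overdispersion=5000.0, seed=1)
        table = ng.simulate_taxa_tables(spec)
        shifts = ng.taxon_shifts(table, "genus")
        genus = ";".join(table.lineages.iloc[0].split(";")[:5])
        got = float(shifts.loc[shifts.taxon == genus, "pct_change"].iloc[0])
        assert got == pytest.approx(-49.0, abs=6.0)

    def test_rank_collapse_conserves_depth(self, paired_table):
        for rank in ("phylum", "genus", "species"):
            collapsed = collapse_rank(paired_table, rank)
            assert np.allclose(collapsed.sum(axis=0), paired_table.counts.sum(axis=0))

    def test_unknown_rank_rejected(self, paired_table):
        with pytest.raises(ValueError, match="rank"):
            ng.taxon_shifts(paired_table, "kingdom")


class TestTaxaTableIO:
    def test_tsv_roundtrip(self, paired_table, tmp_path):
        from neurogut.microbiome import read_taxa_table, write_taxa_table

        write_taxa_table(paired_table, tmp_path / "counts.tsv", tmp_path / "manifest.tsv")
        back = read_taxa_table(tmp_path / "counts.tsv", tmp_path / "manifest.tsv")
        assert np.allclose(back.counts.to_numpy(), paired_table.counts.to_numpy())
        assert list(back.lineages) == list(paired_table.lineages)
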
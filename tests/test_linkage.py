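"""Nearest-gene, windowed correlation, net change, bins and overlap tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erna_scout.differential import LABEL_A, LABEL_B, LABEL_NONE
from erna_scout.intervals import GenomeAnnotation, Gene, Interval, RegionSet
from erna_scout.linkage import (
    bin_expression_shift,
    nearest_gene,
    net_enhancer_change,
    overlap_test,
    stratify_by_gene,
    windowed_best_correlation,
)


def _ann(genes, chrom_len=1_000_000):
    chroms = {g[1] for g in genes}
    return GenomeAnnotation(
        [Gene(*g) for g in genes], {c: chrom_len for c in chroms}
    )


def _regions(*spans, chrom="c"):
    return RegionSet(
        [Interval(chrom, s, e, name=f"r{i}") for i, (s, e) in enumerate(spans)],
        sorted=True,
        merged=True,
    )


class TestNearestGene:
    def test_signed_distance(self):
        ann = _ann([("a", "c", 4000, 4500, "+"), ("b", "c", 9000, 9500, "+")])
        res = nearest_gene(_regions((4900, 5100)), ann)  # centre 5000
        assert res.loc[0, "nearest_gene_id"] == "a"
        assert res.loc[0, "distance"] == -1000

    def test_tie_breaks_lexicographically(self):
        ann = _ann([("B", "c", 3000, 3500, "+"), ("A", "c", 7000, 7500, "+")])
        res = nearest_gene(_regions((4900, 5100)), ann)  # equidistant +/-2000
        assert res.loc[0, "nearest_gene_id"] == "A"

    def test_chromosome_without_genes_gets_na(self):
        ann = _ann([("a", "c", 0, 100, "+")])
        rs = RegionSet([Interval("other", 10, 20, name="r0")], sorted=True, merged=True)
        res = nearest_gene(rs, ann)
        assert res.loc[0, "nearest_gene_id"] is None

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(50):
            s = int(rng.integers(0, 900_000))
            genes.append((f"g{i:02d}", "c", s, s + 500, "+" if rng.random() < 0.5 else "-"))
        ann = _ann(genes)
        spans = sorted({(int(s), int(s) + 200) for s in rng.integers(0, 900_000, 30)})
        spans = [sp for i, sp in enumerate(spans) if i == 0 or sp[0] >= spans[i - 1][1]]
        res = nearest_gene(_regions(*spans), ann)
        tss = {g.gene_id: g.tss for g in ann.genes}
        for (_, row), iv in zip(res.iterrows(), _regions(*spans)):
            centre = iv.centre
            best = min(tss, key=lambda g: (abs(tss[g] - centre), g))
            assert row["nearest_gene_id"] == best


class TestWindowedCorrelation:
    def _setup(self, n_samples=10, seed=0):
        rng = np.random.default_rng(seed)
        ann = _ann([("g1", "c", 4000, 4500, "+"), ("g2", "c", 40_000, 40_500, "+"),
                    ("far", "c", 900_000, 900_500, "+")])
        regions = _regions((9_900, 10_100))
        cols = [f"s{i}" for i in range(n_samples)]
        e = rng.normal(size=n_samples)
        erna = pd.DataFrame([e], index=["r0"], columns=cols)
        return ann, regions, erna, cols, e, rng

    def test_monotone_transform_gives_rho_one(self):
        ann, regions, erna, cols, e, rng = self._setup()
        gene = pd.DataFrame(
            [np.exp(e), rng.normal(size=len(cols))], index=["g1", "g2"], columns=cols
        )
        link, rho = windowed_best_correlation(erna, gene, ann, regions)
        assert link.loc[0, "best_corr_gene_id"] == "g1"
        assert link.loc[0, "rho"] == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        ann, regions, erna, cols, e, _ = self._setup()
        gene = pd.DataFrame([-e], index=["g1"], columns=cols)
        _, rho = windowed_best_correlation(erna, gene, ann, regions)
        assert rho["rho"].iloc[0] == pytest.approx(-1.0)

    def test_window_excludes_distant_genes(self):
        ann, regions, erna, cols, e, _ = self._setup()
        gene = pd.DataFrame([e, e], index=["g1", "far"], columns=cols)
        _, rho = windowed_best_correlation(erna, gene, ann, regions, half_window=100_000)
        assert set(rho["gene_id"]) == {"g1"}

    def test_requires_three_shared_samples(self):
        ann, regions, erna, cols, e, _ = self._setup(n_samples=2)
        gene = pd.DataFrame([e], index=["g1"], columns=cols)
        with pytest.raises(ValueError):
            windowed_best_correlation(erna, gene, ann, regions)

    def test_matches_scipy_spearman(self):
        ann, regions, erna, cols, e, rng = self._setup(n_samples=5, seed=3)
        g = rng.normal(size=(2, 5))
        g[0, 0] = g[0, 1]  # force a tie to exercise average ranks
        gene = pd.DataFrame(g, index=["g1", "g2"], columns=cols)
        _, rho = windowed_best_correlation(erna, gene, ann, regions)
        for _, row in rho.iterrows():
            expected = stats.spearmanr(e, gene.loc[row["gene_id"]]).statistic
            assert row["rho"] == pytest.approx(expected, abs=1e-12)


class TestNetChange:
    def test_gained_minus_lost(self):
        ann = _ann([("g", "c", 100_000, 101_000, "+")])
        rs = _regions((50_000, 50_400), (150_000, 150_400), (260_000, 260_400),
                      (600_000, 600_400))
        labels = {"r0": LABEL_B, "r1": LABEL_B, "r2": LABEL_A, "r3": LABEL_A}
        nct = net_enhancer_change(ann, rs, labels)
        # r0, r1 gained within 200 kb; r2 lost at 160 kb; r3 outside window
        assert nct.loc[0, ["gained", "lost", "net_change", "bin"]].tolist() == [2, 1, 1, 1]

    def test_clamped_to_four(self):
        ann = _ann([("g", "c", 100_000, 101_000, "+")])
        spans = [(90_000 + i * 2000, 90_000 + i * 2000 + 400) for i in range(6)]
        rs = _regions(*spans)
        labels = {f"r{i}": LABEL_B for i in range(6)}
        nct = net_enhancer_change(ann, rs, labels)
        assert nct.loc[0, "net_change"] == 6 and nct.loc[0, "bin"] == 4

    def test_unclassified_regions_ignored(self):
        ann = _ann([("g", "c", 100_000, 101_000, "+")])
        rs = _regions((90_000, 90_400))
        nct = net_enhancer_change(ann, rs, {"r0": LABEL_NONE})
        assert nct.loc[0, "net_change"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_distance_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = [(f"g{i:02d}", "c", int(s), int(s) + 800, "+")
                 for i, s in enumerate(sorted(rng.integers(0, 900_000, 40)))]
        ann = _ann(genes)
        spans = sorted({(int(s), int(s) + 300) for s in rng.integers(0, 900_000, 60)})
        spans = [sp for i, sp in enumerate(spans) if i == 0 or sp[0] >= spans[i - 1][1]]
        rs = _regions(*spans)
        lab_choices = [LABEL_A, LABEL_B, LABEL_NONE]
        labels = {f"r{i}": lab_choices[int(rng.integers(3))] for i in range(len(spans))}
        nct = net_enhancer_change(ann, rs, labels).set_index("gene_id")
        for g in ann.genes:
            exp = 0
            for iv in rs:
                if abs(g.tss - iv.centre) <= 200_000:
                    lab = labels[iv.name]
                    exp += 1 if lab == LABEL_B else (-1 if lab == LABEL_A else 0)
            assert nct.loc[g.gene_id, "net_change"] == exp


class TestBinShift:
    def test_identical_values_degenerate(self):
        nct = pd.DataFrame({"bin": [0, 0, 1, 1], "log2FC": [2.0] * 4})
        _, h, p = bin_expression_shift(nct)
        assert h == 0.0 and p == 1.0

    def test_two_group_hand_value(self):
        nct = pd.DataFrame({"bin": [0] * 3 + [1] * 3, "log2FC": [1, 2, 3, 4, 5, 6]})
        _, h, p = bin_expression_shift(nct)
        assert h == pytest.approx(3.857142857, abs=1e-6)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            bin_expression_shift(pd.DataFrame({"bin": [1, 1], "log2FC": [0.5, 1.0]}))

    def test_matches_scipy_kruskal(self, rng):
        nct = pd.DataFrame(
            {"bin": rng.integers(-2, 3, 100), "log2FC": rng.normal(size=100)}
        )
        _, h, p = bin_expression_shift(nct)
        groups = [g["log2FC"].to_numpy() for _, g in nct.groupby("bin")]
        exp_h, exp_p = stats.kruskal(*groups)
        assert h == pytest.approx(exp_h) and p == pytest.approx(exp_p)


class TestOverlap:
    def test_exact_enumeration_value(self):
        res = overlap_test(set("abcde"), set("abcde"), set("abcdefghij"))
        assert res.p_hypergeom == pytest.approx(1 / 252)

    def test_zero_overlap_p_one(self):
        res = overlap_test({"a"}, {"b"}, {"a", "b", "c"})
        assert res.p_hypergeom == pytest.approx(1.0)

    def test_full_universe_forced_overlap(self):
        u = set("abcd")
        res = overlap_test(u, u, u)
        assert res.overlap == 4 and res.p_hypergeom == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            overlap_test({"x"}, {"a"}, {"a", "b"})

    def test_fisher_vs_one_sided_bound(self, rng):
        u = set(range(60))
        for _ in range(10):
            a = set(rng.choice(60, size=15, replace=False).tolist())
            b = set(rng.choice(60, size=20, replace=False).tolist())
            res = overlap_test(a, b, u)
            table = [[res.overlap, res.n_a - res.overlap],
                     [res.n_b - res.overlap, res.universe - res.n_a - res.n_b + res.overlap]]
            one_sided = min(
                stats.fisher_exact(table, "greater")[1],
                stats.fisher_exact(table, "less")[1],
            )
            assert res.p_fisher >= one_sided - 1e-12


class TestStratify:
    def test_median_plus_two_sd_rule(self):
        x = pd.Series([1.0] * 9 + [100.0], index=[f"s{i}" for i in range(10)], name="ERBB2")
        high = stratify_by_gene(x)
        # median 1, population SD ~29.7: only the amplified sample exceeds it
        assert high.sum() == 1 and bool(high.iloc[-1])

    def test_constant_expression_nobody_high(self):
        x = pd.Series([5.0] * 6)
        assert stratify_by_gene(x).sum() == 0


def test_linkage_recovers_planted_targets_in_isolated_model(rng):
    """Module-level coupled model: target = baseline + gamma*eRNA + noise,
    all other genes pure noise; recovery must be near-perfect at SNR 2."""
    n, n_genes = 40, 30
    genes = [(f"g{i:02d}", "c", 10_000 + i * 30_000, 10_500 + i * 30_000, "+")
             for i in range(n_genes)]
    ann = _ann(genes)
    spans = [(12_000 + i * 30_000, 12_400 + i * 30_000) for i in range(0, n_genes, 3)]
    rs = _regions(*spans)
    cols = [f"s{i}" for i in range(n)]
    erna = pd.DataFrame(rng.normal(size=(len(spans), n)),
                        index=[f"r{i}" for i in range(len(spans))], columns=cols)
    gene_expr = pd.DataFrame(2.5 * rng.normal(size=(n_genes, n)),
                             index=[g[0] for g in genes], columns=cols)
    for i in range(len(spans)):
        target = f"g{3 * i:02d}"
        gene_expr.loc[target] = 2.0 * erna.iloc[i] + rng.normal(size=n)
    link, _ = windowed_best_correlation(erna, gene_expr, ann, rs)
    hits = sum(link.loc[i, "best_corr_gene_id"] == f"g{3 * i:02d}" for i in range(len(spans)))
    assert hits / len(spans) >= 0.9
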
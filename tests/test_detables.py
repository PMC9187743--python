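"""Differential-table operations: sets, ratios, correlations, overlaps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ribolens.detables import (
    DifferentialTable,
    consistent_direction_genes,
    correlate_contrasts,
    overlap_test,
    read_de_table,
    significant_set,
    trap_over_total,
)
from tests.conftest import make_de


class TestReadDeTable:
    def _write(self, tmp_path, df, name="de.tsv"):
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_well_formed(self, tmp_path):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(5)],
                "log2fc": np.linspace(-1, 1, 5),
                "stat": np.zeros(5),
                "pvalue": np.full(5, 0.5),
                "padj": np.full(5, 0.8),
            }
        )
        table = read_de_table(self._write(tmp_path, df))
        assert len(table.df) == 5

    def test_padj_optional(self, tmp_path):
        df = pd.DataFrame({"gene_id": ["a"], "log2fc": [1.0], "pvalue": [0.1]})
        table = read_de_table(self._write(tmp_path, df))
        assert "padj" not in table.df.columns

    def test_missing_required_column_named(self, tmp_path):
        df = pd.DataFrame({"gene_id": ["a"], "pvalue": [0.1]})
        with pytest.raises(ValueError, match="log2fc"):
            read_de_table(self._write(tmp_path, df))

    def test_duplicate_gene_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"gene_id": ["a", "a"], "log2fc": [1.0, 2.0], "pvalue": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="a"):
            read_de_table(self._write(tmp_path, df))

    def test_unparseable_rows_dropped(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("gene_id\tlog2fc\tpvalue\na\t1.0\t0.5\nb\tnot_a_number\t0.5\n")
        table = read_de_table(path)
        assert list(table.df["gene_id"]) == ["a"]


class TestTrapOverTotal:
    def test_elementwise_ratio_and_zero_guard(self):
        idx = pd.Index(["g1", "g2"], name="gene_id")
        trap = pd.DataFrame({"trap_1": [10, 4]}, index=idx)
        total = pd.DataFrame({"total_1": [5, 0]}, index=idx)
        ratio = trap_over_total(trap, total, [("trap_1", "total_1")])
        assert ratio.loc["g1", "trap_1/total_1"] == 2.0
        assert math.isnan(ratio.loc["g2", "trap_1/total_1"])

    def test_matches_division_oracle(self, rng):
        idx = pd.Index([f"g{i}" for i in range(20)])
        trap = pd.DataFrame({f"trap_{j}": rng.integers(0, 100, 20) for j in range(3)}, index=idx)
        total = pd.DataFrame({f"total_{j}": rng.integers(0, 100, 20) for j in range(3)}, index=idx)
        pairs = [(f"trap_{j}", f"total_{j}") for j in range(3)]
        ratio = trap_over_total(trap, total, pairs)
        for t_col, n_col in pairs:
            expected = trap[t_col] / total[n_col].replace(0, np.nan)
            pd.testing.assert_series_equal(
                ratio[f"{t_col}/{n_col}"], expected, check_names=False
            )

    def test_unmatched_sample_errors(self):
        trap = pd.DataFrame({"trap_1": [1]})
        total = pd.DataFrame({"total_1": [1]})
        with pytest.raises(ValueError, match="unmatched"):
            trap_over_total(trap, total, [("trap_1", "total_9")])


class TestSignificantSet:
    def test_strict_boundary(self):
        t = make_de(list("abc"), [1, 1, 1], padj=[0.05, 0.1, 0.2])
        assert significant_set(t, alpha_adj=0.1) == {"a"}

    def test_direction_filters_sign(self):
        t = make_de(list("ab"), [1.0, -1.0], padj=[0.01, 0.01])
        assert significant_set(t, direction="up") == {"a"}
        assert significant_set(t, direction="down") == {"b"}

    def test_missing_padj_nonsignificant_and_monotone_alpha(self, rng):
        genes = [f"g{i}" for i in range(100)]
        padj = rng.uniform(0, 1, 100)
        padj[::10] = np.nan
        t = make_de(genes, rng.normal(size=100), padj=padj)
        brute = {g for g, p in zip(genes, padj) if not np.isnan(p) and p < 0.3}
        assert significant_set(t, alpha_adj=0.3) == brute
        assert significant_set(t, 0.05) <= significant_set(t, 0.2)


class TestConsistentDirection:
    def test_sign_patterns(self):
        tables = [
            make_de(list("abc"), signs)
            for signs in ([1, 1, -1], [2, 1, -1], [0.5, -1, -2])
        ]
        up, down = consistent_direction_genes(tables)
        assert up == {"a"}
        assert down == {"c"}
        assert up.isdisjoint(down)

    def test_missing_gene_excluded(self):
        t1 = make_de(list("ab"), [1, 1])
        t2 = make_de(list("a"), [1])
        up, down = consistent_direction_genes([t1, t2])
        assert up == {"a"} and down == set()

    def test_matches_all_reduction_oracle(self, rng):
        genes = [f"g{i}" for i in range(40)]
        mats = rng.choice([-1.0, 1.0], size=(6, 40)) * rng.uniform(0.1, 2, (6, 40))
        tables = [make_de(genes, row, name=f"t{i}") for i, row in enumerate(mats)]
        up, down = consistent_direction_genes(tables)
        assert up == {g for j, g in enumerate(genes) if (mats[:, j] > 0).all()}
        assert down == {g for j, g in enumerate(genes) if (mats[:, j] < 0).all()}


class TestCorrelateContrasts:
    def test_identity_and_negation(self):
        genes = [f"g{i}" for i in range(10)]
        vals = np.linspace(-2, 2, 10)
        a = make_de(genes, vals, name="a")
        assert correlate_contrasts(a, make_de(genes, vals, name="b"))[0] == pytest.approx(1.0)
        assert correlate_contrasts(a, make_de(genes, -vals, name="c"))[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula_and_affine_invariance(self, rng):
        genes = [f"g{i}" for i in range(50)]
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(scale=0.5, size=50)
        r, p = correlate_contrasts(make_de(genes, x, name="a"), make_de(genes, y, name="b"))
        xc, yc = x - x.mean(), y - y.mean()
        r_manual = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(r_manual, rel=1e-12)
        r2, _ = correlate_contrasts(
            make_de(genes, 3.0 * x + 7, name="a"), make_de(genes, -2.0 * y + 1, name="b")
        )
        assert r2 == pytest.approx(-r, rel=1e-12)

    def test_zero_variance_warns_missing(self):
        genes = list("abcd")
        a = make_de(genes, [1, 1, 1, 1], name="a")
        b = make_de(genes, [1, 2, 3, 4], name="b")
        with pytest.warns(UserWarning):
            r, p = correlate_contrasts(a, b)
        assert math.isnan(r)


class TestOverlapTest:
    def test_full_and_disjoint(self):
        u = {f"g{i}" for i in range(10)}
        k, p = overlap_test(u, u, 10)
        assert k == 10 and p == pytest.approx(1.0)
        k, p = overlap_test({"g0"}, {"g1"}, 10)
        assert k == 0 and p == pytest.approx(1.0)

    def test_matches_combinatorial_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        set_a = set(universe[:6])
        set_b = {"g0", "g1", "g2", "g3", "g10"}
        k, p = overlap_test(set_a, set_b, 20)
        assert k == 4
        count = sum(
            1
            for draw in itertools.combinations(universe, len(set_b))
            if len(set_a & set(draw)) >= k
        )
        assert p == pytest.approx(count / math.comb(20, len(set_b)), rel=1e-12)

    def test_monotone_in_overlap(self):
        # larger observed overlap at fixed margins -> smaller upper-tail p
        universe = [f"g{i}" for i in range(50)]
        set_a = set(universe[:10])
        ps = []
        for k in range(0, 11):
            set_b = set(universe[:k]) | set(universe[10 : 10 + 12 - k])
            overlap, p = overlap_test(set_a, set_b, 50)
            assert overlap == k
            ps.append(p)
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_set_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_test({f"g{i}" for i in range(30)}, {"g0"}, 20)
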
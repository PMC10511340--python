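import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microstab as ms
from tests.conftest import make_meta


def table_from(rows, samples, taxa):
    return ms.AbundanceTable(
        pd.DataFrame(rows, index=samples, columns=taxa, dtype=float), kind="counts"
    )


class TestDepthFilter:
    def test_boundary_at_min_reads(self):
        t = table_from([[2999, 0], [3000, 0], [5000, 0]], ["a", "b", "c"], ["g1", "g2"])
        meta = make_meta([("a", "s1", 0), ("b", "s2", 0), ("c", "s2", 7)])
        out, rep = ms.filter_samples_by_depth(t, meta, min_reads=3000)
        assert out.sample_ids == ["b", "c"]
        assert rep.removed_samples["below_depth"] == ["a"]

    def test_orphaned_subject_removed_entirely(self):
        # one sample fails depth; the survivor is then alone and dropped too
        t = table_from([[5000, 0], [100, 0]], ["a", "b"], ["g1", "g2"])
        meta = make_meta([("a", "s1", 0), ("b", "s1", 7)])
        out, rep = ms.filter_samples_by_depth(t, meta, min_reads=3000)
        assert out.n_samples == 0
        assert rep.removed_samples["below_depth"] == ["b"]
        assert rep.removed_samples["orphaned_subject"] == ["a"]

    def test_identity_when_all_deep(self):
        t = table_from([[5000, 0], [4000, 0]], ["a", "b"], ["g1", "g2"])
        meta = make_meta([("a", "s1", 0), ("b", "s1", 7)])
        out, _ = ms.filter_samples_by_depth(t, meta, min_reads=3000)
        assert out.sample_ids == ["a", "b"]

    def test_relative_input_rejected(self, counts_table):
        with pytest.raises(ValueError, match="needs counts"):
            ms.filter_samples_by_depth(counts_table.to_relative(), None)

    def test_idempotent(self):
        t = table_from(
            [[5000, 0], [100, 0], [4000, 1], [4500, 2]],
            ["a", "b", "c", "d"],
            ["g1", "g2"],
        )
        meta = make_meta(
            [("a", "s1", 0), ("b", "s1", 7), ("c", "s2", 0), ("d", "s2", 3)]
        )
        once, _ = ms.filter_samples_by_depth(t, meta, min_reads=3000)
        twice, _ = ms.filter_samples_by_depth(once, meta, min_reads=3000)
        assert once.sample_ids == twice.sample_ids


class TestCrossStudyFilter:
    def _toy(self):
        # 3 studies x 2 subjects x 3 days; g1 at 5% everywhere; g2 at 5%
        # only on non-adjacent days (days 0 and 14, zero on day 7)
        rows, meta_rows = [], []
        i = 0
        for study in ("stA", "stB", "stC"):
            for subj in range(2):
                for day in (0, 7, 14):
                    g2 = 50 if day != 7 else 0
                    rows.append([50, g2, 1000 - 50 - g2])
                    meta_rows.append(
                        (f"x{i}", f"{study}_s{subj}", day, study)
                    )
                    i += 1
        t = table_from(rows, [m[0] for m in meta_rows], ["g1", "g2", "g3"])
        return t, make_meta(meta_rows)

    def test_consecutive_support_rule(self):
        t, meta = self._toy()
        out, rep = ms.filter_taxa_cross_study(
            t, meta, min_studies=2, min_subjects=1, abund_thr=0.01
        )
        assert "g1" in out.taxon_names
        assert "g2" not in out.taxon_names
        assert "g2" in rep.removed_taxa["insufficient_subject_support"]

    def test_vacuous_thresholds_identity(self):
        t, meta = self._toy()
        out, _ = ms.filter_taxa_cross_study(t, meta, min_studies=0, min_subjects=0)
        assert out.taxon_names == t.taxon_names

    def test_study_count_rule_overrides_abundance(self):
        t, meta = self._toy()
        # zero out g1 in study C entirely -> seen in 2 studies only
        data = t.data.copy()
        in_c = meta.loc[meta["study_id"] == "stC", "sample_id"]
        data.loc[in_c, "g1"] = 0
        t2 = ms.AbundanceTable(data, kind="counts")
        out, _ = ms.filter_taxa_cross_study(t2, meta, min_studies=3, min_subjects=1)
        assert "g1" not in out.taxon_names

    def test_idempotent(self):
        t, meta = self._toy()
        once, _ = ms.filter_taxa_cross_study(t, meta, min_studies=2, min_subjects=1)
        twice, _ = ms.filter_taxa_cross_study(once, meta, min_studies=2, min_subjects=1)
        assert once.taxon_names == twice.taxon_names


class TestEnterotypeFilter:
    def _table(self, n_samples=100, n_taxa=15, support_high=30):
        rng = np.random.default_rng(0)
        # taxa 0..4 abundant in many subjects; rest rare
        rows, meta_rows = [], []
        n_subj = n_samples // 2
        i = 0
        for s in range(n_subj):
            for day in (0, 7):
                row = np.full(n_taxa, 5.0)
                row[:5] = 300.0  # well above 1%
                rows.append(row)
                meta_rows.append((f"x{i}", f"s{s}", day))
                i += 1
        t = table_from(rows, [m[0] for m in meta_rows], [f"g{j:02d}" for j in range(n_taxa)])
        return t, make_meta(meta_rows)

    def test_sqrt_cap_on_taxon_count(self):
        t, meta = self._table()
        out, _ = ms.filter_taxa_enterotype(t, meta, min_subject_support=0)
        assert out.n_taxa <= int(np.ceil(np.sqrt(t.n_samples)))

    def test_min_subject_support_prunes_top_ranked(self):
        t, meta = self._table()
        out, rep = ms.filter_taxa_enterotype(t, meta, min_subject_support=25)
        # all kept taxa are supported by all 50 subjects; rare taxa by none
        assert set(out.taxon_names) <= {f"g{j:02d}" for j in range(5)}

    def test_mixed_enterotypes_rejected(self):
        t, _ = self._table()
        meta_rows = [(s, f"s{i//2}", (i % 2) * 7, "st1", "none", "Rum" if i < 50 else "Prev")
                     for i, s in enumerate(t.sample_ids)]
        meta = make_meta(meta_rows)
        with pytest.raises(ValueError, match="mixed enterotypes"):
            ms.filter_taxa_enterotype(t, meta)

    def test_tie_break_is_deterministic(self):
        # two taxa with identical support; higher mean abundance wins
        rows, meta_rows = [], []
        i = 0
        for s in range(4):
            for day in (0, 7):
                rows.append([400, 200, 10, 10])
                meta_rows.append((f"x{i}", f"s{s}", day))
                i += 1
        t = table_from(rows, [m[0] for m in meta_rows], ["hi", "lo", "r1", "r2"])
        meta = make_meta(meta_rows)
        out, _ = ms.filter_taxa_enterotype(t, meta, min_subject_support=0)
        k = int(np.ceil(np.sqrt(8)))  # 3 slots for 4 taxa
        assert out.n_taxa == k
        assert "hi" in out.taxon_names and "lo" in out.taxon_names
        # rank ties among r1/r2 resolved lexicographically
        assert out.taxon_names == ["hi", "lo", "r1"]


class TestRarefy:
    def test_full_depth_is_identity(self, counts_table):
        depth = int(counts_table.data.sum(axis=1).min())
        sub = counts_table.select(samples=[counts_table.sample_ids[0]])
        full = int(sub.data.sum(axis=1).iloc[0])
        out = ms.rarefy(sub, full, seed=0)
        assert np.array_equal(out.values, sub.values)

    def test_zero_taxa_stay_zero(self):
        t = table_from([[10, 0]], ["a"], ["g1", "g2"])
        out = ms.rarefy(t, 5, seed=1)
        assert out.values[0, 1] == 0
        assert out.values[0, 0] == 5

    def test_depth_above_total_names_sample(self):
        t = table_from([[10, 0]], ["a"], ["g1", "g2"])
        with pytest.raises(ValueError, match="'a'"):
            ms.rarefy(t, 100, seed=1)

    def test_deterministic_given_seed(self, counts_table):
        a = ms.rarefy(counts_table, 3000, seed=42)
        b = ms.rarefy(counts_table, 3000, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_hypergeometric_mean(self):
        # 1000 replicate rows of [500, 500] rarefied to 100:
        # E = 50, Var = 100*.25*(900/999) = 22.5 -> SE of mean 0.15
        t = table_from([[500, 500]] * 1000, [f"r{i}" for i in range(1000)], ["g1", "g2"])
        out = ms.rarefy(t, 100, seed=7)
        mean = out.values[:, 0].mean()
        assert abs(mean - 50.0) < 3 * np.sqrt(22.5 / 1000)
        assert np.all(out.values.sum(axis=1) == 100)


class TestShannonAndTransforms:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([10, 10, 10], np.log(3)),
            ([5, 5, 10], 1.0397207708399179),
            ([42, 0, 0], 0.0),
        ],
    )
    def test_shannon_values(self, row, expected):
        assert ms.shannon_alpha(row) == pytest.approx(expected, abs=1e-10)

    def test_shannon_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ms.shannon_alpha([0, 0])

    @given(
        st.lists(st.floats(min_value=0, max_value=1e4), min_size=2, max_size=10).filter(
            lambda r: sum(r) > 1e-6
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_clr_sums_to_zero(self, row):
        clr = ms.close_and_transform(row, "clr")
        assert abs(clr.sum()) < 1e-8

    def test_relative_closure(self):
        assert np.allclose(ms.close_and_transform([2, 2], "relative"), [0.5, 0.5])

    def test_clr_scale_invariance(self):
        a = ms.close_and_transform([1, 3], "clr")
        b = ms.close_and_transform([2, 6], "clr")
        assert np.allclose(a, b)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ms.close_and_transform([-1, 2], "relative")
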
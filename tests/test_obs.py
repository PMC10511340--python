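import io as _io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microstab as ms

simplex_pair = st.tuples(
    st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=4, max_size=4),
    st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=4, max_size=4),
).filter(lambda xy: sum(xy[0]) > 1e-6 and sum(xy[1]) > 1e-6)


def closed(v):
    v = np.asarray(v, dtype=float)
    return v / v.sum()


class TestBetaDiversity:
    @pytest.mark.parametrize("metric", ["bc", "jaccard", "euclog", "aitchison"])
    def test_identity_is_zero(self, metric):
        x = np.array([0.5, 0.3, 0.2, 0.0])
        assert ms.beta_diversity(x, x, metric) == pytest.approx(0.0, abs=1e-12)

    def test_identity_correlation_is_one(self):
        x = np.array([0.5, 0.3, 0.2])
        assert ms.beta_diversity(x, x, "cor") == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", ["bc", "jaccard", "euclog", "aitchison"])
    @given(xy=simplex_pair)
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, metric, xy):
        x, y = closed(xy[0]), closed(xy[1])
        assert ms.beta_diversity(x, y, metric) == pytest.approx(
            ms.beta_diversity(y, x, metric), abs=1e-12
        )

    def test_jaccard_partial_overlap(self):
        x = np.array([0.5, 0.5, 0.0])
        y = np.array([0.0, 0.5, 0.5])
        assert ms.beta_diversity(x, y, "jaccard") == pytest.approx(2 / 3)

    def test_bc_half_overlap(self):
        x = np.array([0.5, 0.5, 0.0])
        y = np.array([0.5, 0.0, 0.5])
        assert ms.beta_diversity(x, y, "bc") == pytest.approx(0.5)

    def test_bc_within_unit_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.dirichlet(np.ones(5))
            y = rng.dirichlet(np.ones(5))
            assert 0.0 <= ms.beta_diversity(x, y, "bc") <= 1.0

    def test_aitchison_scale_invariance(self):
        x = np.array([1.0, 3.0, 6.0])
        assert ms.beta_diversity(x, 2 * x, "aitchison") == pytest.approx(0.0, abs=1e-10)

    def test_constant_profile_correlation_flagged(self):
        x = np.array([0.25, 0.25, 0.25, 0.25])
        y = np.array([0.4, 0.3, 0.2, 0.1])
        assert np.isnan(ms.beta_diversity(x, y, "cor"))


class TestWeightedUnifrac:
    def _star(self, n):
        leaves = ",".join(f"t{i}:1" for i in range(n))
        return ms.read_newick(_io.StringIO(f"({leaves});"))

    def test_identity(self):
        tree = self._star(4)
        x = np.array([0.4, 0.3, 0.2, 0.1])
        names = [f"t{i}" for i in range(4)]
        assert ms.weighted_unifrac(x, x, tree, names) == pytest.approx(0.0)

    def test_star_tree_equals_bray_curtis(self):
        tree = self._star(5)
        names = [f"t{i}" for i in range(5)]
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.dirichlet(np.ones(5))
            y = rng.dirichlet(np.ones(5))
            wu = ms.weighted_unifrac(x, y, tree, names)
            bc = ms.beta_diversity(x, y, "bc")
            assert wu == pytest.approx(bc, abs=1e-10)

    def test_opposite_clades_maximal(self):
        tree = ms.read_newick(_io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
        x = np.array([0.5, 0.5, 0.0, 0.0])
        y = np.array([0.0, 0.0, 0.5, 0.5])
        assert ms.weighted_unifrac(x, y, tree, ["A", "B", "C", "D"]) == pytest.approx(1.0)

    def test_missing_taxon_named_in_error(self):
        tree = self._star(3)
        x = np.array([0.5, 0.5])
        with pytest.raises(ValueError, match="ghost"):
            ms.weighted_unifrac(x, x, tree, ["t0", "ghost"])

    def test_matches_skbio_on_random_ultrametric_tree(self):
        # independent implementation as the oracle
        from skbio.diversity.beta import weighted_unifrac as skbio_wuni

        names = [f"t{i}" for i in range(6)]
        tree = ms.read_newick(_io.StringIO(ms.random_ultrametric_tree(names, seed=4)))
        skbio_tree = tree.copy()
        skbio_tree.length = 0.0
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.integers(1, 100, size=6)
            y = rng.integers(1, 100, size=6)
            mine = ms.weighted_unifrac(x, y, tree, names)
            ref = skbio_wuni(x, y, taxa=names, tree=skbio_tree, normalized=True)
            assert mine == pytest.approx(float(ref), abs=1e-10)


class TestRaupCrick:
    def _context(self, n_taxa=6, n_samples=20, seed=0):
        rng = np.random.default_rng(seed)
        return rng.multinomial(500, rng.dirichlet(np.ones(n_taxa)), size=n_samples)

    def test_identical_pair_is_strongly_negative(self):
        ctx = self._context()
        x = ctx[0]
        x = (x * 500 / x.sum()).astype(int)
        x[0] += 500 - x.sum()
        assert ms.raup_crick_bray(x, x, ctx, reps=999, seed=1) <= -0.99

    def test_always_within_range(self):
        ctx = self._context(seed=2)
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = rng.dirichlet(np.ones(6))
            x = rng.multinomial(300, p)
            y = rng.multinomial(300, rng.dirichlet(np.ones(6)))
            rc = ms.raup_crick_bray(x, y, ctx, reps=199, seed=4)
            assert -1.0 <= rc <= 1.0

    def test_null_draws_score_near_zero(self):
        # pairs generated by the null itself should centre around rc = 0
        from microstab.obs import _null_community

        ctx = self._context(seed=5)
        occ = (ctx > 0).mean(axis=0)
        rel = ctx / ctx.sum(axis=1, keepdims=True)
        mean_rel = rel.mean(axis=0)
        rng = np.random.default_rng(6)
        vals = []
        for i in range(100):
            x = _null_community(rng, 5, 300, occ, mean_rel)
            y = _null_community(rng, 5, 300, occ, mean_rel)
            vals.append(ms.raup_crick_bray(x, y, ctx, reps=199, seed=100 + i))
        assert abs(np.mean(vals)) < 0.1

    def test_depth_mismatch_rejected(self):
        ctx = self._context()
        with pytest.raises(ValueError, match="common depth"):
            ms.raup_crick_bray([10, 0, 0, 0, 0, 0], [5, 0, 0, 0, 0, 0], ctx, reps=199)


class TestResponsePotential:
    def test_context_of_copies_gives_zero(self):
        x = np.array([0.5, 0.3, 0.2])
        ctx = np.tile(x, (5, 1))
        assert ms.response_potential(x, ctx, "bc") == pytest.approx(0.0)

    def test_mean_over_context(self):
        x = np.array([1.0, 0.0])
        ctx = np.array([[0.9, 0.1], [0.8, 0.2]])  # BC 0.1 and 0.2
        assert ms.response_potential(x, ctx, "bc") == pytest.approx(0.15)

    def test_nearest_neighbour_only(self):
        x = np.array([1.0, 0.0])
        ctx = np.array([[0.9, 0.1], [0.8, 0.2]])
        assert ms.response_potential(x, ctx, "bc", k=1) == pytest.approx(0.1)

    def test_empty_context_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ms.response_potential([1.0, 0.0], np.empty((0, 2)), "bc")


class TestStabilityPanel:
    def test_panel_shape_and_flags(self, small_cohort):
        _, _, table, meta, _ = small_cohort
        panel = ms.stability_panel(table, meta, rc_reps=199, seed=0)
        n_eligible = (
            meta.groupby("subject_id")["sample_id"].count().ge(2).sum()
        )
        assert len(panel) == n_eligible
        # no tree supplied -> weighted UniFrac flagged missing everywhere
        assert panel["inv_wuni"].isna().all()
        for col in ("inv_bc", "inv_jaccard"):
            assert panel[col].dropna().between(0, 1).all()
        assert panel["neg_rc_bray"].dropna().between(-1, 1).all()
        assert {"delta_t", "intervention", "shannon_baseline"} <= set(panel.columns)

    def test_identical_time_points_score_perfectly_stable(self):
        import pandas as pd
        from tests.conftest import make_meta

        rows, meta_rows = [], []
        base = np.array([3000, 2000, 1000, 500])
        for s in range(12):
            for day in (0, 7):
                rows.append(base)
                meta_rows.append((f"x{s}_{day}", f"s{s}", day))
        t = ms.AbundanceTable(
            pd.DataFrame(
                rows, index=[m[0] for m in meta_rows], columns=list("abcd"), dtype=float
            ),
            kind="counts",
        )
        panel = ms.stability_panel(t, make_meta(meta_rows), rc_reps=199, seed=0)
        assert np.allclose(panel["inv_bc"], 1.0)
        assert np.allclose(panel["neg_ait"], 0.0, atol=1e-10)
        assert np.allclose(panel["inv_jaccard"], 1.0)
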
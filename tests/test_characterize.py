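import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from chemcca import characterize as chz
from chemcca import rcca, synth
from chemcca.genesets import GeneSetCollection
from chemcca.io import InputError, ParameterError
from chemcca.retrieval import AnnotationSet
from oracles import enumerate_overlap_tail


@pytest.fixture(scope="module")
def fitted():
    x, y, truth = synth.simulate_joint_data(80, 8, 10, 2, (0.9, 0.8), 0.5, seed=0)
    model = rcca.fit_rcca(x, y, 0.01, 0.01, n_components=2)
    split = rcca.split_subcomponents(model)
    return x, y, model, split


class TestTopGeneSets:
    def test_column_equal_to_variate_ranks_first(self, fitted):
        x, y, model, _ = fitted
        y2 = y.copy()
        y2["mirror"] = model.bio_variates.iloc[:, 0]
        ranked = chz.top_gene_sets(model, y2, 0, k=3)
        assert ranked[0][0] == "mirror"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_exactly_k_returned(self, fitted):
        x, y, model, _ = fitted
        assert len(chz.top_gene_sets(model, y, 0, k=10)) == 10

    def test_constant_column_gets_zero_association(self, fitted):
        x, y, model, _ = fitted
        y2 = y.copy()
        y2["flat"] = 0.5
        ranked = dict(chz.top_gene_sets(model, y2, 0, k=y2.shape[1]))
        assert ranked["flat"] == 0.0


class TestTopCompounds:
    def test_default_cap_and_short_side(self, fitted):
        x, y, model, split = fitted
        top = chz.top_compounds(split, 0, "A", k=20)
        assert len(top) <= 20
        few = chz.top_compounds(split, 0, "A", k=3)
        assert len(few) == 3
        mags = [abs(s) for _, s in few]
        assert mags == sorted(mags, reverse=True)

    def test_rank_invariant_to_positive_rescaling(self, fitted):
        x, y, model, split = fitted
        before = [c for c, _ in chz.top_compounds(split, 0, "A", k=10)]
        scaled = rcca.ComponentSplit(scores=split.scores * 3.7)
        for col in scaled.scores.columns:
            s = scaled.scores[col]
            scaled.members_a.append(list(s.index[s > 0]))
            scaled.members_b.append(list(s.index[s < 0]))
        after = [c for c, _ in chz.top_compounds(scaled, 0, "A", k=10)]
        assert before == after


class TestRegularizedT:
    def test_zero_prior_equals_student_t(self, rng):
        vals = rng.standard_normal((50, 8)) + 0.3
        t, p = chz.regularized_t(vals, background_var=1.0, prior_df=0.0)
        t_ref, p_ref = stats.ttest_1samp(vals, 0.0, axis=1)
        np.testing.assert_allclose(t, t_ref, atol=1e-10)
        np.testing.assert_allclose(p, p_ref, atol=1e-10)

    def test_zero_sample_variance_stays_finite_with_prior(self):
        vals = np.full((1, 5), 2.0)
        t, p = chz.regularized_t(vals, background_var=1.0, prior_df=4.0)
        assert np.isfinite(t).all() and 0 < p[0] < 1

    def test_guard_conditions(self):
        with pytest.raises(InputError):
            chz.regularized_t(np.ones((3, 1)), 1.0, 1.0)
        with pytest.raises(ParameterError):
            chz.regularized_t(np.ones((3, 2)), 1.0, 0.0)  # prior_df + n - 2 = 0

    def test_moderation_shrinks_toward_background(self, rng):
        vals = rng.standard_normal((200, 4)) * 0.1  # small sample variance
        t_mod, _ = chz.regularized_t(vals, background_var=4.0, prior_df=50.0)
        t_plain, _ = chz.regularized_t(vals, background_var=4.0, prior_df=1e-9)
        assert np.abs(t_mod).mean() < np.abs(t_plain).mean()


class TestWindowedBackground:
    def test_constant_variance_recovered(self, rng):
        vals = rng.standard_normal((500, 10))
        bg = chz.windowed_background_variance(vals, window=101)
        assert bg == pytest.approx(np.ones(500), abs=0.5)
        assert bg.shape == (500,)


class TestComponentDeGenes:
    def test_planted_signal_recovered_null_rejected(self, rng):
        # component variate drives a block of genes; unrelated genes stay null
        n, n_genes = 40, 120
        score = rng.standard_normal(n)
        responses = pd.DataFrame(
            rng.standard_normal((n, n_genes)) * 0.3,
            index=[f"c{i}" for i in range(n)],
            columns=[f"g{i:03d}" for i in range(n_genes)],
        )
        responses.iloc[:, :30] += np.outer(score, np.ones(30)) * 2.0
        y = pd.DataFrame(
            {
                "sig": score + rng.standard_normal(n) * 0.1,
                "null1": rng.standard_normal(n),
                "null2": rng.standard_normal(n),
            },
            index=responses.index,
        )
        coll = GeneSetCollection(
            sets={
                "sig": frozenset(responses.columns[:30]),
                "null1": frozenset(responses.columns[30:60]),
                "null2": frozenset(responses.columns[60:90]),
            },
            universe=list(responses.columns),
        )
        x = pd.DataFrame(rng.standard_normal((n, 5)), index=responses.index)
        model = rcca.fit_rcca(x, y, 0.1, 0.1, n_components=1)
        # make the variate the planted score itself for a controlled check
        model.bio_variates.iloc[:, 0] = score
        split = rcca.split_subcomponents(model, side="bio")
        table = chz.component_de_genes(model, split, responses, y, coll, 0, "A")
        hits = set(table.index)
        assert len(hits & set(responses.columns[:30])) >= 20

    def test_empty_result_is_valid(self, fitted, rng):
        x, y, model, split = fitted
        responses = pd.DataFrame(
            rng.standard_normal((80, 40)) * 1e-12,
            index=x.index,
            columns=[f"g{i}" for i in range(40)],
        )
        coll = GeneSetCollection(
            sets={name: frozenset(responses.columns[:5]) for name in y.columns},
            universe=list(responses.columns),
        )
        table = chz.component_de_genes(model, split, responses, y, coll, 0, "A")
        assert list(table.columns) == ["t", "p"]


class TestTermEnrichment:
    def test_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(12)]
        term = set(universe[:5])
        coll = GeneSetCollection(sets={"T": frozenset(term)}, universe=universe)
        for draw_size in (1, 3, 5, 8):
            gene_list = universe[2 : 2 + draw_size]
            (name, p), = chz.term_enrichment(gene_list, coll, universe)
            observed = len(term & set(gene_list))
            if observed == 0:
                assert p == 1.0
            else:
                expected = enumerate_overlap_tail(universe, term, draw_size, observed)
                assert p == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = ["a", "b", "c", "d"]
        coll = GeneSetCollection(sets={"T": frozenset({"a"})}, universe=universe)
        (_, p), = chz.term_enrichment(["b", "c"], coll, universe)
        assert p == 1.0

    def test_list_outside_universe_rejected(self):
        coll = GeneSetCollection(sets={"T": frozenset({"a"})}, universe=["a", "b"])
        with pytest.raises(InputError):
            chz.term_enrichment(["zz"], coll, ["a", "b"])


class TestTanimoto:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"x"}, {"x", "y", "z"}, 1 / 3),
            (set(), set(), 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert chz.tanimoto(a, b) == pytest.approx(expected)

    @given(
        a=st.sets(st.integers(0, 20)),
        b=st.sets(st.integers(0, 20)),
    )
    def test_symmetric_bounded_identity(self, a, b):
        t = chz.tanimoto(a, b)
        assert 0 <= t <= 1
        assert t == chz.tanimoto(b, a)
        if a and a == b:
            assert t == 1.0
        if t == 1.0 and a:
            assert a == b


class TestTargetEnrichment:
    def _ann(self, mapping):
        rows = [(c, lab, "target") for c, labs in mapping.items() for lab in labs]
        return AnnotationSet(pairs=pd.DataFrame(rows, columns=["compound_id", "label_id", "kind"]))

    def test_exclusive_shared_target_reaches_minimum_p(self):
        pool = {f"c{i}": {f"T{i}"} for i in range(200)}
        members = [f"s{i}" for i in range(20)]
        for m in members:
            pool[m] = {"SHARED"}
        ann = self._ann(pool)
        # pair statistic: observed C(20,2)=190 pairs is unreachable by random
        # draws (at most a handful of SHARED carriers per draw)
        shared, statistic, p = chz.target_enrichment(
            members, ann, n_draws=200, seed=0, statistic="pairs"
        )
        assert shared == ["SHARED"]
        assert statistic == 190
        assert p == pytest.approx(1 / 201)

    def test_no_targets_gives_zero_statistic(self):
        ann = self._ann({f"c{i}": {f"T{i}"} for i in range(50)})
        shared, statistic, p = chz.target_enrichment(["x1", "x2", "x3"], ann, n_draws=100, seed=1)
        assert statistic == 0 and shared == []
        assert p == pytest.approx(1.0)

    def test_pair_statistic_variant(self):
        ann = self._ann({"a": {"T"}, "b": {"T"}, "c": {"T"}, "d": {"U"}})
        _, statistic, _ = chz.target_enrichment(
            ["a", "b", "c"], ann, n_draws=50, seed=2, statistic="pairs"
        )
        assert statistic == 3  # three pairs share T

    def test_short_list_rejected(self):
        ann = self._ann({"a": {"T"}})
        with pytest.raises(InputError):
            chz.target_enrichment(["a"], ann, n_draws=10, seed=0)


class TestEyeDiagram:
    def test_shape_and_consistency_with_top_gene_sets(self, fitted):
        x, y, model, split = fitted
        table = chz.eye_diagram_table(model, split, y, x, k_sets=5, components=[0, 1])
        sets_rows = table[(table["kind"] == "gene-set") & (table["component"] == 1)]
        assert len(sets_rows) == 5
        expected = chz.top_gene_sets(model, y, 0, k=5)
        got = list(zip(sets_rows["element"], sets_rows["weight"]))
        assert [e for e, _ in got] == [e for e, _ in expected]
        desc_rows = table[(table["kind"] == "descriptor") & (table["component"] == 1)]
        # every descriptor appears for each non-empty side
        sides = set(desc_rows["side"])
        for side in sides:
            assert len(desc_rows[desc_rows["side"] == side]) == x.shape[1]


class TestSubcomponentSimilarity:
    def test_self_similarity_and_symmetry(self):
        r1 = chz.SubcomponentReport(component=0, side="A")
        r1.top_compounds = [(f"c{i}", 1.0) for i in range(20)]
        r1.significant_genes = pd.DataFrame(
            {"t": 1.0, "p": 0.01}, index=[f"g{i}" for i in range(30)]
        )
        r2 = chz.SubcomponentReport(component=1, side="B")
        r2.top_compounds = [(f"c{i}", 1.0) for i in range(10, 30)]
        r2.significant_genes = pd.DataFrame(
            {"t": 1.0, "p": 0.01}, index=[f"h{i}" for i in range(30)]
        )
        bio, overlap = chz.subcomponent_similarity([r1, r2])
        assert bio.loc["1A", "1A"] == 1.0
        assert overlap.loc["1A", "1A"] == 20
        assert overlap.loc["1A", "2B"] == overlap.loc["2B", "1A"] == 10
        assert bio.loc["1A", "2B"] == 0.0
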
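"""Twelve-category classification, silencing/novel detection, properties."""

import pytest
from hypothesis import given, strategies as st

from triploidexpr.classifier import (Category, ClassifierConfig, MIRROR,
                                     classify_all, classify_gene, detect_novel,
                                     detect_silenced, pairwise_call)
from triploidexpr.io import GroupExpression, growth_panel_expression, load_growth_panel

positive = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


class TestPairwiseCall:
    @pytest.mark.parametrize("x, y, expected", [
        (4.68, 2.00, "higher"),   # log2 = 1.226, outside the band
        (3.3, 3.3, "equal"),
        (6.95, 3.51, "equal"),    # log2 = 0.986, inside the band (non-strict)
        (1.0, 4.2, "lower"),
    ])
    def test_band_edges(self, x, y, expected):
        assert pairwise_call(x, y).value == expected

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_call(0.0, 1.0)

    @given(x=positive, y=positive)
    def test_antisymmetry(self, x, y):
        a, b = pairwise_call(x, y), pairwise_call(y, x)
        flip = {"higher": "lower", "lower": "higher", "equal": "equal"}
        assert b.value == flip[a.value]


class TestSilencedNovel:
    @pytest.mark.parametrize("b, g, h, expected", [
        (15, 12, 0, True),
        (15, 5, 0, False),    # maternal below the floor
        (15, 12, 0.3, False),  # hybrid not fully silent
    ])
    def test_silencing_rule(self, b, g, h, expected):
        assert detect_silenced(b, g, h) is expected

    @pytest.mark.parametrize("b, g, h, expected", [
        (0, 0, 12, True),
        (0, 0, 4, False),     # below the floor
        (0.2, 0, 12, False),  # parental expression present
    ])
    def test_novel_rule(self, b, g, h, expected):
        assert detect_novel(b, g, h) is expected

    @given(b=st.floats(0, 100), g=st.floats(0, 100), h=st.floats(0, 100))
    def test_mutually_exclusive(self, b, g, h):
        assert not (detect_silenced(b, g, h) and detect_novel(b, g, h))


class TestClassifyGene:
    @pytest.mark.parametrize("b, g, h, expected", [
        (1.28, 0.09, 0.05, Category.IX),     # maternal dominance
        (21.24, 19.72, 53.65, Category.IV),  # transgressive up
        (5.83, 19.20, 18.91, Category.X),    # maternal dominance, mother high
        (1.0, 1.0, 1.0, Category.NO_CHANGE),
        (4.0, 1.1, 2.1, Category.AMBIGUOUS),  # ratios 0.93/-0.93 vs parents 1.86
        (8.0, 1.0, 2.83, Category.XI),       # geometric mid-point
        (1.0, 8.0, 2.83, Category.XII),
        (8.0, 1.0, 80.0, Category.V),
        (1.0, 8.0, 80.0, Category.VI),
        (8.0, 1.0, 0.1, Category.I),
        (1.0, 8.0, 0.1, Category.II),
        (4.0, 4.0, 0.5, Category.III),
        (8.0, 1.0, 8.0, Category.VII),
        (1.0, 8.0, 1.0, Category.VIII),
    ])
    def test_decision_table(self, b, g, h, expected):
        assert classify_gene(b, g, h).category is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_gene(0.0, 1.0, 1.0)

    def test_ambiguous_tiebreak_moves_toward_closer_parent(self):
        config = ClassifierConfig(ambiguous_tiebreak=True)
        # hybrid inside both bands (ratios -1.0 and 0.86) but nearer the mother
        assert classify_gene(4.0, 1.1, 2.0).category is Category.AMBIGUOUS
        assignment = classify_gene(4.0, 1.1, 2.0, config)
        assert assignment.category is Category.IX

    @given(b=positive, g=positive, h=positive)
    def test_totality(self, b, g, h):
        """Every strictly positive triple maps to exactly one category."""
        category = classify_gene(b, g, h).category
        assert category in set(Category)
        assert category is not Category.UNRESOLVED  # impossible in threshold mode

    @given(b=positive, g=positive, h=positive,
           c=st.floats(1e-3, 1e3, allow_nan=False))
    def test_scale_invariance(self, b, g, h, c):
        assert classify_gene(b, g, h).category is \
            classify_gene(c * b, c * g, c * h).category

    @given(b=positive, g=positive, h=positive)
    def test_parental_mirror_symmetry(self, b, g, h):
        """Swapping parents maps I<->II, V<->VI, VII<->X, VIII<->IX, XI<->XII."""
        forward = classify_gene(b, g, h).category
        swapped = classify_gene(g, b, h).category
        assert swapped is MIRROR.get(forward, forward)


class TestClassifyAll:
    def test_growth_panel_reproduces_published_labels(self):
        panel = load_growth_panel()
        assignments, summary = classify_all(growth_panel_expression())
        assert [a.category.value for a in assignments] == list(panel["category"])
        assert summary["paternalELD"] == 11
        assert summary["maternalELD"] == 13
        assert summary["mid"] == 11
        assert summary["up"] == 4
        assert summary["down"] == 6  # recount of rows labelled I-III

    def test_scaling_all_levels_preserves_assignments(self):
        expr = growth_panel_expression()
        scaled = [GroupExpression(e.gene_id, 3.7 * e.chi_paternal,
                                  3.7 * e.chi_maternal, 3.7 * e.at_elv)
                  for e in expr]
        base, _ = classify_all(expr)
        after, _ = classify_all(scaled)
        assert [a.category for a in base] == [a.category for a in after]

    def test_silenced_novel_excluded_routed_before_ratios(self):
        expr = [
            GroupExpression("silent", 15.0, 12.0, 0.0),
            GroupExpression("novel", 0.0, 0.0, 12.0),
            GroupExpression("excluded", 5.0, 0.0, 3.0),  # zero mother, below rules
            GroupExpression("classified", 5.0, 5.0, 5.0),
        ]
        assignments, summary = classify_all(expr)
        assert [a.category for a in assignments] == [
            Category.SILENCED, Category.NOVEL, Category.EXCLUDED, Category.NO_CHANGE]
        assert summary["Silenced"] == summary["Novel"] == summary["Excluded"] == 1

    def test_statistical_mode_requires_and_uses_de_calls(self):
        expr = [GroupExpression("g1", 8.0, 1.0, 8.0)]
        with pytest.raises(ValueError, match="statistical"):
            classify_all(expr, ClassifierConfig(mode="statistical"))
        de_results = {
            "parents": {"g1": "up"},          # paternal above maternal
            "hybrid_paternal": {"g1": "ns"},  # hybrid matches father
            "hybrid_maternal": {"g1": "up"},
        }
        assignments, _ = classify_all(expr, ClassifierConfig(mode="statistical"),
                                      de_results=de_results)
        assert assignments[0].category is Category.VII

    def test_statistical_mode_surfaces_inconsistent_triples(self):
        expr = [GroupExpression("g1", 8.0, 1.0, 8.0)]
        de_results = {
            "parents": {"g1": "up"},            # father above mother...
            "hybrid_paternal": {"g1": "up"},    # ...hybrid above father...
            "hybrid_maternal": {"g1": "down"},  # ...yet below mother: impossible
        }
        assignments, summary = classify_all(
            expr, ClassifierConfig(mode="statistical"), de_results=de_results)
        assert assignments[0].category is Category.UNRESOLVED
        assert summary["Unresolved"] == 1
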
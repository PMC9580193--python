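"""Similarity-method contracts: worked examples and property-based checks."""

import pytest
from hypothesis import given, settings, strategies as st

from vaxalign import (
    Code,
    classify,
    build_dictionary,
    property_values,
    similarity_classes,
    similarity_equivalence,
    similarity_properties,
    similarity_tokens,
    vaccine_class,
)
from vaxalign.compiler import PropertyValues


class TestTokens:
    def test_jaccard_of_token_sets(self):
        a = Code("a", "hepatitis a vaccine")
        b = Code("b", "hepatitis b vaccine")
        assert similarity_tokens(a, b) == pytest.approx(0.5)

    def test_identical_descriptors(self):
        a = Code("a", "oral polio vaccine")
        assert similarity_tokens(a, a) == 1.0

    def test_disjoint_and_empty(self):
        assert similarity_tokens(Code("a", "influenza"), Code("b", "tetanus")) == 0.0
        assert similarity_tokens(Code("a", ""), Code("b", "")) == 0.0


class TestClasses:
    def test_jaccard_of_class_sets(self):
        assert similarity_classes(
            frozenset({"influenza", "live-attenuated"}), frozenset({"influenza"})
        ) == pytest.approx(0.5)

    def test_empty_side_scores_zero(self):
        assert similarity_classes(frozenset(), frozenset({"influenza"})) == 0.0
        assert similarity_classes(frozenset(), frozenset()) == 0.0

    def test_distinct_linked_classes_do_not_overlap(self, mini_onto, mini_dict):
        # the documented weakness: pathogen- and disease-based descriptors
        # tag different classes, so the Classes method sees no similarity
        a = vaccine_class("Human papillomavirus vaccine", mini_onto, mini_dict)
        b = vaccine_class("Vaccine against cervical cancer", mini_onto, mini_dict)
        assert similarity_classes(a.class_ids, b.class_ids) == 0.0


class TestEquivalence:
    def test_causally_linked_descriptions_are_equivalent(
        self, mini_onto, mini_index, mini_dict
    ):
        a = vaccine_class("Vaccine against cervical cancer", mini_onto, mini_dict)
        b = vaccine_class("Human papillomavirus vaccine", mini_onto, mini_dict)
        assert similarity_equivalence(a, b, mini_index) == 1.0

    def test_strict_specialization_scores_zero(self, mini_onto, mini_index, mini_dict):
        a = vaccine_class("Live/attenuated influenza vaccine", mini_onto, mini_dict)
        b = vaccine_class("Flu vaccine", mini_onto, mini_dict)
        assert similarity_equivalence(a, b, mini_index) == 0.0

    def test_self_equivalence(self, mini_onto, mini_index, mini_dict):
        a = vaccine_class("Flu vaccine", mini_onto, mini_dict)
        assert similarity_equivalence(a, a, mini_index) == 1.0

    def test_uninformative_never_equivalent(self, mini_onto, mini_index, mini_dict):
        a = vaccine_class("zzz", mini_onto, mini_dict)
        assert similarity_equivalence(a, a, mini_index) == 0.0


def _pv(targets=(), strategy=(), uninformative=False):
    return PropertyValues(
        values={
            "immunizes-against": frozenset(targets),
            "has-strategy": frozenset(strategy),
            "has-ingredient": frozenset(),
            "has-valence": frozenset(),
            "has-route": frozenset(),
        },
        uninformative=uninformative,
    )


class TestProperties:
    def test_identical_values_score_one(self):
        a = _pv(targets={"influenza"}, strategy={"inactivated"})
        assert similarity_properties(a, a) == 1.0

    def test_extra_strategy_halves_overlap(self):
        a = _pv(targets={"influenza"}, strategy={"inactivated"})
        b = _pv(targets={"influenza"})
        assert similarity_properties(a, b) == pytest.approx(0.5)

    def test_target_gate_fires_on_unequal_sets(self):
        a = _pv(targets={"diphtheria", "tetanus"})
        b = _pv(targets={"diphtheria", "tetanus", "pertussis"})
        assert similarity_properties(a, b) == 0.0

    def test_overlap_gate_reading(self):
        a = _pv(targets={"diphtheria", "tetanus"})
        b = _pv(targets={"diphtheria", "tetanus", "pertussis"})
        assert similarity_properties(a, b, targets_gate="overlap") == pytest.approx(2 / 3)
        c = _pv(targets={"influenza"})
        assert similarity_properties(a, c, targets_gate="overlap") == 0.0

    def test_both_uninformative_score_zero(self):
        a = _pv(uninformative=True)
        assert similarity_properties(a, a) == 0.0


# -- property-based contracts over generated descriptors ----------------

_DESCRIPTOR_PARTS = [
    "influenza", "flu", "hepatitis a", "tuberculosis", "pertussis", "tetanus",
    "diphtheria", "cervical cancer", "human papillomavirus", "inactivated",
    "attenuated", "toxoid", "oral", "trivalent", "dtwp", "iiv3", "influvac",
    "havrix", "vaccine", "zzz",
]

descriptors = st.lists(
    st.sampled_from(_DESCRIPTOR_PARTS), min_size=1, max_size=4
).map(" ".join)


@pytest.fixture(scope="module")
def method_context(mini_onto):
    index = classify(mini_onto)
    dictionary = build_dictionary(mini_onto)
    return mini_onto, index, dictionary


@given(a=descriptors, b=descriptors)
@settings(max_examples=60, deadline=None)
def test_all_methods_symmetric_and_bounded(method_context, a, b):
    onto, index, dictionary = method_context
    ca = Code("a", a)
    cb = Code("b", b)
    va = vaccine_class(a, onto, dictionary)
    vb = vaccine_class(b, onto, dictionary)
    pa = property_values(va, onto, index)
    pb = property_values(vb, onto, index)

    scores = {
        "tokens": (similarity_tokens(ca, cb), similarity_tokens(cb, ca)),
        "classes": (
            similarity_classes(va.class_ids, vb.class_ids),
            similarity_classes(vb.class_ids, va.class_ids),
        ),
        "equivalence": (
            similarity_equivalence(va, vb, index),
            similarity_equivalence(vb, va, index),
        ),
        "properties": (similarity_properties(pa, pb), similarity_properties(pb, pa)),
    }
    for name, (fwd, bwd) in scores.items():
        assert fwd == bwd, name
        assert 0.0 <= fwd <= 1.0, name
    assert scores["equivalence"][0] in (0.0, 1.0)
    if scores["properties"][0] > 0:
        # gate consistency: positive properties score implies equal target sets
        assert pa["immunizes-against"] == pb["immunizes-against"]


@given(text=descriptors)
@settings(max_examples=40, deadline=None)
def test_self_similarity_one_for_informative_codes(method_context, text):
    onto, index, dictionary = method_context
    code = Code("x", text)
    vc = vaccine_class(text, onto, dictionary)
    pv = property_values(vc, onto, index)
    assert similarity_tokens(code, code) == (1.0 if text.strip() else 0.0)
    if not vc.uninformative:
        assert similarity_classes(vc.class_ids, vc.class_ids) == 1.0
        assert similarity_equivalence(vc, vc, index) == 1.0
        assert similarity_properties(pv, pv) == 1.0
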
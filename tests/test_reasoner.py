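"""Reasoner tests: completion rules, chains, and oracle equivalence."""

import random

import pytest

from vaxalign import (
    Assertion,
    And,
    Named,
    ObjectProperty,
    Ontology,
    OntologyClass,
    PropertyChain,
    Some,
    classify,
    entailed_fillers,
    equivalent,
    is_subsumed,
)
from vaxalign.errors import CycleError, UnknownIdentifierError
from vaxalign.ontology import FUNDAMENTAL_ROOTS

from oracle_utils import naive_closure, random_ontology


def _base(extra_classes=(), properties=(), chains=(), assertions=()):
    classes = [OntologyClass(r) for r in FUNDAMENTAL_ROOTS] + list(extra_classes)
    return Ontology(classes, properties, chains, assertions)


IMM = ObjectProperty("immunizes-against", "vaccine", ("pathogen", "disease"))
ING = ObjectProperty("has-ingredient", "vaccine", ("ingredient",))
STRAT = ObjectProperty("has-strategy", "vaccine", ("strategy",))
CAUSES = ObjectProperty("causes", "pathogen", ("disease",))


def test_ingredient_chain_propagates_immunization_target():
    # v has an ingredient that immunizes against flu => v immunizes against flu
    onto = _base(
        extra_classes=[
            OntologyClass("v", ("vaccine",)),
            OntologyClass("active-ingredient", ("ingredient",)),
            OntologyClass("i", ("active-ingredient",)),
            OntologyClass("flu", ("disease",)),
        ],
        properties=[IMM, ING],
        chains=[PropertyChain(("has-ingredient", "immunizes-against"), "immunizes-against")],
        assertions=[
            Assertion("v", "has-ingredient", "i"),
            Assertion("i", "immunizes-against", "flu"),
        ],
    )
    index = classify(onto)
    assert index.relation_holds("v", "immunizes-against", "flu")


def test_ingredient_chain_propagates_strategy():
    onto = _base(
        extra_classes=[
            OntologyClass("v", ("vaccine",)),
            OntologyClass("active-ingredient", ("ingredient",)),
            OntologyClass("i", ("active-ingredient",)),
            OntologyClass("inactivated", ("strategy",)),
        ],
        properties=[ING, STRAT],
        chains=[PropertyChain(("has-ingredient", "has-strategy"), "has-strategy")],
        assertions=[
            Assertion("v", "has-ingredient", "i"),
            Assertion("i", "has-strategy", "inactivated"),
        ],
    )
    index = classify(onto)
    assert index.relation_holds("v", "has-strategy", "inactivated")


def test_causal_chain_unifies_immunization_targets():
    # minimal fixture spelled exactly as the motivating example:
    # v immunizes against Hib, Hib causes cervical cancer => v immunizes
    # against cervical cancer
    onto = _base(
        extra_classes=[
            OntologyClass("v", ("vaccine",)),
            OntologyClass("hib", ("pathogen",)),
            OntologyClass("cervical-cancer", ("disease",)),
        ],
        properties=[IMM, CAUSES],
        chains=[PropertyChain(("immunizes-against", "causes"), "immunizes-against")],
        assertions=[
            Assertion("v", "immunizes-against", "hib"),
            Assertion("hib", "causes", "cervical-cancer"),
        ],
    )
    index = classify(onto)
    assert index.relation_holds("v", "immunizes-against", "cervical-cancer")


def test_subsumption_reflexive_and_transitive():
    onto = _base(
        extra_classes=[
            OntologyClass("a", ("disease",)),
            OntologyClass("b", ("a",)),
            OntologyClass("c", ("b",)),
        ]
    )
    index = classify(onto)
    for cid in onto.classes:
        assert index.is_subclass(cid, cid)
    assert index.is_subclass("c", "a")
    assert index.is_subclass("c", "disease")
    assert not index.is_subclass("a", "c")


def test_cycle_in_parent_links_names_the_cycle():
    classes = [OntologyClass(r) for r in FUNDAMENTAL_ROOTS] + [
        OntologyClass("a", ("b",)),
        OntologyClass("b", ("a",)),
    ]
    with pytest.raises(CycleError) as err:
        Ontology(classes)
    assert {"a", "b"} <= set(err.value.cycle)


def test_oracle_equivalence_on_random_ontologies():
    """Worklist closure equals the brute-force fixpoint on 200 random ontologies."""
    rng = random.Random(20240)
    for _ in range(200):
        onto = random_ontology(rng)
        index = classify(onto)
        subs_oracle, triples_oracle = naive_closure(onto)
        subs_impl = {
            (a, b) for a in onto.classes for b in onto.classes if index.is_subclass(a, b)
        }
        assert subs_impl == subs_oracle
        assert index.triples() == triples_oracle


def test_monotonicity_adding_an_assertion_never_removes_entailments():
    rng = random.Random(77)
    for _ in range(30):
        onto = random_ontology(rng)
        before = classify(onto).triples()
        ids = list(onto.classes)
        prop_ids = list(onto.properties)
        extra = Assertion(rng.choice(ids), rng.choice(prop_ids), rng.choice(ids))
        bigger = Ontology(
            onto.classes.values(),
            onto.properties.values(),
            onto.chains,
            (*onto.assertions, extra),
        )
        after = classify(bigger).triples()
        assert before <= after


def test_chain_soundness_on_random_closures():
    """Every instantiated chain premise pair in the closure yields its conclusion."""
    rng = random.Random(4242)
    for _ in range(50):
        onto = random_ontology(rng)
        index = classify(onto)
        triples = index.triples()
        for chain in onto.chains:
            p1, p2 = chain.lhs
            for (a, q1, b) in triples:
                if q1 != p1:
                    continue
                for (b2, q2, c) in triples:
                    if q2 == p2 and b2 == b:
                        assert (a, chain.rhs, c) in triples


class TestCompoundSubsumption:
    def test_conjunct_dropping(self, mini_index):
        a = And(
            (
                Named("vaccine"),
                Some("immunizes-against", Named("influenza")),
                Some("has-strategy", Named("live-attenuated")),
            )
        )
        b = And((Named("vaccine"), Some("immunizes-against", Named("influenza"))))
        assert is_subsumed(mini_index, a, b)
        assert not is_subsumed(mini_index, b, a)

    def test_causally_linked_fillers_interchange(self, mini_index):
        a = Some("immunizes-against", Named("human-papillomavirus"))
        b = Some("immunizes-against", Named("cervical-cancer"))
        assert is_subsumed(mini_index, a, b)  # via hpv causes cervical-cancer
        assert is_subsumed(mini_index, b, a)  # via the declared reverse link
        assert equivalent(mini_index, a, b)

    def test_unrelated_fillers_do_not_subsume(self, mini_index):
        a = Some("immunizes-against", Named("influenza"))
        b = Some("immunizes-against", Named("tuberculosis"))
        assert not is_subsumed(mini_index, a, b)
        assert not is_subsumed(mini_index, b, a)

    def test_unknown_identifier_raises_lookup_error(self, mini_index):
        with pytest.raises(UnknownIdentifierError, match="nonexistent"):
            is_subsumed(mini_index, Named("nonexistent"), Named("vaccine"))


class TestEntailedFillers:
    def test_product_inherits_target_through_ingredient(self, mini_index):
        assert entailed_fillers(mini_index, Named("havrix"), "immunizes-against") == {
            "hepatitis-a"
        }

    def test_bare_vaccine_entails_nothing(self, mini_index):
        assert entailed_fillers(mini_index, Named("vaccine"), "immunizes-against") == frozenset()

    def test_roots_excluded_by_default(self, mini_onto):
        # assert a filler that generalizes to the disease root: the root must
        # be filtered, its non-root ancestors kept
        index = classify(mini_onto)
        expr = Some("immunizes-against", Named("influenza"))
        fillers = entailed_fillers(
            index, And((Named("vaccine"), expr)), "immunizes-against", exclude_roots=False
        )
        assert "disease" in fillers
        fillers_no_roots = entailed_fillers(
            index, And((Named("vaccine"), expr)), "immunizes-against"
        )
        assert "disease" not in fillers_no_roots
        assert "influenza" in fillers_no_roots
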
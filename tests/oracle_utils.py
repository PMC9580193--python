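"""Independent brute-force oracle and random-ontology generator for reasoner tests.

The oracle enumerates all derivable subsumptions and existential triples by
repeated full-scan rule application until nothing changes.  It shares no code
with the package's indexed worklist reasoner.
"""

from __future__ import annotations

import random

from vaxalign.ontology import (
    Assertion,
    FUNDAMENTAL_ROOTS,
    ObjectProperty,
    Ontology,
    OntologyClass,
    PropertyChain,
)


def naive_closure(onto: Ontology) -> tuple[set[tuple[str, str]], set[tuple[str, str, str]]]:
    """(subsumption pairs, existential triples) by dumb fixpoint iteration."""
    classes = list(onto.classes)
    subs = {(c, c) for c in classes}
    for cls in onto.classes.values():
        for p in cls.parent_ids:
            subs.add((cls.id, p))
    triples = {(a.subject_id, a.property_id, a.filler_id) for a in onto.assertions}
    chains = [(c.lhs[0], c.lhs[1], c.rhs) for c in onto.chains]
    changed = True
    while changed:
        changed = False
        for (a, b) in list(subs):
            for (b2, c) in list(subs):
                if b == b2 and (a, c) not in subs:
                    subs.add((a, c))
                    changed = True
        for (a, b) in list(subs):
            for (a2, p, f) in list(triples):
                if a2 == b and (a, p, f) not in triples:  # inheritance
                    triples.add((a, p, f))
                    changed = True
        for (s, p, f) in list(triples):
            for (f2, g) in list(subs):
                if f == f2 and (s, p, g) not in triples:  # filler generalization
                    triples.add((s, p, g))
                    changed = True
        for (p1, p2, rhs) in chains:
            for (a, q1, b) in list(triples):
                if q1 != p1:
                    continue
                for (b2, q2, c) in list(triples):
                    if q2 == p2 and b2 == b and (a, rhs, c) not in triples:
                        triples.add((a, rhs, c))
                        changed = True
    return subs, triples


def random_ontology(
    rng: random.Random,
    max_extra_classes: int = 5,
    max_properties: int = 3,
    max_chains: int = 2,
    max_assertions: int = 8,
) -> Ontology:
    """A random small ontology: the seven roots plus a few classes, properties,
    binary chains, and existential assertions."""
    classes = [OntologyClass(r) for r in FUNDAMENTAL_ROOTS]
    ids = list(FUNDAMENTAL_ROOTS)
    for i in range(rng.randint(0, max_extra_classes)):
        n_parents = rng.randint(1, min(2, len(ids)))
        parents = tuple(rng.sample(ids, n_parents))
        # keep the single-fundamental-root invariant: all parents must sit
        # under the same root, so pick parents sharing a root
        root_of = {}
        tmp = Ontology(classes, validate=False)
        for pid in ids:
            try:
                root_of[pid] = tmp.fundamental_root(pid)
            except Exception:
                root_of[pid] = None
        first = parents[0]
        parents = tuple(p for p in parents if root_of.get(p) == root_of.get(first)) or (first,)
        cid = f"c{i}"
        classes.append(OntologyClass(cid, parents))
        ids.append(cid)
    props = []
    for i in range(rng.randint(1, max_properties)):
        props.append(
            ObjectProperty(
                f"p{i}",
                domain_id=rng.choice(ids),
                range_ids=tuple(rng.sample(ids, rng.randint(1, 2))),
            )
        )
    prop_ids = [p.id for p in props]
    chains = [
        PropertyChain(
            (rng.choice(prop_ids), rng.choice(prop_ids)), rng.choice(prop_ids)
        )
        for _ in range(rng.randint(0, max_chains))
    ]
    assertions = [
        Assertion(rng.choice(ids), rng.choice(prop_ids), rng.choice(ids))
        for _ in range(rng.randint(0, max_assertions))
    ]
    return Ontology(classes, props, chains, assertions)
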
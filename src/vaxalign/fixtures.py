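"""Curated mini ontology and seeded synthetic benchmark generation.

:func:`build_mini_ontology` returns a small, hand-curated vaccine ontology
(seven fundamental roots, a handful of pathogens/diseases with causal links,
strategies, routes, valences, abbreviation classes, and two products with
ingredient assertions) sufficient to exercise every pipeline stage.

:func:`generate_benchmark` builds, deterministically from a seed, a pair of
synthetic coding systems describing the same underlying vaccine groups in
different descriptor styles and languages, together with the programmatic
ontology that knows about those groups and the gold alignment.  It emulates
the heterogeneity real vaccine coding systems exhibit — multilingual
descriptors, pathogen-vs-disease naming, abbreviations, products, extra
strategy/route/valence qualifiers, and differing target granularity — with
small hand-written synthetic lexicons (no machine translation).
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from typing import Optional

from .coding import Code, CodingSystem
from .errors import ConfigurationError
from .evaluation import ReferenceAlignment
from .ontology import Assertion, ObjectProperty, Ontology, OntologyClass, PropertyChain

# ----------------------------------------------------------------------
# curated mini ontology
# ----------------------------------------------------------------------

_STANDARD_PROPERTIES = [
    ObjectProperty("immunizes-against", "vaccine", ("pathogen", "disease")),
    ObjectProperty("has-strategy", "vaccine", ("strategy",)),
    ObjectProperty("has-ingredient", "vaccine", ("ingredient",)),
    ObjectProperty("has-valence", "vaccine", ("valence",)),
    ObjectProperty("has-route", "vaccine", ("route",)),
    ObjectProperty("causes", "pathogen", ("disease",)),
    ObjectProperty("caused-by", "disease", ("pathogen",)),
]

#: Ingredient targets propagate to the containing vaccine; pathogens and
#: diseases in a causal relation are interchangeable immunization targets.
_STANDARD_CHAINS = [
    PropertyChain(("has-ingredient", "immunizes-against"), "immunizes-against"),
    PropertyChain(("has-ingredient", "has-strategy"), "has-strategy"),
    PropertyChain(("immunizes-against", "causes"), "immunizes-against"),
    PropertyChain(("immunizes-against", "caused-by"), "immunizes-against"),
]


def _roots() -> list[OntologyClass]:
    return [
        OntologyClass("vaccine", (), (("vaccine", "en"), ("vacuna", "es"), ("vaccino", "it"), ("vacuna", "ca"))),
        OntologyClass("valence", (), (("valence", "en"),)),
        OntologyClass("route", (), (("route", "en"),)),
        OntologyClass("ingredient", (), (("ingredient", "en"),)),
        OntologyClass("strategy", (), (("strategy", "en"),)),
        OntologyClass("disease", (), (("disease", "en"),)),
        OntologyClass("pathogen", (), (("pathogen", "en"),)),
    ]


def build_mini_ontology() -> Ontology:
    """The curated mini vaccine ontology used by fixtures and examples.

    Causal assertions are deliberately asymmetric: the flu and DTP disease
    families only declare pathogen→disease ``causes`` links (so abbreviation
    descriptors normalize to diseases only), while the HPV/cervical-cancer
    pair declares both directions (so pathogen- and disease-based phrasings
    are fully interchangeable).
    """
    classes = _roots() + [
        # pathogens
        OntologyClass("influenza-a-virus", ("pathogen",), (("influenza a virus", "en"),)),
        OntologyClass(
            "human-papillomavirus",
            ("pathogen",),
            (("human papillomavirus", "en"), ("hpv", "en"), ("virus del papiloma humano", "es")),
        ),
        OntologyClass(
            "mycobacterium-tuberculosis", ("pathogen",), (("mycobacterium tuberculosis", "en"),)
        ),
        OntologyClass("hepatitis-a-virus", ("pathogen",), (("hepatitis a virus", "en"),)),
        OntologyClass("bordetella-pertussis", ("pathogen",), (("bordetella pertussis", "en"),)),
        OntologyClass(
            "corynebacterium-diphtheriae", ("pathogen",), (("corynebacterium diphtheriae", "en"),)
        ),
        OntologyClass("clostridium-tetani", ("pathogen",), (("clostridium tetani", "en"),)),
        # diseases
        OntologyClass(
            "influenza",
            ("disease",),
            (("influenza", "en"), ("flu", "en"), ("gripe", "es"), ("influenza", "it"), ("grip", "ca")),
        ),
        OntologyClass(
            "cervical-cancer", ("disease",), (("cervical cancer", "en"), ("cancer cervical", "es"))
        ),
        OntologyClass(
            "tuberculosis",
            ("disease",),
            (("tuberculosis", "en"), ("tuberculosis", "es"), ("tubercolosi", "it")),
        ),
        OntologyClass(
            "hepatitis-a", ("disease",), (("hepatitis a", "en"), ("hepatitis a", "es"), ("epatite a", "it"))
        ),
        OntologyClass(
            "pertussis",
            ("disease",),
            (("pertussis", "en"), ("whooping cough", "en"), ("tos ferina", "es"), ("pertosse", "it")),
        ),
        OntologyClass(
            "diphtheria", ("disease",), (("diphtheria", "en"), ("difteria", "es"), ("difterite", "it"))
        ),
        OntologyClass(
            "tetanus", ("disease",), (("tetanus", "en"), ("tetanos", "es"), ("tetano", "it"))
        ),
        # strategies
        OntologyClass(
            "live-attenuated",
            ("strategy",),
            (
                ("live attenuated", "en"),
                ("attenuated", "en"),
                ("live", "en"),
                ("atenuada", "es"),
                ("attenuato", "it"),
            ),
        ),
        OntologyClass(
            "inactivated",
            ("strategy",),
            (("inactivated", "en"), ("inactivada", "es"), ("inattivato", "it")),
        ),
        OntologyClass("toxoid", ("strategy",), (("toxoid", "en"), ("toxoide", "es"))),
        OntologyClass(
            "conjugated", ("strategy",), (("conjugate", "en"), ("conjugated", "en"), ("conjugada", "es"))
        ),
        OntologyClass("subunit", ("strategy",), (("subunit", "en"), ("acellular", "en"))),
        # routes
        OntologyClass("oral-route", ("route",), (("oral", "en"), ("oral", "es"), ("orale", "it"))),
        OntologyClass(
            "intramuscular-route",
            ("route",),
            (("intramuscular", "en"), ("intramuscular", "es"), ("intramuscolare", "it")),
        ),
        # valences
        OntologyClass("valence-1", ("valence",), (("monovalent", "en"), ("1 valent", "en"))),
        OntologyClass("valence-2", ("valence",), (("bivalent", "en"), ("2 valent", "en"))),
        OntologyClass("valence-3", ("valence",), (("trivalent", "en"), ("3 valent", "en"))),
        OntologyClass(
            "valence-4", ("valence",), (("quadrivalent", "en"), ("tetravalent", "en"), ("4 valent", "en"))
        ),
        # ingredients
        OntologyClass("active-ingredient", ("ingredient",), (("active ingredient", "en"),)),
        OntologyClass("hepatitis-a-antigen", ("active-ingredient",), (("hepatitis a antigen", "en"),)),
        OntologyClass("influenza-antigen", ("active-ingredient",), (("influenza antigen", "en"),)),
        # pharmacological abbreviation classes and products (vaccines)
        OntologyClass("dtwp", ("vaccine",), (("dtwp", "en"), ("dtwp", "es"), ("dtwp", "it"))),
        OntologyClass("dtap", ("vaccine",), (("dtap", "en"), ("dtap", "es"), ("dtap", "it"))),
        OntologyClass("iiv3", ("vaccine",), (("iiv3", "en"), ("iiv3", "es"), ("iiv3", "it"))),
        OntologyClass("havrix", ("vaccine",), (("havrix", "en"),)),
        OntologyClass("influvac", ("vaccine",), (("influvac", "en"),)),
    ]
    assertions = [
        # causal links (pathogen -> disease); HPV also declares the reverse
        Assertion("influenza-a-virus", "causes", "influenza"),
        Assertion("human-papillomavirus", "causes", "cervical-cancer"),
        Assertion("cervical-cancer", "caused-by", "human-papillomavirus"),
        Assertion("mycobacterium-tuberculosis", "causes", "tuberculosis"),
        Assertion("hepatitis-a-virus", "causes", "hepatitis-a"),
        Assertion("bordetella-pertussis", "causes", "pertussis"),
        Assertion("corynebacterium-diphtheriae", "causes", "diphtheria"),
        Assertion("clostridium-tetani", "causes", "tetanus"),
        # abbreviation classes
        Assertion("dtwp", "immunizes-against", "diphtheria"),
        Assertion("dtwp", "immunizes-against", "tetanus"),
        Assertion("dtwp", "immunizes-against", "pertussis"),
        Assertion("dtwp", "has-strategy", "inactivated"),
        Assertion("dtap", "immunizes-against", "diphtheria"),
        Assertion("dtap", "immunizes-against", "tetanus"),
        Assertion("dtap", "immunizes-against", "pertussis"),
        Assertion("dtap", "has-strategy", "subunit"),
        Assertion("iiv3", "immunizes-against", "influenza"),
        Assertion("iiv3", "has-strategy", "inactivated"),
        Assertion("iiv3", "has-valence", "valence-3"),
        # products and their active ingredients
        Assertion("havrix", "has-ingredient", "hepatitis-a-antigen"),
        Assertion("havrix", "has-route", "intramuscular-route"),
        Assertion("influvac", "has-ingredient", "influenza-antigen"),
        Assertion("hepatitis-a-antigen", "immunizes-against", "hepatitis-a"),
        Assertion("hepatitis-a-antigen", "has-strategy", "inactivated"),
        Assertion("influenza-antigen", "immunizes-against", "influenza"),
        Assertion("influenza-antigen", "has-strategy", "inactivated"),
    ]
    return Ontology(classes, _STANDARD_PROPERTIES, _STANDARD_CHAINS, assertions)


# ----------------------------------------------------------------------
# synthetic benchmark generation
# ----------------------------------------------------------------------

STYLES = (
    "pathogen-name",
    "disease-name",
    "abbreviation",
    "product-name",
    "with-strategy",
    "with-route",
    "with-valence",
)

LANGUAGES = ("en", "es", "it", "ca")

#: Hand-written synthetic lexicons for the shared qualifier classes.
_VACCINE_WORD = {"en": "vaccine", "es": "vacuna", "it": "vaccino", "ca": "vacuna"}
_STRATEGY_TERMS = {
    "strat-attenuated": {"en": "attenuated", "es": "atenuada", "it": "attenuato", "ca": "atenuada"},
    "strat-inactivated": {"en": "inactivated", "es": "inactivada", "it": "inattivato", "ca": "inactivada"},
    "strat-conjugated": {"en": "conjugate", "es": "conjugada", "it": "coniugato", "ca": "conjugada"},
    "strat-subunit": {"en": "subunit", "es": "subunidad", "it": "subunita", "ca": "subunitat"},
    "strat-toxoid": {"en": "toxoid", "es": "toxoide", "it": "tossoide", "ca": "toxoide"},
}
_ROUTE_TERMS = {
    "route-oral": {"en": "oral", "es": "oral", "it": "orale", "ca": "oral"},
    "route-intramuscular": {
        "en": "intramuscular", "es": "intramuscular", "it": "intramuscolare", "ca": "intramuscular",
    },
}
_VALENCE_TERMS = {
    "valence-1": {"en": "monovalent", "es": "monovalente", "it": "monovalente", "ca": "monovalent"},
    "valence-2": {"en": "bivalent", "es": "bivalente", "it": "bivalente", "ca": "bivalent"},
    "valence-3": {"en": "trivalent", "es": "trivalente", "it": "trivalente", "ca": "trivalent"},
    "valence-4": {"en": "quadrivalent", "es": "tetravalente", "it": "quadrivalente", "ca": "quadrivalent"},
}

_SYLLABLES = [
    c + v
    for c in ("b", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z")
    for v in ("a", "e", "i", "o", "u")
]


@dataclass(frozen=True)
class NoiseSpec:
    """Independent corruption probabilities applied to rendered descriptors."""

    dropout: float = 0.0  # per-token removal probability
    distractor: float = 0.0  # probability of inserting an out-of-dictionary token
    synonym: float = 0.0  # probability of replacing the key term by an unknown synonym

    def __post_init__(self) -> None:
        for name in ("dropout", "distractor", "synonym"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"noise probability {name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class BenchmarkSpec:
    """Conditions a synthetic coding-system pair is generated under.

    The defaults describe the canonical hard case: the same vaccine groups
    named by disease plus strategy in Spanish on the source side, and by
    disease plus valence in English on the target side.
    """

    n_groups: int = 20
    style_source: str = "with-strategy"
    style_target: str = "with-valence"
    language_source: str = "es"
    language_target: str = "en"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hierarchy_target: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        for style in (self.style_source, self.style_target):
            if style not in STYLES:
                raise ConfigurationError(f"unknown descriptor style {style!r}; one of {STYLES}")
        for lang in (self.language_source, self.language_target):
            if lang not in LANGUAGES:
                raise ConfigurationError(f"unknown language {lang!r}; one of {LANGUAGES}")


@dataclass
class Benchmark:
    """A generated ontology, coding-system pair, and gold alignment."""

    ontology: Ontology
    source: CodingSystem
    target: CodingSystem
    gold: ReferenceAlignment
    spec: BenchmarkSpec


class _WordFactory:
    """Seeded pseudoword source with global uniqueness."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        reserved = set(_VACCINE_WORD.values())
        for table in (_STRATEGY_TERMS, _ROUTE_TERMS, _VALENCE_TERMS):
            for terms in table.values():
                reserved.update(terms.values())
        self.used: set[str] = reserved

    def word(self, n_syllables: int = 3) -> str:
        while True:
            w = "".join(self.rng.choice(_SYLLABLES) for _ in range(n_syllables))
            if w not in self.used:
                self.used.add(w)
                return w

    def abbreviation(self) -> str:
        while True:
            w = "".join(self.rng.choice(string.ascii_uppercase) for _ in range(4))
            if w.lower() not in self.used:
                self.used.add(w.lower())
                return w


@dataclass
class _Group:
    index: int
    pathogen_terms: dict[str, str]  # language -> term
    disease_terms: dict[str, str]
    abbreviation: str
    product: str
    strategy: str
    route: str
    valence: str


def _build_benchmark_ontology(groups: list[_Group]) -> Ontology:
    classes = _roots() + [
        OntologyClass("active-ingredient", ("ingredient",), (("active ingredient", "en"),))
    ]
    assertions: list[Assertion] = []
    for cid, terms in _STRATEGY_TERMS.items():
        classes.append(
            OntologyClass(cid, ("strategy",), tuple((t, l) for l, t in sorted(terms.items())))
        )
    for cid, terms in _ROUTE_TERMS.items():
        classes.append(
            OntologyClass(cid, ("route",), tuple((t, l) for l, t in sorted(terms.items())))
        )
    for cid, terms in _VALENCE_TERMS.items():
        classes.append(
            OntologyClass(cid, ("valence",), tuple((t, l) for l, t in sorted(terms.items())))
        )
    for g in groups:
        i = g.index
        pg, ds = f"pg-{i:03d}", f"ds-{i:03d}"
        ab, pr, ing = f"ab-{i:03d}", f"pr-{i:03d}", f"ing-{i:03d}"
        classes.append(
            OntologyClass(pg, ("pathogen",), tuple((t, l) for l, t in sorted(g.pathogen_terms.items())))
        )
        classes.append(
            OntologyClass(ds, ("disease",), tuple((t, l) for l, t in sorted(g.disease_terms.items())))
        )
        classes.append(
            OntologyClass(ab, ("vaccine",), tuple((g.abbreviation.lower(), l) for l in LANGUAGES))
        )
        classes.append(OntologyClass(pr, ("vaccine",), tuple((g.product, l) for l in LANGUAGES)))
        classes.append(OntologyClass(ing, ("active-ingredient",), ()))
        # both causal directions: pathogen- and disease-style names interchange
        assertions.append(Assertion(pg, "causes", ds))
        assertions.append(Assertion(ds, "caused-by", pg))
        assertions.append(Assertion(ab, "immunizes-against", ds))
        assertions.append(Assertion(ab, "has-strategy", g.strategy))
        assertions.append(Assertion(pr, "has-ingredient", ing))
        assertions.append(Assertion(ing, "immunizes-against", ds))
        assertions.append(Assertion(ing, "has-strategy", g.strategy))
    return Ontology(classes, _STANDARD_PROPERTIES, _STANDARD_CHAINS, assertions)


def _render(group: _Group, style: str, lang: str) -> tuple[list[str], str]:
    """Render a descriptor as tokens; returns (tokens, key-term token)."""
    vword = _VACCINE_WORD[lang]
    disease = group.disease_terms[lang]
    pathogen = group.pathogen_terms[lang]

    def phrase(term: str, qualifier: Optional[str] = None) -> list[str]:
        base = [term, vword] if lang == "en" else [vword, term]
        if qualifier:
            base.append(qualifier)
        return base

    if style == "pathogen-name":
        return phrase(pathogen), pathogen
    if style == "disease-name":
        return phrase(disease), disease
    if style == "abbreviation":
        return [group.abbreviation], group.abbreviation
    if style == "product-name":
        return [group.product], group.product
    if style == "with-strategy":
        return phrase(disease, _STRATEGY_TERMS[group.strategy][lang]), disease
    if style == "with-route":
        return phrase(disease, _ROUTE_TERMS[group.route][lang]), disease
    if style == "with-valence":
        return phrase(disease, _VALENCE_TERMS[group.valence][lang]), disease
    raise ConfigurationError(f"style {style!r} is not renderable")


def _apply_noise(
    tokens: list[str], key: str, noise: NoiseSpec, rng: random.Random, words: _WordFactory
) -> list[str]:
    out = list(tokens)
    if noise.synonym and rng.random() < noise.synonym:
        out = [words.word() if t == key else t for t in out]
    if noise.dropout:
        kept = [t for t in out if rng.random() >= noise.dropout]
        out = kept if kept else [rng.choice(out)]
    if noise.distractor and rng.random() < noise.distractor:
        out.insert(rng.randrange(len(out) + 1), words.word())
    return out


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Deterministically generate a benchmark from its specification."""
    rng = random.Random(spec.seed)
    words = _WordFactory(rng)
    strategies = sorted(_STRATEGY_TERMS)
    routes = sorted(_ROUTE_TERMS)
    valences = sorted(_VALENCE_TERMS)
    groups = [
        _Group(
            index=i,
            pathogen_terms={l: words.word() for l in LANGUAGES},
            disease_terms={l: words.word() for l in LANGUAGES},
            abbreviation=words.abbreviation(),
            product=words.word(4),
            strategy=strategies[i % len(strategies)],
            route=routes[i % len(routes)],
            valence=valences[i % len(valences)],
        )
        for i in range(spec.n_groups)
    ]
    ontology = _build_benchmark_ontology(groups)

    source_codes: list[Code] = []
    target_codes: list[Code] = []
    gold_pairs: list[tuple[str, str]] = []
    for g in groups:
        s_tokens, s_key = _render(g, spec.style_source, spec.language_source)
        s_tokens = _apply_noise(s_tokens, s_key, spec.noise, rng, words)
        s_id = f"S{g.index:03d}"
        source_codes.append(
            Code(code=s_id, descriptor=" ".join(s_tokens), language=spec.language_source)
        )
        t_tokens, t_key = _render(g, spec.style_target, spec.language_target)
        t_tokens = _apply_noise(t_tokens, t_key, spec.noise, rng, words)
        t_id = f"T{g.index:03d}"
        if spec.hierarchy_target:
            # a general parent code (plain disease name) over the specific child
            parent_tokens, _ = _render(g, "disease-name", spec.language_target)
            parent_id = f"T{g.index:03d}-gen"
            target_codes.append(
                Code(
                    code=parent_id,
                    descriptor=" ".join(parent_tokens),
                    language=spec.language_target,
                )
            )
            target_codes.append(
                Code(
                    code=t_id,
                    descriptor=" ".join(t_tokens),
                    language=spec.language_target,
                    parent=parent_id,
                )
            )
        else:
            target_codes.append(
                Code(code=t_id, descriptor=" ".join(t_tokens), language=spec.language_target)
            )
        # gold maps each source code to the most specific representable target
        gold_pairs.append((s_id, t_id))

    return Benchmark(
        ontology=ontology,
        source=CodingSystem(f"synthetic-source-{spec.seed}", source_codes),
        target=CodingSystem(f"synthetic-target-{spec.seed}", target_codes),
        gold=ReferenceAlignment(frozenset(gold_pairs)),
        spec=spec,
    )
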
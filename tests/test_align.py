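"""Alignment assignment logic: thresholds, ties, hierarchy, registry."""

import pytest

from vaxalign import (
    Alignment,
    Code,
    CodingSystem,
    align,
    available_methods,
    read_alignment,
    register_external_method,
    similarity_matrix,
    write_alignment,
)
from vaxalign.errors import ConfigurationError
from vaxalign.fixtures import BenchmarkSpec, NoiseSpec, generate_benchmark


@pytest.fixture(scope="module")
def benchmark():
    return generate_benchmark(BenchmarkSpec(n_groups=10, seed=11))


def test_below_threshold_is_unassigned(mini_onto):
    source = CodingSystem("s", [Code("s1", "flu vaccine")])
    target = CodingSystem("t", [Code("t1", "tetanus vaccine")])
    result = align(source, target, method="tokens", threshold=0.5)
    assert result.unassigned == {"s1"}
    assert result.assignments == ()


def test_strict_threshold_comparison(mini_onto):
    # a score exactly equal to the threshold must NOT be assigned
    source = CodingSystem("s", [Code("s1", "a b")])
    target = CodingSystem("t", [Code("t1", "a c")])  # Jaccard 1/3
    exact = align(source, target, method="tokens", threshold=1 / 3)
    assert exact.unassigned == {"s1"}
    below = align(source, target, method="tokens", threshold=0.33)
    assert below.pairs() == {("s1", "t1")}


def test_tie_without_hierarchy_keeps_all(mini_onto):
    source = CodingSystem("s", [Code("s1", "influenza vaccine")])
    target = CodingSystem(
        "t", [Code("t1", "influenza inactivated"), Code("t2", "influenza oral")]
    )
    result = align(source, target, method="tokens", threshold=0.1)
    assert result.pairs() == {("s1", "t1"), ("s1", "t2")}


def test_tie_with_hierarchy_keeps_most_general(mini_onto):
    # parent and child tie at the same score: only the parent is assigned
    source = CodingSystem("s", [Code("s1", "influenza vaccine")])
    target = CodingSystem(
        "t",
        [
            Code("parent", "influenza inactivated"),
            Code("child", "influenza oral", parent="parent"),
        ],
    )
    result = align(source, target, method="tokens", threshold=0.1)
    assert result.pairs() == {("s1", "parent")}


def test_empty_target_system_warns_and_unassigns(caplog):
    source = CodingSystem("s", [Code("s1", "flu")])
    target = CodingSystem("t", [])
    with caplog.at_level("WARNING"):
        result = align(source, target, method="tokens", threshold=0.1)
    assert result.unassigned == {"s1"}
    assert any("empty target" in rec.message for rec in caplog.records)


def test_unknown_method_raises_configuration_error(mini_onto):
    source = CodingSystem("s", [Code("s1", "flu")])
    with pytest.raises(ConfigurationError, match="unknown similarity method"):
        align(source, source, method="nosuchmethod", ontology=mini_onto)


def test_invalid_threshold_rejected():
    source = CodingSystem("s", [Code("s1", "flu")])
    with pytest.raises(ConfigurationError, match="threshold"):
        align(source, source, method="tokens", threshold=1.5)


def test_reflexive_alignment_is_identity(benchmark):
    for method in ("tokens", "classes", "equivalence", "properties"):
        result = align(
            benchmark.source, benchmark.source, method=method, threshold=0.1,
            ontology=benchmark.ontology,
        )
        expected = {(c.code, c.code) for c in benchmark.source}
        assert result.pairs() == expected, method
        assert not result.unassigned


def test_threshold_monotonicity(benchmark):
    matrix = similarity_matrix(
        benchmark.source, benchmark.target, "properties", ontology=benchmark.ontology
    )
    from vaxalign import assignment_from_matrix

    previous = None
    for theta in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
        pairs = assignment_from_matrix(
            matrix, benchmark.source, benchmark.target, "properties", theta
        ).pairs()
        if previous is not None:
            assert pairs <= previous
        previous = pairs


def test_alignment_scores_are_maximal_and_above_threshold(benchmark):
    result = align(
        benchmark.source, benchmark.target, method="classes", threshold=0.1,
        ontology=benchmark.ontology,
    )
    matrix = similarity_matrix(
        benchmark.source, benchmark.target, "classes", ontology=benchmark.ontology
    )
    for s, t, score in result.assignments:
        assert score > 0.1
        assert score == pytest.approx(matrix.loc[s].max())


def test_external_method_registry(mini_onto):
    register_external_method("firstletter", lambda text: {text[:1].lower()} if text else set())
    assert "firstletter" in available_methods()
    source = CodingSystem("s", [Code("s1", "apple")])
    target = CodingSystem("t", [Code("t1", "apricot"), Code("t2", "banana")])
    result = align(source, target, method="firstletter", threshold=0.1)
    assert result.pairs() == {("s1", "t1")}
    with pytest.raises(ConfigurationError):
        register_external_method("tokens", lambda text: set())


def test_alignment_tsv_round_trip(tmp_path, benchmark):
    result = align(
        benchmark.source, benchmark.target, method="properties", threshold=0.1,
        ontology=benchmark.ontology,
    )
    path = tmp_path / "alignment.tsv"
    write_alignment(result, path)
    loaded = read_alignment(path)
    assert loaded.pairs() == result.pairs()
    assert loaded.unassigned == result.unassigned
    assert loaded.method == "properties"
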
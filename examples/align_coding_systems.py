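"""Align two synthetic vaccine coding systems and compare similarity methods.

The benchmark generator produces two coding systems that describe the same 20
vaccine groups: the source names each group by disease plus strategy in
Spanish, the target by disease plus valence in English.  The gold alignment
is known by construction, so each method's precision/recall/F can be
measured.  The ontology-normalized property-value method recovers the gold
alignment exactly; the lexical baseline cannot cross the language gap.
"""

from vaxalign import align, evaluate
from vaxalign.fixtures import BenchmarkSpec, NoiseSpec, generate_benchmark

benchmark = generate_benchmark(BenchmarkSpec(n_groups=20, seed=42))

print("example source descriptors:", [c.descriptor for c in list(benchmark.source)[:3]])
print("example target descriptors:", [c.descriptor for c in list(benchmark.target)[:3]])
print()
print(f"{'method':<12} {'precision':>9} {'recall':>7} {'F':>6}")
for method in ("tokens", "classes", "equivalence", "properties"):
    result = align(
        benchmark.source, benchmark.target, method=method, threshold=0.1,
        ontology=benchmark.ontology,
    )
    r = evaluate(result, benchmark.gold)
    print(f"{method:<12} {r.precision:>9.3f} {r.recall:>7.3f} {r.f_score:>6.3f}")

print()
print(
    "With 20% token dropout the ranking persists directionally\n"
    "(properties >= classes >= tokens):"
)
noisy = generate_benchmark(BenchmarkSpec(n_groups=20, seed=42, noise=NoiseSpec(dropout=0.2)))
for method in ("tokens", "classes", "properties"):
    result = align(
        noisy.source, noisy.target, method=method, threshold=0.1, ontology=noisy.ontology
    )
    print(f"{method:<12} F = {evaluate(result, noisy.gold).f_score:.3f}")
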
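"""Write a benchmark to disk in the formats the command-line tools consume.

Produces an ontology YAML file, two coding-system TSV tables, and a gold
reference TSV under ./benchmark-out, then shows the equivalent CLI calls.
"""

from pathlib import Path

from vaxalign import save_ontology, write_coding_system, write_reference
from vaxalign.fixtures import BenchmarkSpec, generate_benchmark

out = Path("benchmark-out")
out.mkdir(exist_ok=True)

benchmark = generate_benchmark(BenchmarkSpec(n_groups=10, seed=0, hierarchy_target=True))
save_ontology(benchmark.ontology, out / "ontology.yaml")
write_coding_system(benchmark.source, out / "source.tsv")
write_coding_system(benchmark.target, out / "target.tsv")
write_reference(benchmark.gold, out / "gold.tsv")

print(f"wrote {out}/ontology.yaml, source.tsv, target.tsv, gold.tsv")
print("(the target system carries a two-level hierarchy; gold maps to the children)")
print()
print("equivalent shell workflow:")
print(f"  vaxalign align {out}/source.tsv {out}/target.tsv \\")
print(f"      --ontology {out}/ontology.yaml --method properties --out {out}/alignment.tsv")
print(f"  vaxalign evaluate {out}/alignment.tsv {out}/gold.tsv")
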
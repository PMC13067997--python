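"""How faithful are run colors to the true origins of each match?

For every query position with PML L, the documents supported by all colors
tallied during the match are compared (Jaccard) with the brute-force set
of documents containing that exact match.  Fidelity rises with L: long
matches live in runs whose colors pin down the source documents.
"""

import dataclasses

from colormove import (
    QueryEngine,
    RepositionStrategy,
    SimulationConfig,
    build_index,
    color_fidelity,
    simulate_pangenome,
    simulate_reads,
)

config = SimulationConfig(
    seed=4,
    num_species=6,
    genomes_per_species=4,
    genome_length=6_000,
    read_length_mean=1_000.0,
    document_level="species",
)
sim = simulate_pangenome(config)
index = build_index(sim.collection, keep_suffix_structures=True)
engine = QueryEngine(index, RepositionStrategy.LCP_THRESHOLDS)

error_free = dataclasses.replace(config, error_substitution=0.0)
reads = simulate_reads(sim.held_out, error_free, 40, seed_stream=20)
summary = color_fidelity(engine, [r.sequence for r in reads], min_length=16)

print(f"positions with PML >= 16: {summary['positions']}")
print(f"mean Jaccard, score-supported sets: {summary['mean_supported']:.4f}")
print(f"mean Jaccard, single run colors:    {summary['mean_color']:.4f}")
print()
print("PML   mean Jaccard (score-supported)")
shown = 0
for length, j in summary["by_length"].items():
    if shown < 8 or length % 50 == 0:
        print(f"{length:4d}  {j:.3f}")
    shown += 1
print("The supported set intersects colors across the whole match, washing")
print("out documents that only share part of it; fidelity approaches 1 for")
print("long matches.")
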
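"""Identify the most reliable narcosis model for a query chemical.

Reruns the two printed worked neighbourhoods: the first resolves to the
non-polar narcosis (NPN) model, the second to the polar narcosis (PN)
model, by averaging each model's errors over the Pareto neighbours.
"""

from paretomi import NeighbourhoodParams, identify, table3_fixture, table4_fixture

for fixture in (table3_fixture, table4_fixture):
    table, query, expected = fixture()
    result = identify(table, query, method="APMI",
                      params=NeighbourhoodParams(n=3, tau=0.4))
    print(f"query: {query.id}")
    print("  Pareto neighbourhood (distance, error, model):")
    for p in result.neighbourhood.points:
        print(f"    {p.compound_id}: d={p.d:.2f} e={p.e:.3f} [{p.model_id}]")
    for model, avg in result.per_model_scores.items():
        print(f"  mean {model} error over neighbours: {avg:.4f}")
    print(f"  selected: {result.selected_model} (expected {expected})\n")
# the smaller mean error wins: NPN for the first query, PN for the second
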
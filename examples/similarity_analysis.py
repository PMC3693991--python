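"""Pairwise similarity-vs-activity analysis of a chemical dataset.

Counts, for each (distance threshold, activity-difference threshold) cell,
how many chemical pairs are at most that structurally distant AND at most
that different in measured activity.  Few pairs in the top-left corner
means structural similarity alone is a weak predictor of similar activity —
the reason model identification needs the error criterion too.
"""

from paretomi import SyntheticConfig, generate_dataset, similarity_activity_table

table, _ = generate_dataset(SyntheticConfig(n_chemicals=120, seed=42))
counts = similarity_activity_table(
    table.chemicals,
    sim_thresholds=[0.1, 0.2, 0.4, 0.7, 1.0],
    act_thresholds=[0.1, 0.5, 1.0, 2.0, 10.0],
)
print("rows: Tanimoto distance threshold; columns: |activity difference| threshold")
print(counts.to_string())
total = counts.iloc[-1, -1]
print(f"total pairs: {total} (= C({len(table.chemicals)},2))")
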
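"""Compute the 2D Pareto front of a small (distance, error) point set.

Each point is one (chemical, model) candidate: how far the chemical is from
the query and how wrong the model was on it.  The front keeps every
candidate no other candidate beats on both criteria at once.
"""

from paretomi import (
    TaggedPoint,
    Vector2D,
    brute_force_pareto,
    find_pareto_set,
)

points = [
    TaggedPoint(Vector2D(d, e), cid, mid)
    for cid, mid, d, e in [
        ("chem1", "M1", 0.10, 0.50),
        ("chem1", "M2", 0.10, 0.90),
        ("chem2", "M1", 0.20, 0.30),
        ("chem2", "M2", 0.20, 0.60),
        ("chem3", "M1", 0.40, 0.70),
        ("chem3", "M2", 0.40, 0.10),
    ]
]

front = find_pareto_set(points)
print("Pareto front (no candidate is both closer and better-predicted):")
for p in sorted(front.points, key=lambda p: p.d):
    print(f"  {p.compound_id}/{p.model_id}: distance={p.d:.2f} error={p.e:.2f}")
print(f"initial set size: {len(front.initial)} (at most 2 distinct points in 2D)")
print(f"bounds rectangle: d in [{front.bounds.f1_min}, {front.bounds.f1_max}], "
      f"e in [{front.bounds.f2_min}, {front.bounds.f2_max}]")
assert front.points == brute_force_pareto(points)  # matches the O(n^2) definition
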
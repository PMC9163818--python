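"""Ordinate the animals and score the diet-group separation.

Embeds the 12 animals by classical MDS of 1 - Spearman correlation
between their bin-abundance profiles, then quantifies how far the Extreme
group sits from the Standard group with the separation score
(inter-centroid distance over accumulated member-to-centroid distances).
"""

from cazlink import PointCluster, correlation_distance, embed_2d, separation_score
from cazlink.simulate import SimulationConfig, simulate

study = simulate(SimulationConfig(seed=42, n_bins=200))
distances = correlation_distance(study.abundance, method="spearman")
embedding = embed_2d(distances)
print("2-D embedding (arbitrary units):")
print(embedding.coordinates.round(3))
print(f"explained inertia: {embedding.explained[0]:.0%} / "
      f"{embedding.explained[1]:.0%}")

clusters = {
    group: PointCluster(group, embedding.points(
        [s for s in study.abundance.columns if s.startswith(group)]
    ))
    for group in ("Standard", "High", "Extreme")
}
for contrast in ("High", "Extreme"):
    score = separation_score(clusters["Standard"], clusters[contrast], "sum")
    print(f"separation Standard vs {contrast}: {score:.2f}")

# The Extreme animals separate far more strongly from Standard than the
# High animals do, mirroring the planted community shift.
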
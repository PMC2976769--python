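"""Cluster structures from a similarity matrix and test node reliability.

Generates a planted three-family similarity matrix (Dali-style Z-scores),
converts it to distances, builds the UPGMA tree and runs the
leave-one-out jackknife. A reliable node is one whose clade reappears in
every leave-one-structure-out replicate tree.
"""

from ghmotif import (
    ClusterSpec,
    family_distances,
    generate_similarity_matrix,
    jackknife_reliability,
    similarity_to_distance,
)

sim, families = generate_similarity_matrix(ClusterSpec(seed=1))
tree, report = jackknife_reliability(sim)

print(f"{sim.n} structures in {len(set(families.values()))} planted families")
print(f"reliable internal nodes: {report.n_reliable}/{len(report.absent_in)}")

dist = similarity_to_distance(sim)
within, between = family_distances(dist, families)
print("\nmean within-family distance <Dij>:")
print(within.round(2).to_string())
print("\nmean between-family distances:")
print(between.round(1).to_string())
print("\nSmall within-family and large between-family distances mean the")
print("tree separates the families cleanly. Nodes flagged unreliable are")
print("groupings that vanish when some single structure is left out; with")
print("measurement noise a few shallow within-family nodes are expected to")
print("be unstable, exactly as seen in real structure sets.")
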
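"""Disease semantic similarity from a small term hierarchy.

Two lymphoma subtypes share the deep ancestor "lymphoma", while the
colon neoplasm only meets them at the generic "neoplasms" root — the
decayed shared-ancestor score makes the first pair far more similar.
"""

from snfimc import DiseaseDAG, contribution_scores, semantic_similarity_matrix, semantic_value

dag = DiseaseDAG(
    terms=["neoplasms", "lymphoma", "hodgkin", "non_hodgkin", "colon_neoplasm"],
    parent_edges=[
        ("lymphoma", "neoplasms"),
        ("hodgkin", "lymphoma"),
        ("non_hodgkin", "lymphoma"),
        ("colon_neoplasm", "neoplasms"),
    ],
)

print("contribution scores for 'hodgkin' (decay 0.5):")
for term, dd in sorted(contribution_scores(dag, "hodgkin", 0.5).items()):
    print(f"  DD({term}) = {dd}")
print(f"semantic value DV(hodgkin) = {semantic_value(dag, 'hodgkin', 0.5)}")

diseases = ["hodgkin", "non_hodgkin", "colon_neoplasm"]
sim = semantic_similarity_matrix(dag, diseases, delta=0.5)
print("\npairwise semantic similarity:")
for i, d1 in enumerate(diseases):
    for d2 in diseases[i + 1:]:
        j = diseases.index(d2)
        print(f"  DS({d1}, {d2}) = {sim.values[i, j]:.4f}")
print("\nsiblings under 'lymphoma' score much higher than either does "
      "against the colon neoplasm, which shares only the root.")
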
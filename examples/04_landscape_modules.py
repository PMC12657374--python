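"""Combination landscape, Louvain modules and ADMET filtering.

Scores all ingredient-ingredient and ingredient-disease pairs of a
synthetic scenario into one landscape, keeps the significant edges, runs
Louvain community detection, extracts the disease module, and filters the
module members on ADMET criteria.
"""

from herbprox import (
    DistanceEngine,
    FilterSpec,
    admet_filter,
    build_combination_graph,
    build_disease_landscape,
    detect_modules,
    disease_module_members,
    generate_admet_table,
    generate_scenario,
    sample_null,
)

catalog, graph, truth = generate_scenario()
eng = DistanceEngine(graph)
ings = sorted(catalog.ingredient_ids)

ii_null = sample_null([(a, b) for i, a in enumerate(ings) for b in ings[i + 1:]],
                      "ingredient_ingredient", catalog, eng, n=1000, seed=11)
id_null = sample_null([(i, truth.disease_id) for i in ings],
                      "ingredient_disease", catalog, eng, n=1000, seed=12)

landscape = build_disease_landscape(truth.disease_id, ings, catalog, eng,
                                    ii_null, id_null)
n_sig = sum(e.significant for e in landscape.edges)
print(f"landscape: {len(landscape.nodes)} nodes, {len(landscape.edges)} edges, "
      f"{n_sig} significant")

g = build_combination_graph(landscape, significant_only=True)
labels = detect_modules(g, seed=0)
members = disease_module_members(labels, truth.disease_id)
hit = len(set(members) & set(truth.planted))
print(f"disease module: {len(members)} ingredients, {hit} of them planted —")
print("ingredients sharing the disease node's community are the synergy candidates.")

admet = generate_admet_table(members, seed=5)
spec = FilterSpec.parse("HIA eq +\nOB ge 30\nhepatotoxicity eq -")
survivors = admet_filter(admet, spec, members)
print(f"\nADMET filter (good absorption, OB>=30%, non-hepatotoxic): "
      f"{len(survivors)}/{len(members)} survive:")
print(" ", ", ".join(survivors))
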
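"""Proximity metrics on a toy path interactome.

Builds the 5-protein path network v1-v2-v3-v4-v5 and computes the four
proximity metrics between small target sets, printing each with the hand
computation it reduces to.
"""

from herbprox import (
    TargetSet,
    closest_distance,
    disease_proximity,
    load_interactome,
    shortest_distance,
)

graph = load_interactome([("v1", "v2"), ("v2", "v3"), ("v3", "v4"), ("v4", "v5")])

a = TargetSet("ingA", "ingredient", frozenset({"v1", "v2"}))
b = TargetSet("ingB", "ingredient", frozenset({"v4", "v5"}))
disease = TargetSet("disease", "disease", frozenset({"v4", "v5"}))

print("closest d^C(A,B)  =", closest_distance(a, b, graph).value)
print("  each target's min distance to the other set: v1->3, v2->2, v4->2, v5->3;")
print("  (3+2+2+3)/4 = 2.5 hops — the ingredient-ingredient synergy score")

print("shortest d^S(A,B) =", shortest_distance(a, b, graph).value)
print("  mean over all 4 cross pairs: (3+4+2+3)/4 = 3.0 hops")

x = TargetSet("ingC", "ingredient", frozenset({"v1"}))
print("disease proximity d(X,Y) =", disease_proximity(x, disease, graph).value)
print("  per disease gene, distance to nearest drug target: (3+4)/2 = 3.5 hops;")
print("  directed: swapping the roles gives a different value")
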
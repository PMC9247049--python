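"""The five neighborhood-overlap similarity indices on one node pair.

On a triangle with a pendant edge, nodes 1 and 2 share one common neighbor
but have different degrees, which separates the five indices; the game's
utility weights each neighbor by (1 + sim).
"""

from gamecover import Graph, similarity

graph = Graph([(1, 2), (1, 3), (2, 3), (2, 4)])
print("pair (1, 2): neighborhoods", sorted(graph.neighbors(1)),
      "and", sorted(graph.neighbors(2)))
for metric in ("JC", "SI", "SO", "HP", "HD"):
    print(f"  {metric}: {similarity(graph, 1, 2, metric):.4f}")
# JC <= HD <= SO <= SI <= HP always holds when the intersection is
# nonempty; HP (the default) divides by the smaller degree, so hubs do not
# dilute the score of their low-degree neighbors.
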
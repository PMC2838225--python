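"""Size functions of a small vertex-filtered graph, and the matching
distance between two diagrams.

Builds a path graph whose values dip and rise, computes its cornerpoint
diagram, evaluates the size function at a point, and compares two
diagrams with the matching distance.
"""

from lesionsf import (
    SizeGraph,
    compute_size_function,
    evaluate_sf,
    matching_distance,
)

# A path a-b-c-d whose values go 1, 3, 2, 4: the dip at c births a
# second component at level 2 that dies at level 3.
g = SizeGraph(
    vertices=["a", "b", "c", "d"],
    edges={("a", "b"), ("b", "c"), ("c", "d")},
    phi={"a": 1, "b": 3, "c": 2, "d": 4},
)
diagram = compute_size_function(g)
print("proper cornerpoints:", diagram.proper)        # [(2, 3)]
print("cornerlines:", diagram.cornerlines)           # [1]

# ell(2.5, 2.5): both components of {phi <= 2.5} are already touched.
print("ell(2.5, 2.5) =", evaluate_sf(diagram, 2.5, 2.5))  # 2

# Perturb one value and measure how far the size function moved; by the
# stability theorem this can be at most the perturbation (0.4).
g2 = SizeGraph(
    vertices=list(g.vertices), edges=set(g.edges),
    phi={"a": 1, "b": 3, "c": 2.4, "d": 4},
)
d = matching_distance(diagram, compute_size_function(g2))
print("matching distance after 0.4 perturbation:", d)  # 0.4
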
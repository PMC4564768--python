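"""Score flower opening and corolla asymmetry for a simulated population.

Opening = diameter of the circle fitted to the five midrib distal points
over the diameter of the circle fitted to the five lobe intersections.
Asymmetry = sin(theta), theta the angle between the tube's first principal
axis and the normal of the tube-opening circle.  Both are similarity
invariants: size, position and pose of the flower do not matter.
"""

from floramorph import make_population, trait_table

population = make_population(10, seed=15)
table = trait_table([gt.landmarks for _, gt in population])

print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# The last three rows summarise the population: mean, standard deviation
# and the correlation between the two traits (near zero: independent draws).
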
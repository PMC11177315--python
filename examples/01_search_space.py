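"""Build the default reaction-condition search space and encode a condition.

The space mixes three Boolean switches, four numeric grids (signed acid/base
axis, methylhydrazine equivalents, temperature, solvent volume) and a choice
among 200 descriptor-parametrized solvents.
"""

from upbo import acid_base_axis, default_space

space = default_space(seed=0)
print(f"variables: {[v.name for v in space.variables]}")
print(f"cardinality: {space.cardinality:,} candidate conditions")

cond = space.unrank(1_234_567)
print(f"condition #1,234,567: {cond.as_dict()}")

x = space.encode(cond)
print(f"encoded feature vector ({len(x)} features, solvent -> 4 descriptors):")
print("  ", [round(float(v), 3) for v in x])

print("signed acid/base axis: 5 equiv AcOH ->", acid_base_axis(5, 0),
      "; 5 equiv NaOH ->", acid_base_axis(0, 5))
# The encoded vector is what every surrogate model sees; raw lab values
# stay on the condition so proposals are always executable grid points.
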
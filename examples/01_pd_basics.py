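"""PD, PD loss, and phylogenetic tipping points on a five-species tree.

Faith's phylogenetic diversity (PD) of a species set is the total branch
length connecting those species to the root of the tree.  Losing a species
costs only its unshared branches — until the last member of a clade goes,
at which point the clade's deep stem branch is lost too (a tipping point).
"""

from phylorisk import load_fixture, pd_loss, pd_value

fx = load_fixture("fig1")
tree = fx.tree

print(f"PD of all 5 species: {pd_value(tree):.0f}")
print(f"PD lost if species a goes extinct: {pd_loss(tree, ['a']):.0f}")
for extra in (["a", "b"], ["a", "b", "c"], ["a", "b", "c", "d"]):
    print(f"PD lost if {{{','.join(extra)}}} go extinct: {pd_loss(tree, extra):.0f}")

# Losing a, b, c one by one costs 5, 4, 2 extra units; losing d as well
# costs its 1-unit terminal branch PLUS the 20-unit stem of the whole clade
# and the two internal branches: the loss jumps from 11 to 38.
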
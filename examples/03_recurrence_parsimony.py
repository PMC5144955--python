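"""Counting independent origins of a rearrangement on a phylogeny.

The carrier state of a translocation is a binary tip character.  Fitch
parsimony gives the minimum number of state changes; the origin count
constrains the root to non-carrier and (because a fixed translocation does
not revert) forbids losses, so it counts 0->1 gains only.  A species in
which the rearrangement is not fixed enters as an ambiguous tip.
"""

from synbreak import CharacterStateTree, min_changes_fitch, min_origins

tree = "((((wheat:0.8,einkorn:0.8):0.6,(goatgrass_D:1.0,goatgrass_S:1.0):0.4):5.6,rye:7.0):4.0,barley:11.0);"
states = {
    "wheat": 1,
    "einkorn": 1,
    "goatgrass_D": 0,
    "goatgrass_S": 0,
    "rye": 1,
    "barley": 0,
}

cst = CharacterStateTree.from_newick(tree, states)
print("Fitch changes:", min_changes_fitch(cst))
print("independent origins (root non-carrier):", min_origins(cst, root_state=0))
print("origins if losses were free:", min_origins(cst, 0, allow_losses=True))

# With a polymorphic species added as an ambiguous tip, no extra origin is
# forced: the ambiguity resolves to whichever state is cheaper.
states_poly = dict(states, villosa="ambiguous")
tree_poly = tree.replace("rye:7.0", "(rye:5.0,villosa:5.0):2.0")
cst_poly = CharacterStateTree.from_newick(tree_poly, states_poly)
print("origins with a polymorphic species:", min_origins(cst_poly, 0))
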
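"""Select clusters in a dendrogram, export labels, cut a child dendrogram.

Mirrors the interactive workflow: hover information for a node, multi-level
selection with automatic colors, a long-format membership export, and a
standalone re-indexed child dendrogram of a selected cluster.
"""

from dendroselect import (
    SelectionState,
    build_tree,
    extract_child,
    membership_table,
    random_linkage,
    select,
)

m, labels = random_linkage(8, seed=42)
d = build_tree(m, labels)

root = d.root.id
print("root info (id, name, leaf_count, height):", d.node_info(root))

a, b = (c.id for c in d.root.children)
state = SelectionState()
state = select(state, d, a)   # gets palette color 1
state = select(state, d, b)   # gets palette color 2
for label, cluster, color in membership_table(d, state):
    print(f"{label}\t{cluster}\t{color}")
# every leaf appears exactly once: the two selections partition the tree

child = extract_child(d, a)
print("child leaves:", child.leaf_order)
print("child Newick:", child.to_newick())
# the child is standalone: leaves renumbered 0..m-1, heights unchanged
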
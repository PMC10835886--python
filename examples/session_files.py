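"""Save an analysis session to JSON and reconstruct it elsewhere.

A session bundles the dendrogram, the selection state (with colors) and any
extracted child dendrograms into one portable file.
"""

from pathlib import Path
from tempfile import mkdtemp

from dendroselect import (
    DendroJSON,
    Session,
    SelectionState,
    load_session,
    random_linkage,
    save_session,
    select,
)
from dendroselect.tree import from_dendro_json

m, labels = random_linkage(12, seed=3)
dendro = DendroJSON(labels=labels, linkage=m)
d = from_dendro_json(dendro)

sess = Session(dendrogram=dendro, session_name="demo-session")
state = SelectionState()
a, b = (c.id for c in d.root.children)
state = select(state, d, a, name="left-arm")
state = select(state, d, b, name="right-arm")
sess.selection = state
sess.add_child(a)  # materialize the left arm as a child dendrogram

path = Path(mkdtemp()) / "session.json"
stamp = save_session(sess, path)
print("saved", path.name, "at", stamp)

back = load_session(path)
print("session name:", back.session_name)
print("selections:", [(s.node_id, s.name, s.color)
                      for s in back.selection.selections])
print("children:", [(c.parent_node_id, c.dendrogram.n_leaves)
                    for c in back.children])
# everything needed to reconstruct the view travels in the one JSON file
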
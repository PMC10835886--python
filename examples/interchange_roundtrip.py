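"""Convert an R-style signed merge table to the JSON interchange schema.

Builds the 3-leaf clustering by hand in the hclust encoding (negative
entries are 1-based leaves), converts it to the condensed form, writes the
interchange JSON and reads it back.
"""

from pathlib import Path
from tempfile import mkdtemp

from dendroselect import (
    DendroJSON,
    SignedMergeTable,
    condensed_to_signed,
    read_linkage_json,
    signed_to_condensed,
    write_linkage_json,
)

# A and B merge at height 0.2; C joins that cluster at 0.7
signed = SignedMergeTable(
    merge=((-1, -2), (-3, 1)),
    heights=(0.2, 0.7),
    order=(1, 2, 3),
    labels=("A", "B", "C"),
)

condensed, labels = signed_to_condensed(signed)
print("condensed rows:", condensed.rows)
# -> ((0, 1, 0.2, 2), (2, 3, 0.7, 3)): leaf -k became id k-1, merge row 1
#    became id n+0 = 3, and counts were recomputed

out = Path(mkdtemp()) / "tree.json"
write_linkage_json(DendroJSON(labels=labels, linkage=condensed), out)
back = read_linkage_json(out)
print("round trip equal:", back.linkage == condensed)

signed_again = condensed_to_signed(condensed, labels)
print("signed again:", signed_again.merge, signed_again.heights)
# the double round trip reproduces the merge table and heights exactly
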
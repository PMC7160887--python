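"""Reconstruct the ancestor of two sibling gene orders (the 2-SPP).

Two genomes that differ by one in-operon deletion and one anticodon
substitution are compared; the inferred ancestor and the branch-assigned
events are printed.
"""

from operonevo.builder import infer_cherry
from operonevo.io import gene_order_from_text

x = gene_order_from_text(
    "<o> [16S 23S 5S tRNA-Ala(tgc)] tRNA-Ile(gat) <t> -[tRNA-Asn(gtt) tRNA-Glu(ttc)]", "X"
)
y = gene_order_from_text(
    "<o> [16S 23S tRNA-Ala(agc)] tRNA-Ile(gat) <t> -[tRNA-Asn(gtt) tRNA-Glu(ttc)]", "Y"
)

rec = infer_cherry(x, y, "X", "Y", parent_id="ancestor")
print("ancestor:", rec.ancestor)
for e in rec.events:
    print(f"  {e.event_type} on branch {e.branch}, size {e.size}")

# Without a neighboring genome the 5S gap is an arbitrary deletion/duplication
# choice (here: deletion on the Y branch) and the substitution keeps the first
# child's anticodon ancestral; a neighbor would polarize both decisions.
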
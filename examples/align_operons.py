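"""Score two rRNA/tRNA operons with the orthology alignment kernel.

Operons are aligned gene-by-gene in transcription order: +1 for a full match
(same identity class and anticodon), +0.5 for a partial match (same tRNA
class, different anticodon), -1 for mismatches and gaps.  The score decides
whether two operons are treated as orthologous (score >= 0).
"""

from operonevo.align import align_operons
from operonevo.model import Gene

x = [Gene("Ala", "tgc", 1), Gene("Ile", "gat", 1), Gene("Asn", "gtt", 1)]
y = [Gene("Ala", "ggc", 1), Gene("Asn", "gtt", 1)]

al = align_operons(x, y)
print(f"alignment score: {al.score}")
for col in al.columns:
    gx = x[col.x_pos] if col.x_pos is not None else "-"
    gy = y[col.y_pos] if col.y_pos is not None else "-"
    print(f"  {col.label:8s} {gx} / {gy}")

# The score (0.5 here) combines one partial match (+0.5: Ala with a changed
# anticodon), one full match (+1: Asn) and one gap (-1: Ile missing from the
# second operon); non-negative, so the operons would be paired as orthologs.
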
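"""Does the amplified fragment resolve the panel like the full gene does?

Extracts the in-silico PCR fragments from every panel member, builds
p-distance neighbor-joining trees from the fragments and from the
full-length genes, and compares the two topologies by Robinson-Foulds
distance (0 = identical splits).
"""

from degenmix import nj_tree, pairwise_pdistance, rf_distance
from degenmix.core import SequenceRecord
from degenmix.fixtures import benchmark_panel
from degenmix.ispcr import predict_amplicons

panel = benchmark_panel(seed=0)
fragments = []
for t in panel.templates:
    amps = predict_amplicons(panel.mixes["Fw1_mixB"], panel.mixes["Rv1"], t)
    # fragments share the design alignment frame, so no re-alignment is needed
    fragments.append(SequenceRecord(id=t.id, seq=amps[0].sequence))

full_tree = nj_tree(pairwise_pdistance(panel.templates))
frag_tree = nj_tree(pairwise_pdistance(fragments))
rf = rf_distance(full_tree, frag_tree)
n_splits = 2 * (len(panel.templates) - 3)
print(f"fragment length: {len(fragments[0].seq)} bp of "
      f"{len(panel.templates[0].seq)} bp genes")
print(f"Robinson-Foulds distance fragment vs full-gene tree: {rf} "
      f"(max {n_splits})")
print("a small RF distance means the amplicon retains most of the "
      "full gene's phylogenetic signal")
print("\nfragment tree (newick):")
print(str(frag_tree).strip())
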
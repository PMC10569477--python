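"""Thermodynamic and secondary-structure QC of candidate primers.

Screens three oligos against the binding-region guidelines: a compliant
degenerate 22-mer, a GC-rich self-complementary one, and a short AT-rich
one that misses the melting-temperature window.
"""

from degenmix import DegenerateSequence, DesignRules, qc_primer

rules = DesignRules()
candidates = [
    DegenerateSequence("GWGTCWAACWGGAWGGGATCAA", name="good_degenerate"),
    DegenerateSequence("GCGCGCGCGCGCGCGCGCGC", name="gc_palindrome"),
    DegenerateSequence("ATCAGTCAGTACGACTGATG", name="cool_20mer"),
]
for oligo in candidates:
    print(qc_primer(oligo, rules))
    print()
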
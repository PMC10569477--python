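# degenmix

Design and in-silico validation of **degenerate primer mixes** for
marker-gene PCR assays, built around the workflow used to target *hglT* —
the glycosyltransferase gene that performs the final step of heterocyte
glycolipid biosynthesis in heterocytous (nitrogen-fixing) cyanobacteria.
Heterocyte glycolipids are preserved lipid biomarkers, so a PCR assay on
*hglT* gives a fast, DNA-based way to detect *living* producers where lipid
analysis alone cannot distinguish live communities from preserved remnants.
The toolkit is generic: it applies to any panel of homologous nucleotide
sequences for which a selective, broadly covering primer pair is needed.

## What it does

Starting from an aligned FASTA of marker-gene orthologs:

1. **Region scan** — find gap-free alignment windows of primer length
   (17–22 bp) whose columns are conserved (majority-base fraction ≥ 75 %)
   and whose consensus satisfies the binding-region guidelines: Tm within
   50–65 °C, GC < 50 %, no long homopolymers, no hairpin- or dimer-prone
   self-complementarity. Forward/reverse windows are paired to maximize
   product length under the paired-Tm constraint (ΔTm ≤ 4 °C).
2. **Variant design** — partition the target sequences at a chosen region
   into the fewest groups whose *minimal degenerate consensus* (IUPAC codes
   never wider than the observed bases) is compliant: at most 4 degenerate
   positions, never consecutive, spread apart, thermodynamics intact. Each
   group yields one variant; the equimolar pool is the mix. A variant below
   the degeneracy cap can be *relaxed* by one extra degenerate position to
   pick up additional targets (G1 → G1n).
3. **Thermodynamic QC** — composition-formula melting temperatures
   (Wallace rule `Tm = 2(A+T) + 4(G+C)` for <14-mers, the long-oligo
   formula `Tm = 64.9 + 41(GC − 16.4)/L` otherwise), GC bounds over the
   expansion pool, homopolymer, hairpin and self/3′-dimer screening by
   complementary-run counting.
4. **In-silico PCR** — expansion-aware matching of mixes on both strands of
   template sequences (strict zero-mismatch by default, an optional
   mismatch-tolerant mode with exact 3′ anchoring), amplicon and
   product-size prediction, and the strain × variant **coverage matrix**
   whose column sums are the "targets *N* strains" counts.
5. **Marker resolution** — p-distance neighbor-joining trees from predicted
   amplicons and Robinson–Foulds congruence against full-length trees, to
   check how much phylogenetic signal the amplified fragment retains.
6. **Synthetic fixtures** — deterministic generators for gene families with
   planted conserved blocks and for a 24-taxon benchmark panel emulating
   the published validation conditions, so the full pipeline runs and is
   tested without any downloaded data.

## Worked example

`examples/insilico_pcr_validation.py` screens the pooled mixes against the
synthetic 24-sequence panel:

```text
strict zero-mismatch coverage of the 24-sequence panel:
  Fw1_G1: 3 degenerate bases, targets 6 of 24 strains
  Fw1_G1n: 4 degenerate bases, targets 8 of 24 strains
per-mix union coverage: {'Fw1_mixA': 21, 'Fw1_mixB': 24, 'Rv1': 24}

SYN01_Anabaena_like: product 112..970 (859 bp) via Fw1_G1n + Rv1_G1
```

Reading this: the relaxed variant `Fw1_G1n` trades one extra degenerate
base for two additional covered strains; pooling the relaxed variants
(mix B, 7 oligos) covers the whole panel where the conservative mix A
reaches 21 of 24; and the chosen pair amplifies a single ~850 bp fragment
from the Anabaena-like reference. The other example scripts cover region
scanning and mix design (`design_primer_mixes.py`), primer QC reports
(`primer_qc.py`) and amplicon-tree congruence (`marker_tree.py`).

A thin CLI mirrors the library (`degenmix simulate | scan | design | qc |
ispcr | tree`), e.g.:

```bash
degenmix ispcr --fw fw_mix.fasta --rv rv_mix.fasta \
    --templates genes.fasta --max-mismatch 0 \
    --out amplicons.fasta --matrix coverage.tsv
```

All reported coordinates are 1-based inclusive; primer tables are TSV with
columns `name, sequence, region_start, region_end, orientation, mix`.

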
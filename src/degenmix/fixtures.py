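"""Deterministic synthetic sequence families with planted ground truth.

Everything here is generated — no real genome or primer data is shipped.
Two kinds of fixture are provided:

* :func:`simulate_gene_family` — a gene family with conserved blocks planted
  in divergent background, for exercising the region scan and design stages
  with known truth.
* :func:`benchmark_panel` — a fully synthetic stand-in for a published-style
  validation panel: 24 aligned marker-gene sequences whose two binding
  regions are built from degenerate variant groups, together with the
  corresponding primer table.  The panel reproduces the structure of the
  hglT study conditions (a forward mix of seven variants including a
  relaxed G1n that reaches 8 of 24 targets where G1 reaches 6, a reverse
  mix of five variants, and an ~850 bp product on an Anabaena-like
  reference), so every pipeline stage can be measured against those
  figures without any downloaded data.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .core import (
    Alignment,
    DegenerateSequence,
    SequenceError,
    SequenceRecord,
    reverse_complement,
)
from .ispcr import match_primer

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Gene-family simulator
# ---------------------------------------------------------------------------


@dataclass
class FamilySpec:
    """Parameters of a synthetic marker-gene family.

    `conserved_blocks` are (start, length, max_minor_fraction) with start a
    1-based alignment column; within a block every column keeps the root
    base in at least ``1 - max_minor_fraction`` of the taxa.  Background
    columns substitute away from the root with probability
    `background_divergence` per taxon (uniform over the three alternative
    bases); with a `clade_structure` (a partition of taxon indices) half the
    divergence is shared within each clade.
    """

    n_taxa: int = 24
    gene_length: int = 1050
    conserved_blocks: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(112, 20, 0.08), (970, 20, 0.08)]
    )
    background_divergence: float = 0.30
    clade_structure: list[list[int]] | None = None
    seed: int = 1
    root_seq: str | None = None  # full root override; random when None

    def __post_init__(self) -> None:
        if not 0 <= self.background_divergence <= 1:
            raise SequenceError("background_divergence must be in [0, 1]")
        spans = []
        for start, length, mmf in self.conserved_blocks:
            if not 0 <= mmf <= 1:
                raise SequenceError("max_minor_fraction must be in [0, 1]")
            if start < 1 or start + length - 1 > self.gene_length:
                raise SequenceError(f"block ({start}, {length}) outside gene")
            spans.append((start - 1, start - 1 + length))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise SequenceError("conserved blocks overlap")
        if self.root_seq is not None and len(self.root_seq) != self.gene_length:
            raise SequenceError("root_seq length != gene_length")


def _mutate(base: str, rng: np.random.Generator) -> str:
    return rng.choice([b for b in _BASES if b != base])


def simulate_gene_family(
    spec: FamilySpec,
) -> tuple[Alignment, dict, TreeNode]:
    """Generate an aligned family, its planted truth, and the generating tree.

    Returns (alignment, truth, tree) where truth records the 1-based block
    coordinates and the root sequence.  Reproducible: identical spec (incl.
    seed) gives byte-identical output.  The generated family is
    self-validated against its own spec before being returned.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_taxa, spec.gene_length
    root = spec.root_seq or "".join(rng.choice(list(_BASES), size=L))
    block_cols: set[int] = set()
    for start, length, _ in spec.conserved_blocks:
        block_cols.update(range(start - 1, start - 1 + length))

    clades = spec.clade_structure or [[i] for i in range(n)]
    if sorted(i for c in clades for i in c) != list(range(n)):
        raise SequenceError("clade_structure must partition range(n_taxa)")
    p = spec.background_divergence
    p_clade = p / 2 if spec.clade_structure else 0.0
    p_taxon = p / 2 if spec.clade_structure else p

    rows = [list(root) for _ in range(n)]
    for clade in clades:
        clade_seq = list(root)
        for j in range(L):
            if j in block_cols:
                continue
            if p_clade and rng.random() < p_clade:
                clade_seq[j] = _mutate(clade_seq[j], rng)
        for i in clade:
            for j in range(L):
                if j in block_cols:
                    continue
                rows[i][j] = (
                    _mutate(clade_seq[j], rng)
                    if rng.random() < p_taxon
                    else clade_seq[j]
                )
    # plant conserved blocks: root base everywhere, then a bounded minority
    for start, length, mmf in spec.conserved_blocks:
        max_minor = int(mmf * n)
        for j in range(start - 1, start - 1 + length):
            m = int(rng.integers(0, max_minor + 1))
            if m:
                alt = _mutate(root[j], rng)
                for i in rng.choice(n, size=m, replace=False):
                    rows[int(i)][j] = alt

    records = [
        SequenceRecord(id=f"taxon{i + 1:02d}", seq="".join(rows[i]))
        for i in range(n)
    ]
    aln = Alignment(records)
    # self-validation: every block column keeps the promised majority
    for start, length, mmf in spec.conserved_blocks:
        for j in range(start - 1, start - 1 + length):
            col = aln.column(j)
            frac = col.count(root[j]) / n
            assert frac >= 1 - mmf - 1e-9, (j, frac)

    tree = TreeNode(
        children=[
            TreeNode(
                children=[TreeNode(name=records[i].id, length=p_taxon) for i in clade],
                length=p_clade,
            )
            for clade in clades
        ]
    )
    truth = {
        "blocks": [
            {"start": s, "end": s + ln - 1, "max_minor_fraction": mmf}
            for s, ln, mmf in spec.conserved_blocks
        ],
        "root_seq": root,
        "seed": spec.seed,
    }
    return aln, truth, tree


# ---------------------------------------------------------------------------
# Planted in-silico PCR templates
# ---------------------------------------------------------------------------


def plant_primer_sites(
    template_length: int,
    fw: DegenerateSequence,
    rv: DegenerateSequence,
    product_length: int,
    seed: int = 0,
    template_id: str = "planted",
    max_tries: int = 50,
) -> tuple[SequenceRecord, dict]:
    """A random template with exactly one planted product of `product_length`.

    One random expansion of the forward primer and the reverse complement of
    one random expansion of the reverse primer are embedded so that strict
    in-silico PCR returns exactly one amplicon.  The background is
    rejection-sampled until neither primer has any off-target strict match.
    """
    if product_length < len(fw) + len(rv):
        raise SequenceError("product shorter than the two primer footprints")
    if product_length > template_length:
        raise SequenceError("product does not fit in the template")
    rng = np.random.default_rng(seed)
    fw_exp = sorted(fw.expand())
    rv_exp = sorted(rv.expand())
    start = int(rng.integers(0, template_length - product_length + 1))
    fw_site = fw_exp[int(rng.integers(len(fw_exp)))]
    rv_site = reverse_complement(rv_exp[int(rng.integers(len(rv_exp)))]).bases
    end = start + product_length  # 0-based half-open product span
    for _ in range(max_tries):
        seq = list(rng.choice(list(_BASES), size=template_length))
        seq[start : start + len(fw)] = fw_site
        seq[end - len(rv) : end] = rv_site
        rec = SequenceRecord(id=template_id, seq="".join(seq))
        fw_hits = match_primer(fw, rec)
        rv_hits = match_primer(rv, rec)
        want_fw = [h for h in fw_hits if h.strand == "+" and h.start == start + 1]
        want_rv = [h for h in rv_hits if h.strand == "-" and h.end == end]
        if len(fw_hits) == len(want_fw) == 1 and len(rv_hits) == len(want_rv) == 1:
            truth = {
                "fw_start": start + 1,
                "rv_end": end,
                "product_length": product_length,
                "seed": seed,
            }
            return rec, truth
    raise SequenceError("could not place primer sites without off-target matches")


# ---------------------------------------------------------------------------
# Synthetic benchmark panel (structure of the hglT validation study)
# ---------------------------------------------------------------------------

# Skeleton window sequences (plus strand).  Both carry 10 G/C in 22 nt so
# every A/T-degenerate variant keeps GC = 10/22 and Tm = 52.97 degC, inside
# the guideline box; both were screened against the hairpin/dimer checks
# with ambiguity at every variable position.
_FW_SKELETON = "GAGTCAAACAGGATGGGATCAA"
_RV_SKELETON = "CGATACACTGAGCCTGCAATAA"  # reverse primer = its reverse complement

# variable-position layout (0-based within the 22-mer window)
_FW_DEG = (1, 5, 9, 13)
_FW_IDENT = (3, 7, 17, 20)
_RV_DEG = (2, 6, 10, 14)
_RV_IDENT = (4, 8, 18, 21)

# even-weight flip vectors: any two differ at >= 2 identity positions, so no
# variant of one group can strictly match a member of another group
_CODEWORDS = [
    (0, 0, 0, 0),
    (0, 0, 1, 1),
    (0, 1, 0, 1),
    (0, 1, 1, 0),
    (1, 0, 0, 1),
    (1, 0, 1, 0),
    (1, 1, 0, 0),
    (1, 1, 1, 1),
]

_FLIP = {"A": "T", "T": "A"}

# forward groups: (name, taxon indices, degenerate positions)
_FW_GROUPS = [
    ("G1", list(range(0, 8)), (1, 5, 9, 13)),
    ("G2", list(range(8, 12)), (1, 5, 9)),
    ("G3", list(range(12, 15)), (1, 9)),
    ("G4", list(range(15, 18)), (5, 13)),
    ("G5", list(range(18, 20)), (1,)),
    ("G6", list(range(20, 22)), (9,)),
    ("G7", list(range(22, 24)), (5, 13)),
]
# reverse groups
_RV_GROUPS = [
    ("G1", list(range(0, 6)), (2, 6, 10)),
    ("G2", list(range(6, 11)), (2, 10)),
    ("G3", list(range(11, 16)), (6, 14)),
    ("G4", list(range(16, 20)), (2,)),
    ("G5", list(range(20, 24)), (10, 14)),
]

#: 1-based inclusive alignment columns of the two binding regions
FW_REGION = (112, 133)
RV_REGION = (949, 970)
PANEL_SIZE = 24
GENE_LENGTH = 1100


def _apply_codeword(skeleton: str, ident: tuple[int, ...], code) -> str:
    s = list(skeleton)
    for pos, flip in zip(ident, code):
        if flip:
            s[pos] = _FLIP[s[pos]]
    return "".join(s)


def _group_motif(skeleton: str, deg: tuple[int, ...]) -> str:
    s = list(skeleton)
    for pos in deg:
        s[pos] = "W"  # variable positions are A/T, so the code is always W
    return "".join(s)


def _member_window(motif: str, deg: tuple[int, ...], k: int, skeleton: str) -> str:
    """Deterministic expansion of a group motif for its k-th member.

    The alternating pattern guarantees both letters of every W are realized
    in any group of two or more, so the minimal consensus of a full group
    recovers the motif exactly.
    """
    s = list(motif)
    for j, pos in enumerate(deg):
        base = skeleton[pos]
        s[pos] = base if (k + j) % 2 == 0 else _FLIP[base]
    return "".join(s)


@dataclass
class BenchmarkPanel:
    """A synthetic 24-taxon validation panel with its primer table."""

    alignment: Alignment
    templates: list[SequenceRecord]
    primer_table: pd.DataFrame
    mixes: dict[str, list[DegenerateSequence]]
    fw_region: tuple[int, int]
    rv_region: tuple[int, int]
    reference_id: str

    def region_windows(self, region: tuple[int, int]) -> dict[str, str]:
        """Ungapped member windows of a binding region (1-based inclusive)."""
        a, b = region
        return {r.id: r.seq[a - 1 : b] for r in self.alignment.records}


def benchmark_panel(seed: int = 0) -> BenchmarkPanel:
    """Build the synthetic hglT-style panel (24 taxa, 1100 bp, two regions).

    Forward region (columns 112..133): seven variant groups.  Group 1 holds
    eight taxa; its three-degeneracy variant Fw1_G1 matches six of them and
    the one-position relaxation Fw1_G1n (four degeneracies) matches all
    eight.  Group 2 (four taxa) likewise has Fw1_G2 / relaxed Fw1_G2af.
    Mix A pools the conservative variants, mix B the relaxed ones; both
    share Fw1_G3..Fw1_G7.  Reverse region (columns 949..970): five groups,
    Rv1_G1..Rv1_G5.  The first taxon (Anabaena-like synthetic reference)
    yields a single 859 bp product with Fw1 mix B + Rv1.

    The background is random with divergence 0.15 from a random root; only
    the `seed` varies it.  All coverage counts are properties of the
    generated sequences, measured by the matcher — nothing is tabulated.
    """
    rng = np.random.default_rng(seed)
    n, L = PANEL_SIZE, GENE_LENGTH
    root = "".join(rng.choice(list(_BASES), size=L))
    rows = []
    for i in range(n):
        row = [
            _mutate(root[j], rng) if rng.random() < 0.15 else root[j]
            for j in range(L)
        ]
        rows.append(row)

    fw_motifs: dict[str, str] = {}
    rv_motifs: dict[str, str] = {}
    # plant the forward region windows
    for g, (name, members, deg) in enumerate(_FW_GROUPS):
        skel = _apply_codeword(_FW_SKELETON, _FW_IDENT, _CODEWORDS[g])
        motif = _group_motif(skel, deg)
        fw_motifs[name] = motif
        for k, i in enumerate(members):
            win = _member_window(motif, deg, k, skel)
            if name == "G1":
                # position 13 splits the group: first six keep the skeleton
                # base (matched by Fw1_G1), last two carry the alternative
                base13 = skel[13]
                win = win[:13] + (base13 if k < 6 else _FLIP[base13]) + win[14:]
            if name == "G2":
                # position 9 splits 3 + 1 (Fw1_G2 vs relaxed Fw1_G2af)
                base9 = skel[9]
                win = win[:9] + (base9 if k < 3 else _FLIP[base9]) + win[10:]
            rows[i][FW_REGION[0] - 1 : FW_REGION[1]] = win
    # plant the reverse region windows
    for g, (name, members, deg) in enumerate(_RV_GROUPS):
        skel = _apply_codeword(_RV_SKELETON, _RV_IDENT, _CODEWORDS[g])
        motif = _group_motif(skel, deg)
        rv_motifs[name] = motif
        for k, i in enumerate(members):
            win = _member_window(motif, deg, k, skel)
            rows[i][RV_REGION[0] - 1 : RV_REGION[1]] = win

    ids = ["SYN01_Anabaena_like"] + [f"SYN{i + 1:02d}" for i in range(1, n)]
    records = [
        SequenceRecord(
            id=ids[i],
            seq="".join(rows[i]),
            description="synthetic panel member (generated, no real genome data)",
        )
        for i in range(n)
    ]

    # primer oligos: forward = plus-strand motif, reverse = reverse complement
    def _oligo(name: str, motif: str, rv: bool = False) -> DegenerateSequence:
        s = DegenerateSequence(motif, name=name)
        return reverse_complement(s) if rv else s

    g1_skel = _apply_codeword(_FW_SKELETON, _FW_IDENT, _CODEWORDS[0])
    g2_skel = _apply_codeword(_FW_SKELETON, _FW_IDENT, _CODEWORDS[1])
    fw_variants = {
        "Fw1_G1": _oligo(
            "Fw1_G1",
            fw_motifs["G1"][:13] + g1_skel[13] + fw_motifs["G1"][14:],
        ),
        "Fw1_G1n": _oligo("Fw1_G1n", fw_motifs["G1"]),
        "Fw1_G2": _oligo(
            "Fw1_G2", fw_motifs["G2"][:9] + g2_skel[9] + fw_motifs["G2"][10:]
        ),
        "Fw1_G2af": _oligo("Fw1_G2af", fw_motifs["G2"]),
    }
    for name in ("G3", "G4", "G5", "G6", "G7"):
        fw_variants[f"Fw1_{name}"] = _oligo(f"Fw1_{name}", fw_motifs[name])
    rv_variants = {
        f"Rv1_{name}": _oligo(f"Rv1_{name}", motif, rv=True)
        for name, motif in rv_motifs.items()
    }

    mixes = {
        "Fw1_mixA": [fw_variants[f"Fw1_{g}"] for g in ("G1", "G2", "G3", "G4", "G5", "G6", "G7")],
        "Fw1_mixB": [fw_variants[n] for n in ("Fw1_G1n", "Fw1_G2af")]
        + [fw_variants[f"Fw1_{g}"] for g in ("G3", "G4", "G5", "G6", "G7")],
        "Rv1": list(rv_variants.values()),
    }

    table_rows = []
    mix_of: dict[str, list[str]] = {}
    for mix_name, oligos in mixes.items():
        for o in oligos:
            mix_of.setdefault(o.name, []).append(mix_name)
    for name, v in {**fw_variants, **rv_variants}.items():
        region = FW_REGION if name.startswith("Fw") else RV_REGION
        table_rows.append(
            {
                "name": name,
                "sequence": v.bases,
                "region_start": region[0],
                "region_end": region[1],
                "orientation": "fw" if name.startswith("Fw") else "rv",
                "mix": ";".join(mix_of.get(name, [])),
            }
        )
    table = pd.DataFrame(table_rows)

    return BenchmarkPanel(
        alignment=Alignment(records),
        templates=records,
        primer_table=table,
        mixes=mixes,
        fw_region=FW_REGION,
        rv_region=RV_REGION,
        reference_id=ids[0],
    )


# ---------------------------------------------------------------------------
# Helpers for tree tests
# ---------------------------------------------------------------------------


def random_additive_tree(
    n_leaves: int, seed: int = 0
) -> tuple[TreeNode, DistanceMatrix]:
    """A random binary tree and its (additive) patristic distance matrix."""
    if n_leaves < 3:
        raise SequenceError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"L{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        nodes.append(TreeNode(children=[a, b]))
    tree = nodes[0]
    dm = tree.tip_tip_distances()
    return tree, DistanceMatrix(dm.data, list(dm.ids))


def recovery_family(seed: int = 1) -> tuple[Alignment, dict, TreeNode]:
    """The seed-fixed planted-block family used for end-to-end recovery.

    24 taxa, 1050 columns, conserved blocks at (112, 20) and (970, 20) whose
    root neighbourhoods are the QC-compliant skeleton windows, in background
    at divergence 0.30 — divergent enough that only the planted regions
    satisfy the conservation threshold.
    """
    rng = np.random.default_rng(seed)
    L = 1050
    root = list("".join(rng.choice(list(_BASES), size=L)))
    root[111:133] = _FW_SKELETON  # block 112..131 + two flanking columns
    root[967:989] = _RV_SKELETON  # two flanking columns + block 970..989
    spec = FamilySpec(
        n_taxa=24,
        gene_length=L,
        conserved_blocks=[(112, 20, 0.08), (970, 20, 0.08)],
        background_divergence=0.30,
        seed=seed,
        root_seq="".join(root),
    )
    return simulate_gene_family(spec)
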
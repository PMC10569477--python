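"""In-silico PCR: degenerate primer matching, amplicon prediction, coverage.

Matching is expansion-aware string comparison on both strands of a linear
template.  The default policy is strict — zero mismatches over the full
primer footprint, `N` in the template matches nothing — which is the policy
behind "targets N strains" coverage counts.  A permissive mode
(`max_mismatch` up to 2 with the 3'-terminal bases exact) models the
tolerance of a real PCR, where amplification can exceed designed coverage.
All reported coordinates are 1-based inclusive template positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import (
    DegenerateSequence,
    IUPAC_CODES,
    SequenceError,
    SequenceRecord,
    reverse_complement,
)
from .design import PrimerMix, PrimerVariant


@dataclass(frozen=True)
class PrimerHit:
    template_id: str
    strand: str  # "+" | "-"
    start: int  # 1-based inclusive
    end: int
    variant_name: str
    mismatches: int


@dataclass
class AmpliconHit:
    template_id: str
    fw_hit: PrimerHit
    rv_hit: PrimerHit
    product_start: int
    product_end: int
    product_length: int
    sequence: str


def _match_at(
    primer: str, template: str, offset: int, n_match_any: bool
) -> list[int]:
    """Indices (0-based, within primer) of mismatching positions."""
    mm = []
    for k, code in enumerate(primer):
        t = template[offset + k]
        if t in IUPAC_CODES[code]:
            continue
        if t == "N" and n_match_any:
            continue
        mm.append(k)
    return mm


def match_primer(
    primer: DegenerateSequence | str,
    template: SequenceRecord,
    max_mismatch: int = 0,
    three_prime_exact: int = 0,
    n_match_any: bool = False,
) -> list[PrimerHit]:
    """All placements of a degenerate primer on both strands of a template.

    A placement is a hit when the template is compatible with some expansion
    at `max_mismatch` or fewer mismatches, and the `three_prime_exact`
    3'-terminal primer bases are mismatch-free.  On the minus strand the
    primer binds as its reverse complement; its 3' end is then the leftmost
    base of the footprint.
    """
    if isinstance(primer, str):
        primer = DegenerateSequence(primer)
    p = primer.bases
    t = template.seq.upper()
    n, m = len(t), len(p)
    if m > n:
        return []
    hits: list[PrimerHit] = []
    rc = reverse_complement(primer).bases
    for off in range(n - m + 1):
        # plus strand: primer 3' end at the right of the footprint
        mm = _match_at(p, t, off, n_match_any)
        if len(mm) <= max_mismatch and all(k < m - three_prime_exact for k in mm):
            hits.append(
                PrimerHit(template.id, "+", off + 1, off + m, primer.name, len(mm))
            )
        # minus strand: match the reverse complement; 3' end at the left
        mm = _match_at(rc, t, off, n_match_any)
        if len(mm) <= max_mismatch and all(k >= three_prime_exact for k in mm):
            hits.append(
                PrimerHit(template.id, "-", off + 1, off + m, primer.name, len(mm))
            )
    return hits


def _oligos(mix: PrimerMix | list) -> list[DegenerateSequence]:
    if isinstance(mix, PrimerMix):
        return [v.seq for v in mix.variants]
    out = []
    for item in mix:
        if isinstance(item, PrimerVariant):
            out.append(item.seq)
        elif isinstance(item, DegenerateSequence):
            out.append(item)
        else:
            out.append(DegenerateSequence(str(item)))
    return out


def predict_amplicons(
    fw_mix: PrimerMix | list,
    rv_mix: PrimerMix | list,
    template: SequenceRecord,
    size_min: int = 100,
    size_max: int = 3000,
    max_mismatch: int = 0,
    three_prime_exact: int = 0,
    n_match_any: bool = False,
) -> list[AmpliconHit]:
    """Predicted PCR products of a forward/reverse mix pair on one template.

    A product forms between any plus-strand forward hit and any downstream
    minus-strand reverse hit, bounded to [size_min, size_max]; the product
    includes both primer footprints.  Products with identical coordinates
    (several pool members binding the same sites) are collapsed, keeping the
    pair with the fewest total mismatches.
    """
    fw_oligos = _oligos(fw_mix)
    rv_oligos = _oligos(rv_mix)
    if not fw_oligos or not rv_oligos:
        raise SequenceError("empty primer mix")
    kw = dict(
        max_mismatch=max_mismatch,
        three_prime_exact=three_prime_exact,
        n_match_any=n_match_any,
    )
    fw_hits = [
        h for o in fw_oligos for h in match_primer(o, template, **kw) if h.strand == "+"
    ]
    rv_hits = [
        h for o in rv_oligos for h in match_primer(o, template, **kw) if h.strand == "-"
    ]
    best: dict[tuple[int, int], AmpliconHit] = {}
    for f in fw_hits:
        for r in rv_hits:
            if f.start >= r.start:
                continue
            length = r.end - f.start + 1
            if not size_min <= length <= size_max:
                continue
            amp = AmpliconHit(
                template_id=template.id,
                fw_hit=f,
                rv_hit=r,
                product_start=f.start,
                product_end=r.end,
                product_length=length,
                sequence=template.seq[f.start - 1 : r.end],
            )
            key = (amp.product_start, amp.product_end)
            prev = best.get(key)
            if prev is None or (
                amp.fw_hit.mismatches + amp.rv_hit.mismatches,
                amp.fw_hit.variant_name,
                amp.rv_hit.variant_name,
            ) < (
                prev.fw_hit.mismatches + prev.rv_hit.mismatches,
                prev.fw_hit.variant_name,
                prev.rv_hit.variant_name,
            ):
                best[key] = amp
    return [best[k] for k in sorted(best)]


@dataclass
class CoverageMatrix:
    """Boolean template x variant hit matrix with per-variant / per-mix counts."""

    table: pd.DataFrame  # bool, rows = template ids, columns = variant names
    mix_members: dict[str, list[str]]

    @property
    def variant_counts(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def mix_union_counts(self) -> dict[str, int]:
        return {
            mix: int(self.table[cols].any(axis=1).sum())
            for mix, cols in self.mix_members.items()
        }

    def to_tsv(self, path) -> None:
        out = self.table.astype(int)
        out.index.name = "template_id"
        out.to_csv(path, sep="\t")


def coverage_matrix(
    mixes: dict[str, PrimerMix | list] | list[PrimerMix],
    templates: list[SequenceRecord],
    max_mismatch: int = 0,
    three_prime_exact: int = 0,
    n_match_any: bool = False,
) -> CoverageMatrix:
    """Which templates each variant hits, under the active matching policy.

    `mixes` maps mix name -> mix (or is a list of named PrimerMix objects).
    A cell is true iff the variant has at least one hit on either strand.
    """
    if isinstance(mixes, list):
        mixes = {m.name: m for m in mixes}
    ids = [t.id for t in templates]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"duplicate template ids: {dupes}")
    members: dict[str, list[str]] = {}
    oligos: dict[str, DegenerateSequence] = {}
    for mix_name, mix in mixes.items():
        names = []
        for o in _oligos(mix):
            if not o.name:
                raise SequenceError(f"unnamed variant in mix {mix_name!r}")
            oligos[o.name] = o
            names.append(o.name)
        members[mix_name] = names
    data = {}
    for vname, oligo in oligos.items():
        data[vname] = [
            bool(
                match_primer(
                    oligo,
                    t,
                    max_mismatch=max_mismatch,
                    three_prime_exact=three_prime_exact,
                    n_match_any=n_match_any,
                )
            )
            for t in templates
        ]
    table = pd.DataFrame(data, index=ids)
    return CoverageMatrix(table=table, mix_members=members)


def amplicons_to_fasta(amplicons: list[AmpliconHit], path) -> None:
    """Write amplicons as FASTA; headers carry 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(
                f">{a.template_id}:{a.product_start}-{a.product_end}"
                f" fw={a.fw_hit.variant_name} rv={a.rv_hit.variant_name}"
                f" length={a.product_length}\n{a.sequence}\n"
            )
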
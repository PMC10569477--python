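"""Design minimal degenerate primer mixes covering a target panel.

Given the ungapped window sequences of every target at a chosen binding
region, the designer partitions the targets into the fewest groups whose
minimal degenerate consensus is *feasible*:

* at most `max_degenerate` degenerate positions (default 4),
* no two degenerate positions adjacent,
* primer length within the guideline window,
* Tm extremes over the expansion pool inside [tm_min, tm_max] and maximal
  GC fraction below the guideline cap (an equimolar mix anneals only if
  all its expansions do).

Each group yields one degenerate variant; the equimolar pool of variants is
the primer *mix*.  Degenerate codes are never wider than the bases actually
observed in the data.  A variant still below the degeneracy cap can be
*relaxed* by one extra degenerate position to pick up additional targets
(the "mix B" strategy, e.g. G1 -> G1n).

Partitioning is exact (minimum number of groups, dynamic programming over
target subsets) up to `EXACT_LIMIT` targets and greedy set-cover beyond:
repeatedly grow the feasible group covering the most uncovered targets,
breaking ties toward fewer degeneracies, then the lexicographically
smallest variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import (
    DegenerateSequence,
    DesignRules,
    IUPAC_CODES,
    SET_TO_CODE,
    SequenceError,
    consensus_degenerate,
    count_degenerate_positions,
    degenerate_positions,
)
from .thermo import QCReport, gc_range, qc_primer, tm_range

#: Exact minimum-partition search is used for panels up to this many targets.
EXACT_LIMIT = 12


class InfeasibleGroup(SequenceError):
    """A target group admits no guideline-compliant degenerate consensus."""

    def __init__(self, rule: str):
        super().__init__(rule)
        self.rule = rule


@dataclass
class PrimerVariant:
    """One degenerate oligo of a mix, with its coverage and QC report."""

    name: str
    seq: DegenerateSequence
    covered_ids: frozenset[str]
    qc: QCReport
    group_ids: frozenset[str] = frozenset()  # targets the variant was built from

    @property
    def n_degenerate(self) -> int:
        return count_degenerate_positions(self.seq)


@dataclass
class PrimerMix:
    """An equimolar pool of degenerate variants for one binding region."""

    name: str
    variants: list[PrimerVariant]
    uncoverable: list[str] = field(default_factory=list)

    @property
    def union_coverage(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for v in self.variants:
            out |= v.covered_ids
        return out


def _check_rows(rows: dict[str, str]) -> int:
    if not rows:
        raise SequenceError("empty target group")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise SequenceError(f"target windows of unequal length: {sorted(lengths)}")
    for rid, s in rows.items():
        if any(b not in "ACGT" for b in s.upper()):
            raise SequenceError(f"target window {rid!r} is not concrete/gap-free")
    return lengths.pop()


def _feasibility(seqs: list[str], rules: DesignRules) -> tuple[DegenerateSequence, str | None]:
    """Minimal consensus of concrete rows and the first violated rule, if any."""
    cols = [set(col) for col in zip(*seqs)]
    cons = consensus_degenerate(cols)
    n = len(cons)
    if not rules.primer_len_min <= n <= rules.primer_len_max:
        return cons, f"length {n} outside [{rules.primer_len_min}, {rules.primer_len_max}]"
    pos = degenerate_positions(cons)
    if len(pos) > rules.max_degenerate:
        return cons, f"{len(pos)} degenerate positions (no more than {rules.max_degenerate})"
    if any(b - a == 1 for a, b in zip(pos, pos[1:])):
        return cons, "consecutive degenerate positions"
    tlo, thi = tm_range(cons)
    if tlo < rules.tm_min or thi > rules.tm_max:
        return cons, f"Tm [{tlo:.1f}, {thi:.1f}] outside [{rules.tm_min}, {rules.tm_max}]"
    _, ghi = gc_range(cons)
    if ghi >= rules.gc_max:
        return cons, f"GC up to {ghi:.2f} not below {rules.gc_max}"
    return cons, None


def coverage_of(seq: DegenerateSequence, targets: dict[str, str]) -> frozenset[str]:
    """Ids of targets exactly matched by some expansion (zero mismatches)."""
    return frozenset(rid for rid, s in targets.items() if seq.matches(s.upper()))


def minimal_variant_for_group(
    rows: dict[str, str],
    rules: DesignRules | None = None,
    name: str = "",
    panel: dict[str, str] | None = None,
) -> PrimerVariant:
    """Minimal degenerate consensus of a target group, if guideline-compliant.

    Raises :class:`InfeasibleGroup` naming the violated rule otherwise.
    Coverage is evaluated against `panel` (defaults to the group itself):
    a variant can legitimately match targets outside its group.
    """
    rules = rules or DesignRules()
    _check_rows(rows)
    cons, violation = _feasibility([s.upper() for s in rows.values()], rules)
    if violation is not None:
        raise InfeasibleGroup(violation)
    cons = DegenerateSequence(cons.bases, name=name)
    panel = panel if panel is not None else rows
    return PrimerVariant(
        name=name,
        seq=cons,
        covered_ids=coverage_of(cons, panel),
        qc=qc_primer(cons, rules),
        group_ids=frozenset(rows),
    )


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def _exact_partition(
    ids: list[str], rows: dict[str, str], rules: DesignRules
) -> list[list[str]]:
    """Minimum number of feasible groups by DP over target subsets."""
    n = len(ids)
    seqs = [rows[i].upper() for i in ids]
    feasible = [False] * (1 << n)
    for mask in range(1, 1 << n):
        sel = [seqs[i] for i in range(n) if mask >> i & 1]
        _, violation = _feasibility(sel, rules)
        feasible[mask] = violation is None
    INF = n + 1
    best = [INF] * (1 << n)
    choice = [0] * (1 << n)
    best[0] = 0
    for mask in range(1, 1 << n):
        # iterate submasks containing the lowest set bit (canonical, no dupes)
        low = mask & -mask
        sub = mask
        while sub:
            if sub & low and feasible[sub] and best[mask ^ sub] + 1 < best[mask]:
                best[mask] = best[mask ^ sub] + 1
                choice[mask] = sub
            sub = (sub - 1) & mask
    full = (1 << n) - 1
    if best[full] > n:
        raise InfeasibleGroup("some single target admits no compliant variant")
    groups = []
    mask = full
    while mask:
        sub = choice[mask]
        groups.append([ids[i] for i in range(n) if sub >> i & 1])
        mask ^= sub
    return groups


def _grow_group(
    seed: str, pool: list[str], rows: dict[str, str], rules: DesignRules
) -> tuple[list[str], DegenerateSequence]:
    group = [seed]
    cons, _ = _feasibility([rows[seed].upper()], rules)
    remaining = [t for t in pool if t != seed]
    while True:
        best_t = None
        best_key = None
        best_cons = None
        for t in remaining:
            cand, violation = _feasibility([rows[g].upper() for g in group + [t]], rules)
            if violation is not None:
                continue
            key = (count_degenerate_positions(cand), cand.bases, t)
            if best_key is None or key < best_key:
                best_key, best_t, best_cons = key, t, cand
        if best_t is None:
            return group, cons
        group.append(best_t)
        cons = best_cons
        remaining.remove(best_t)


def _greedy_partition(
    ids: list[str], rows: dict[str, str], rules: DesignRules
) -> list[list[str]]:
    uncovered = sorted(ids)
    groups = []
    while uncovered:
        best = None
        best_key = None
        for seed in uncovered:
            group, cons = _grow_group(seed, uncovered, rows, rules)
            key = (-len(group), count_degenerate_positions(cons), cons.bases)
            if best_key is None or key < best_key:
                best_key, best = key, group
        groups.append(sorted(best))
        uncovered = [t for t in uncovered if t not in best]
    return groups


def partition_targets(
    rows: dict[str, str],
    rules: DesignRules | None = None,
    mix_name: str = "mix",
    name_prefix: str = "G",
    exact_limit: int = EXACT_LIMIT,
) -> PrimerMix:
    """Partition a target panel into the fewest feasible variant groups.

    Targets whose window alone admits no compliant variant are reported in
    ``mix.uncoverable`` rather than failing the whole design.  Groups are
    named ``G1..Gk`` in order of decreasing coverage.
    """
    rules = rules or DesignRules()
    _check_rows(rows)
    designable: dict[str, str] = {}
    uncoverable: list[str] = []
    for rid in sorted(rows):
        _, violation = _feasibility([rows[rid].upper()], rules)
        if violation is None:
            designable[rid] = rows[rid]
        else:
            uncoverable.append(rid)
    ids = sorted(designable)
    if not ids:
        return PrimerMix(name=mix_name, variants=[], uncoverable=uncoverable)
    if len(ids) <= exact_limit:
        groups = _exact_partition(ids, designable, rules)
    else:
        groups = _greedy_partition(ids, designable, rules)
    variants = []
    for group in groups:
        v = minimal_variant_for_group(
            {g: designable[g] for g in group}, rules, panel=rows
        )
        variants.append(v)
    variants.sort(key=lambda v: (-len(v.covered_ids), v.seq.bases))
    for k, v in enumerate(variants, 1):
        name = f"{name_prefix}{k}"
        v.name = name
        v.seq = DegenerateSequence(v.seq.bases, name=name)
        v.qc.name = name
    return PrimerMix(name=mix_name, variants=variants, uncoverable=uncoverable)


# ---------------------------------------------------------------------------
# Relaxation (mix B)
# ---------------------------------------------------------------------------


def relax_variant(
    v: PrimerVariant,
    targets: dict[str, str],
    rules: DesignRules | None = None,
    suffix: str = "n",
) -> PrimerVariant:
    """Add exactly one degenerate position to maximize coverage gain.

    Considers every concrete position not adjacent to an existing degenerate
    one, widening it only to bases observed (at that position) in targets
    that mismatch the variant there and nowhere else.  Returns `v` unchanged
    when no single widening gains coverage; raises when `v` is already at
    the degeneracy limit.  Coverage never decreases.
    """
    rules = rules or DesignRules()
    if v.n_degenerate >= rules.max_degenerate:
        raise InfeasibleGroup("at degeneracy limit")
    seq = v.seq.bases
    deg_pos = set(degenerate_positions(v.seq))
    uncovered = {rid: s.upper() for rid, s in targets.items() if rid not in v.covered_ids}
    best = None  # (gain, -extra_bases, position, code) maximization
    for p in range(len(seq)):
        if p in deg_pos or (p - 1) in deg_pos or (p + 1) in deg_pos:
            continue
        # targets that would match if position p were widened to their base
        gain_bases: dict[str, list[str]] = {}
        for rid, s in uncovered.items():
            if len(s) != len(seq):
                continue
            if all(i == p or s[i] in IUPAC_CODES[seq[i]] for i in range(len(seq))):
                gain_bases.setdefault(s[p], []).append(rid)
        if not gain_bases:
            continue
        observed = frozenset(gain_bases) | IUPAC_CODES[seq[p]]
        code = SET_TO_CODE[observed]
        cand = DegenerateSequence(seq[:p] + code + seq[p + 1 :])
        tlo, thi = tm_range(cand)
        _, ghi = gc_range(cand)
        if tlo < rules.tm_min or thi > rules.tm_max or ghi >= rules.gc_max:
            # widening to all observed bases breaks thermo QC; try single bases
            options = [
                (frozenset({b}) | IUPAC_CODES[seq[p]], [b]) for b in gain_bases
            ]
        else:
            options = [(observed, sorted(gain_bases))]
        for opt_set, _ in options:
            code = SET_TO_CODE[opt_set]
            cand = DegenerateSequence(seq[:p] + code + seq[p + 1 :])
            tlo, thi = tm_range(cand)
            _, ghi = gc_range(cand)
            if tlo < rules.tm_min or thi > rules.tm_max or ghi >= rules.gc_max:
                continue
            gain = sum(len(gain_bases[b]) for b in opt_set & frozenset(gain_bases))
            key = (-gain, len(opt_set), p, code)
            if best is None or key < best[0]:
                best = (key, p, code)
    if best is None or -best[0][0] <= 0:
        return v
    _, p, code = best
    new_seq = DegenerateSequence(seq[:p] + code + seq[p + 1 :], name=v.name + suffix)
    return PrimerVariant(
        name=v.name + suffix,
        seq=new_seq,
        covered_ids=coverage_of(new_seq, targets),
        qc=qc_primer(new_seq, rules),
        group_ids=v.group_ids,
    )


def relaxed_mix(
    mix: PrimerMix,
    targets: dict[str, str],
    rules: DesignRules | None = None,
    mix_name: str | None = None,
    suffix: str = "n",
) -> PrimerMix:
    """The mix-B counterpart: each variant relaxed where a relaxation gains."""
    rules = rules or DesignRules()
    out = []
    for v in mix.variants:
        if v.n_degenerate < rules.max_degenerate:
            out.append(relax_variant(v, targets, rules, suffix=suffix))
        else:
            out.append(v)
    return PrimerMix(
        name=mix_name or (mix.name + "_relaxed"),
        variants=out,
        uncoverable=list(mix.uncoverable),
    )


def variant_from_oligo(
    oligo: DegenerateSequence,
    targets: dict[str, str],
    rules: DesignRules | None = None,
) -> PrimerVariant:
    """Wrap an existing oligo (e.g. a primer-table row) as a PrimerVariant,
    evaluating its coverage and QC against a target window panel."""
    rules = rules or DesignRules()
    return PrimerVariant(
        name=oligo.name,
        seq=oligo,
        covered_ids=coverage_of(oligo, targets),
        qc=qc_primer(oligo, rules),
    )


def spacing_score(v: PrimerVariant | DegenerateSequence) -> int:
    """Minimal distance between degenerate positions (larger is better).

    With fewer than two degenerate positions there is nothing to space out;
    the sequence length is returned as the sentinel maximum (no genuine
    pairwise distance can reach it).
    """
    seq = v.seq if isinstance(v, PrimerVariant) else v
    pos = degenerate_positions(seq)
    if len(pos) < 2:
        return len(seq)
    return min(b - a for a, b in zip(pos, pos[1:]))


def mix_table(
    mixes: list[PrimerMix],
    region_start: int = 0,
    region_end: int = 0,
    orientation: str = "fw",
) -> pd.DataFrame:
    """IDT-style primer table (5'->3' sequences) for one or more mixes.

    Variants shared by several mixes appear once with a semicolon-separated
    `mix` field.
    """
    rows: dict[str, dict] = {}
    for mix in mixes:
        for v in mix.variants:
            if v.name in rows and rows[v.name]["sequence"] == v.seq.bases:
                rows[v.name]["mix"] += ";" + mix.name
            else:
                rows[v.name] = {
                    "name": v.name,
                    "sequence": v.seq.bases,
                    "region_start": region_start,
                    "region_end": region_end,
                    "orientation": orientation,
                    "mix": mix.name,
                }
    return pd.DataFrame(list(rows.values()))
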
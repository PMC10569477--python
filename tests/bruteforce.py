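"""Independent brute-force oracles used across the test suite.

Each oracle restates the operation's definition as directly as possible
(exhaustive enumeration, sliding windows, set-partition search) without
sharing code paths with the implementation under test.
"""

from __future__ import annotations

import itertools
from collections import Counter

# Independent copy of the standard IUPAC ambiguity table (reference data).
CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def expansions(primer: str) -> list[str]:
    return ["".join(p) for p in itertools.product(*(CODES[c] for c in primer))]


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def bf_match_hits(
    primer: str, template: str, max_mm: int = 0, three_exact: int = 0
) -> set[tuple[str, int, int]]:
    """All (strand, start, end) placements, 1-based inclusive, by full
    expansion x sliding-window scan.  N in the template matches nothing."""
    hits = set()
    m = len(primer)
    for exp in expansions(primer):
        for strand, probe in (("+", exp), ("-", revcomp(exp))):
            for off in range(len(template) - m + 1):
                seg = template[off : off + m]
                mm = [k for k in range(m) if seg[k] != probe[k]]
                if len(mm) > max_mm:
                    continue
                # 3' end of the primer: right end on +, left end on -
                if strand == "+" and any(k >= m - three_exact for k in mm):
                    continue
                if strand == "-" and any(k < three_exact for k in mm):
                    continue
                hits.add((strand, off + 1, off + m))
    return hits


def bf_hairpins(seq: str, stem_min: int, loop_min: int) -> list[tuple[int, int, int]]:
    """Exhaustive O(n^3) hairpin scan on a concrete sequence."""
    n = len(seq)
    out = []
    for i in range(n):
        for stem in range(stem_min, n + 1):
            for loop in range(loop_min, n + 1):
                j = i + stem + loop
                if j + stem > n:
                    continue
                if seq[j : j + stem] == revcomp(seq[i : i + stem]):
                    out.append((i, stem, loop))
    return out


def bf_dimer_runs(a: str, b: str) -> tuple[int, int]:
    """Longest complementary run of a (5'->3') against b (3'->5')."""
    rb = b[::-1]
    best = best3 = 0
    for off in range(-(len(rb) - 1), len(a)):
        run = 0
        for i in range(len(a)):
            j = i - off
            if 0 <= j < len(rb) and COMP[a[i]] == rb[j]:
                run += 1
                best = max(best, run)
                if i == len(a) - 1:
                    best3 = max(best3, run)
            else:
                run = 0
    return best, best3


def bf_consensus(rows: list[str]) -> str:
    inv = {frozenset(v): k for k, v in CODES.items()}
    return "".join(inv[frozenset(col)] for col in zip(*rows))


def bf_feasible(rows: list[str], max_deg: int = 4) -> bool:
    """Degeneracy-rule + Tm/GC feasibility, restated from the definitions."""
    cons = bf_consensus(rows)
    n = len(cons)
    if not 17 <= n <= 22:
        return False
    deg = [i for i, c in enumerate(cons) if len(CODES[c]) > 1]
    if len(deg) > max_deg:
        return False
    if any(b - a == 1 for a, b in zip(deg, deg[1:])):
        return False
    gcs = [sum(1 for x in e if x in "GC") for e in expansions(cons)] if len(deg) <= 6 else None
    if gcs is None:  # positions independent: bound by per-position extremes
        lo = sum(1 for c in cons if set(CODES[c]) <= set("GC"))
        hi = sum(1 for c in cons if set(CODES[c]) & set("GC"))
        gcs = [lo, hi]
    tms = [64.9 + 41.0 * (gc - 16.4) / n if n >= 14 else 2.0 * (n - gc) + 4.0 * gc
           for gc in (min(gcs), max(gcs))]
    if min(tms) < 50 or max(tms) > 65:
        return False
    if max(gcs) / n >= 0.50:
        return False
    return True


def set_partitions(items: list):
    """All set partitions (standard recursive enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def bf_optimal_partition_size(rows: dict[str, str], max_deg: int = 4) -> int:
    best = None
    ids = sorted(rows)
    for part in set_partitions(ids):
        if best is not None and len(part) >= best:
            continue
        if all(bf_feasible([rows[i] for i in group], max_deg) for group in part):
            best = len(part)
    return best


def bf_bipartitions(newick_tree) -> set[frozenset]:
    """Non-trivial splits of an skbio TreeNode, canonical by reference leaf."""
    tips = sorted(t.name for t in newick_tree.tips())
    ref, all_tips = tips[0], frozenset(tips)
    out = set()
    for node in newick_tree.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(t.name for t in node.tips())
        side = clade if ref not in clade else all_tips - clade
        if 2 <= len(side) <= len(tips) - 2:
            out.add(side)
    return out
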
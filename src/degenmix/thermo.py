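"""Composition-based thermodynamic and secondary-structure primer QC.

Melting temperatures come from the two classic composition formulas
(no salt correction, no nearest-neighbour thermodynamics):

* Wallace rule (short oligos, < 14 nt):    Tm = 2·(A+T) + 4·(G+C)
* basic long-oligo formula (>= 14 nt):     Tm = 64.9 + 41·(GC − 16.4) / L

Hairpin and dimer screening is alignment-free complementary-run counting
(the string check an oligo calculator performs), not free-energy folding.
For a degenerate oligo every statistic is reported over its expansion pool:
Tm and GC as [min, max], homopolymer runs and complementarity as the
worst case any expansion (or pair of pool members) can realize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    DegenerateSequence,
    DesignRules,
    IUPAC_CODES,
    SequenceError,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def gc_fraction(seq: str) -> float:
    """(G+C)/length of a concrete sequence."""
    seq = seq.upper()
    if not seq:
        raise SequenceError("empty sequence")
    if any(b not in "ACGT" for b in seq):
        raise SequenceError("gc_fraction requires a concrete A/C/G/T sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _gc_count_range(seq: DegenerateSequence) -> tuple[int, int]:
    """Min and max G+C count over all expansions (positions independent)."""
    lo = hi = 0
    for b in seq.bases:
        opts = IUPAC_CODES[b]
        gc = {x in "GC" for x in opts}
        lo += gc == {True}
        hi += True in gc
    return lo, hi


def gc_range(seq: DegenerateSequence | str) -> tuple[float, float]:
    """[min, max] GC fraction over the expansions of a degenerate oligo."""
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    if len(seq) == 0:
        raise SequenceError("empty sequence")
    lo, hi = _gc_count_range(seq)
    return lo / len(seq), hi / len(seq)


def melting_temperature(seq: str, method: str = "auto") -> float:
    """Tm (°C) of a concrete sequence by composition formula.

    `method` is one of ``wallace``, ``basic_long`` or ``auto`` (Wallace for
    < 14-mers, long-oligo formula otherwise).  Sequences shorter than 8 nt
    are rejected as unreliable.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise SequenceError(f"sequence too short for a Tm estimate ({len(seq)} < 8)")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at != len(seq):
        raise SequenceError("melting_temperature requires a concrete A/C/G/T sequence")
    if method == "auto":
        method = "wallace" if len(seq) < 14 else "basic_long"
    if method == "wallace":
        return 2.0 * at + 4.0 * gc
    if method == "basic_long":
        return 64.9 + 41.0 * (gc - 16.4) / len(seq)
    raise ValueError(f"unknown Tm method {method!r}")


def tm_range(seq: DegenerateSequence | str, method: str = "auto") -> tuple[float, float]:
    """[min, max] Tm over all expansions of a degenerate oligo.

    Both formulas are monotone increasing in GC count at fixed length, so
    the extremes are attained at the GC-poorest and GC-richest expansions.
    """
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    if len(seq) < 8:
        raise SequenceError(f"sequence too short for a Tm estimate ({len(seq)} < 8)")
    lo, hi = _gc_count_range(seq)
    if method == "auto":
        method = "wallace" if len(seq) < 14 else "basic_long"
    if method == "wallace":
        f = lambda gc: 2.0 * (len(seq) - gc) + 4.0 * gc
    elif method == "basic_long":
        f = lambda gc: 64.9 + 41.0 * (gc - 16.4) / len(seq)
    else:
        raise ValueError(f"unknown Tm method {method!r}")
    return f(lo), f(hi)


def longest_homopolymer(seq: DegenerateSequence | str) -> int:
    """Longest homopolymer run any expansion can realize.

    Dynamic programme over positions: a run of base X continues wherever X
    is among the position's allowed bases.
    """
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    best = 0
    run = {b: 0 for b in "ACGT"}
    for code in seq.bases:
        opts = IUPAC_CODES[code]
        for b in "ACGT":
            run[b] = run[b] + 1 if b in opts else 0
        best = max(best, max(run.values()))
    return best


def _can_pair(code_a: str, code_b: str) -> bool:
    """True if some expansion of code_a Watson-Crick pairs some of code_b."""
    return any(_COMP[x] in IUPAC_CODES[code_b] for x in IUPAC_CODES[code_a])


def find_hairpins(
    seq: DegenerateSequence | str, stem_min: int = 4, loop_min: int = 3
) -> list[tuple[int, int, int]]:
    """All potential hairpin sites (stem_start, stem_len, loop_len).

    A hairpin is an upstream stem ``seq[i : i+L]`` reverse-complementary to a
    downstream stem, separated by a loop of at least `loop_min` unpaired
    bases.  `stem_start` is 0-based.  For degenerate oligos the check is
    whether *some* expansion can fold.
    """
    if stem_min < 3:
        raise ValueError("stem_min must be >= 3")
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    s = seq.bases
    n = len(s)
    hits = []
    for i in range(n):
        for stem_len in range(stem_min, (n - i) // 2 + 1):
            for loop_len in range(loop_min, n - i - 2 * stem_len + 1):
                j = i + stem_len + loop_len  # downstream stem start
                # stem1 position i+k pairs stem2 position j+stem_len-1-k
                if all(
                    _can_pair(s[i + k], s[j + stem_len - 1 - k])
                    for k in range(stem_len)
                ):
                    hits.append((i, stem_len, loop_len))
    return hits


def dimer_runs(
    a: DegenerateSequence | str, b: DegenerateSequence | str
) -> tuple[int, int]:
    """(max_run, max_3prime_run) of contiguous complementarity between a and b.

    The duplex geometry is a 5'->3' against b 3'->5' (i.e. b reversed), slid
    over every ungapped offset.  `max_run` is the longest contiguous run of
    Watson-Crick pairs anywhere; `max_3prime_run` only counts runs covering
    the 3'-terminal base of `a`.  Self-dimerisation is ``dimer_runs(a, a)``.
    """
    if isinstance(a, str):
        a = DegenerateSequence(a)
    if isinstance(b, str):
        b = DegenerateSequence(b)
    sa, rb = a.bases, b.bases[::-1]
    na, nb = len(sa), len(rb)
    max_run = 0
    max_3p = 0
    for off in range(-(nb - 1), na):
        run = 0
        i0 = max(0, off)
        i1 = min(na, off + nb)
        for i in range(i0, i1):
            if _can_pair(sa[i], rb[i - off]):
                run += 1
                max_run = max(max_run, run)
                if i == na - 1:
                    max_3p = max(max_3p, run)
            else:
                run = 0
    return max_run, max_3p


@dataclass
class QCReport:
    """Per-primer QC statistics and pass/fail flags for each guideline."""

    name: str
    length: int
    tm_min: float
    tm_max: float
    gc_min: float
    gc_max: float
    longest_homopolymer: int
    hairpins: list[tuple[int, int, int]]
    max_self_dimer_run: int
    max_3prime_dimer_run: int
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.flags.values())

    def as_row(self) -> dict:
        row = {
            "name": self.name,
            "length": self.length,
            "tm_min": round(self.tm_min, 2),
            "tm_max": round(self.tm_max, 2),
            "gc_min": round(self.gc_min, 3),
            "gc_max": round(self.gc_max, 3),
            "longest_homopolymer": self.longest_homopolymer,
            "n_hairpins": len(self.hairpins),
            "max_self_dimer_run": self.max_self_dimer_run,
            "max_3prime_dimer_run": self.max_3prime_dimer_run,
        }
        row.update(self.flags)
        row["verdict"] = "pass" if self.passed else "fail"
        return row

    def __str__(self) -> str:
        lines = [f"QC report for {self.name or '<unnamed>'} ({self.length} nt)"]
        lines.append(f"  Tm  [{self.tm_min:.2f}, {self.tm_max:.2f}] degC")
        lines.append(f"  GC  [{self.gc_min:.3f}, {self.gc_max:.3f}]")
        lines.append(f"  longest homopolymer: {self.longest_homopolymer}")
        lines.append(f"  hairpins: {self.hairpins or 'none'}")
        lines.append(
            f"  self-dimer run {self.max_self_dimer_run}"
            f" (3'-anchored {self.max_3prime_dimer_run})"
        )
        for k, v in self.flags.items():
            lines.append(f"  {k}: {'pass' if v else 'FAIL'}")
        lines.append(f"  verdict: {'pass' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def qc_primer(
    variant: DegenerateSequence | str,
    rules: DesignRules | None = None,
    tm_method: str = "auto",
) -> QCReport:
    """Screen one (possibly degenerate) primer against every guideline.

    Failures are reported in the flags, never raised: a candidate that
    breaks a guideline is a legitimate result of the scan.
    """
    if isinstance(variant, str):
        variant = DegenerateSequence(variant)
    rules = rules or DesignRules()
    n = len(variant)
    try:
        tlo, thi = tm_range(variant, method=tm_method)
    except SequenceError:
        tlo = thi = math.nan
    glo, ghi = gc_range(variant)
    poly = longest_homopolymer(variant)
    pins = find_hairpins(variant, rules.hairpin_stem_min, rules.hairpin_loop_min)
    self_run, self_3p = dimer_runs(variant, variant)
    flags = {
        "length_ok": rules.primer_len_min <= n <= rules.primer_len_max,
        "tm_ok": (not math.isnan(tlo)) and tlo >= rules.tm_min and thi <= rules.tm_max,
        "gc_ok": ghi < rules.gc_max,
        "polyN_ok": poly <= rules.polyN_max_run,
        "hairpin_ok": not pins,
        "dimer_ok": self_3p < rules.dimer_run_max,
    }
    return QCReport(
        name=variant.name,
        length=n,
        tm_min=tlo,
        tm_max=thi,
        gc_min=glo,
        gc_max=ghi,
        longest_homopolymer=poly,
        hairpins=pins,
        max_self_dimer_run=self_run,
        max_3prime_dimer_run=self_3p,
        flags=flags,
    )


def qc_table(
    variants: list[DegenerateSequence], rules: DesignRules | None = None
) -> pd.DataFrame:
    """QC reports for a list of primers as a TSV-ready table."""
    return pd.DataFrame([qc_primer(v, rules).as_row() for v in variants])
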
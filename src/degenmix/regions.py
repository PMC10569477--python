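"""Find and pair candidate primer-binding windows in a marker-gene alignment.

A binding region is a gap-free alignment window of primer length (17-22
columns by default) whose columns are well conserved and whose majority-base
consensus passes the thermodynamic QC.  Forward and reverse windows are then
paired to maximize the spanned product, subject to the paired-Tm guideline.

Coordinates in every report are 1-based inclusive alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import Alignment, DegenerateSequence, DesignRules, SequenceError, reverse_complement
from .thermo import QCReport, qc_primer

logger = logging.getLogger(__name__)


@dataclass
class ColumnStats:
    majority_base: str
    majority_fraction: float
    has_gap: bool


def column_conservation(aln: Alignment) -> list[ColumnStats]:
    """Per-column majority base and its fraction among all rows.

    Ties are broken alphabetically (A < C < G < T); the fraction denominator
    is the total row count, so gaps and ambiguity codes dilute conservation.
    """
    stats = []
    n = aln.n_rows
    for j in range(aln.n_columns):
        col = aln.column(j)
        counts = {b: 0 for b in "ACGT"}
        for c in col:
            if c in counts:
                counts[c] += 1
        best = max("ACGT", key=lambda b: (counts[b], -ord(b)))
        stats.append(
            ColumnStats(
                majority_base=best if counts[best] else "N",
                majority_fraction=counts[best] / n,
                has_gap=aln.gap in col,
            )
        )
    return stats


@dataclass
class CandidateRegion:
    """An alignment window eligible as a primer-binding region."""

    start: int  # 1-based inclusive alignment column
    end: int
    orientation: str  # "fw" | "rv"
    mean_conservation: float
    gap_free: bool
    consensus: DegenerateSequence  # majority-base consensus, rv: minus strand oligo
    qc: QCReport

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def scan_windows(
    aln: Alignment, rules: DesignRules | None = None, orientation: str = "fw"
) -> list[CandidateRegion]:
    """All windows satisfying the binding-region guidelines.

    A window is emitted iff it is gap-free in every row, its mean per-column
    majority fraction reaches the conservation threshold, and its
    majority-base consensus (reverse-complemented first for ``rv``, since
    the synthesized oligo is the minus-strand primer) passes `qc_primer`.
    Sorted by mean conservation descending, then leftmost first.
    """
    rules = rules or DesignRules()
    if orientation not in ("fw", "rv"):
        raise ValueError(f"orientation must be fw or rv, got {orientation!r}")
    if aln.n_columns < rules.primer_len_min:
        raise SequenceError(
            f"alignment has {aln.n_columns} columns; "
            f"need at least {rules.primer_len_min}"
        )
    stats = column_conservation(aln)
    out: list[CandidateRegion] = []
    for start in range(aln.n_columns):
        for length in range(rules.primer_len_min, rules.primer_len_max + 1):
            end = start + length  # 0-based half-open
            if end > aln.n_columns:
                break
            win = stats[start:end]
            if any(s.has_gap for s in win):
                continue
            mean_cons = sum(s.majority_fraction for s in win) / length
            if mean_cons < rules.conservation_threshold:
                continue
            consensus = DegenerateSequence("".join(s.majority_base for s in win))
            if orientation == "rv":
                consensus = reverse_complement(consensus)
            qc = qc_primer(consensus, rules)
            if not qc.passed:
                continue
            out.append(
                CandidateRegion(
                    start=start + 1,
                    end=end,
                    orientation=orientation,
                    mean_conservation=mean_cons,
                    gap_free=True,
                    consensus=consensus,
                    qc=qc,
                )
            )
    out.sort(key=lambda r: (-r.mean_conservation, r.start, r.end))
    return out


@dataclass
class RegionPair:
    fw: CandidateRegion
    rv: CandidateRegion
    product_span: int  # alignment columns, rv.end - fw.start + 1
    tm_delta: float


def _consensus_tm(region: CandidateRegion) -> float:
    # majority-base consensus is concrete, so the QC extremes coincide
    return (region.qc.tm_min + region.qc.tm_max) / 2.0


def pair_regions(
    fw: list[CandidateRegion],
    rv: list[CandidateRegion],
    rules: DesignRules | None = None,
    min_product: int = 400,
) -> list[RegionPair]:
    """All admissible forward/reverse window pairs, largest product first.

    Admissible: forward entirely upstream of reverse, spanned product at
    least `min_product` alignment columns, consensus Tm difference within
    the paired-primer tolerance.
    """
    rules = rules or DesignRules()
    rejections = {"order": 0, "min_product": 0, "tm_delta": 0}
    pairs: list[RegionPair] = []
    for f in fw:
        for r in rv:
            if not f.end < r.start:
                rejections["order"] += 1
                continue
            span = r.end - f.start + 1
            if span < min_product:
                rejections["min_product"] += 1
                continue
            delta = abs(_consensus_tm(f) - _consensus_tm(r))
            if delta > rules.pair_tm_delta_max:
                rejections["tm_delta"] += 1
                continue
            pairs.append(RegionPair(fw=f, rv=r, product_span=span, tm_delta=delta))
    if not pairs:
        for reason, count in rejections.items():
            if count:
                logger.warning("pair_regions: %d pairs rejected (%s)", count, reason)
    pairs.sort(key=lambda p: (-p.product_span, p.fw.start, p.rv.start))
    return pairs


def regions_table(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Candidate windows as a TSV-ready table (1-based inclusive columns)."""
    return pd.DataFrame(
        [
            {
                "start": r.start,
                "end": r.end,
                "orientation": r.orientation,
                "length": r.length,
                "mean_conservation": round(r.mean_conservation, 4),
                "consensus": str(r.consensus),
                "tm": round(_consensus_tm(r), 2),
                "qc_verdict": "pass" if r.qc.passed else "fail",
            }
            for r in regions
        ]
    )


def pairs_table(pairs: list[RegionPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fw_start": p.fw.start,
                "fw_end": p.fw.end,
                "rv_start": p.rv.start,
                "rv_end": p.rv.end,
                "product_span": p.product_span,
                "tm_delta": round(p.tm_delta, 2),
            }
            for p in pairs
        ]
    )
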
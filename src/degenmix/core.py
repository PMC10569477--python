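"""IUPAC sequence algebra and the shared domain types.

Degenerate oligonucleotides are written over the 15-letter IUPAC alphabet
(A, C, G, T plus the 11 ambiguity codes).  A degenerate primer is synthesized
as the equimolar mixture of all its concrete expansions, so its *degeneracy*
(the number of expansions) is the product of the per-position code sizes.

Coordinate convention: all user-facing coordinates are 1-based inclusive
(matching the usual "112..131" notation for alignment regions); internal
indexing is 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse map: observed base set -> minimal IUPAC code.
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

GAP = "-"


class SequenceError(ValueError):
    """Raised for malformed sequences, alignments or tables."""


def _normalize(bases: str) -> str:
    """Upper-case and map RNA-style U to T."""
    return bases.upper().replace("U", "T")


@dataclass(frozen=True)
class DegenerateSequence:
    """A nucleotide string over the IUPAC alphabet, with degeneracy accounting.

    Parameters
    ----------
    bases:
        Sequence letters; case-insensitive on input, stored upper-case.
        ``U`` is accepted and mapped to ``T``.
    name:
        Optional identifier (primer name, template id).
    """

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        norm = _normalize(self.bases)
        for i, b in enumerate(norm):
            if b not in IUPAC_CODES:
                raise SequenceError(
                    f"invalid IUPAC character {b!r} at position {i + 1}"
                    + (f" in {self.name!r}" if self.name else "")
                )
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __iter__(self):
        return iter(self.bases)

    @property
    def degeneracy(self) -> int:
        """Number of concrete sequences this oligo represents."""
        d = 1
        for b in self.bases:
            d *= len(IUPAC_CODES[b])
        return d

    def expand(self) -> set[str]:
        """All concrete {A,C,G,T} sequences obtainable from this oligo."""
        pools = [sorted(IUPAC_CODES[b]) for b in self.bases]
        return {"".join(p) for p in itertools.product(*pools)}

    def matches(self, concrete: str) -> bool:
        """True if `concrete` (over A/C/G/T) is one of the expansions.

        Position-wise containment check; avoids enumerating expansions.
        An ``N`` in `concrete` never matches (strict template policy lives
        in :mod:`degenmix.ispcr`; here N-in-template is simply not a base).
        """
        if len(concrete) != len(self.bases):
            return False
        return all(c in IUPAC_CODES[b] for b, c in zip(self.bases, concrete))


def expand_degenerate(seq: DegenerateSequence | str) -> set[str]:
    """Expand a degenerate sequence into its set of concrete sequences."""
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    return seq.expand()


def count_degenerate_positions(seq: DegenerateSequence | str) -> int:
    """Number of positions whose IUPAC code stands for more than one base."""
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    return sum(1 for b in seq.bases if len(IUPAC_CODES[b]) > 1)


def degenerate_positions(seq: DegenerateSequence | str) -> list[int]:
    """0-based indices of the degenerate positions."""
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    return [i for i, b in enumerate(seq.bases) if len(IUPAC_CODES[b]) > 1]


def reverse_complement(seq: DegenerateSequence | str) -> DegenerateSequence:
    """IUPAC-aware reverse complement (an involution)."""
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    rc = seq.bases.translate(_COMPLEMENT)[::-1]
    return DegenerateSequence(rc, name=seq.name)


def consensus_degenerate(
    columns: Sequence[Iterable[str]], name: str = ""
) -> DegenerateSequence:
    """Minimal degenerate consensus of per-column base sets.

    Each column is the set of concrete bases observed there; the consensus
    letter is the unique IUPAC code whose expansion equals that set exactly
    (never wider than the data).
    """
    letters = []
    for j, col in enumerate(columns):
        s = frozenset(_normalize("".join(col)))
        if not s:
            raise SequenceError(f"empty base set at column {j + 1}")
        if not s <= IUPAC_CODES["N"]:
            raise SequenceError(f"non-concrete bases {sorted(s)} at column {j + 1}")
        letters.append(SET_TO_CODE[s])
    return DegenerateSequence("".join(letters), name=name)


# ---------------------------------------------------------------------------
# Records and alignments
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named sequence (template gene, genome contig, or primer)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        self.seq = _normalize(self.seq)
        DegenerateSequence(self.seq, name=self.id)  # validation only

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """A gapped multiple sequence alignment (rows of equal length).

    Rows may contain the gap character ``-``; primers and templates may not.
    """

    records: list[SequenceRecord]
    gap: str = GAP

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError("alignment has no rows")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate record ids: {dupes}")
        n = len(self.records[0].seq)
        ragged = [r.id for r in self.records if len(r.seq) != n]
        if ragged:
            raise SequenceError(f"ragged alignment; offending ids: {ragged}")

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].seq)

    def column(self, j: int) -> list[str]:
        """Bases (incl. gaps) of 0-based column j, in row order."""
        return [r.seq[j] for r in self.records]

    def window(self, start: int, end: int) -> list[str]:
        """Row slices for 0-based half-open column range [start, end)."""
        return [r.seq[start:end] for r in self.records]

    def ungap_row(self, row_id: str) -> str:
        for r in self.records:
            if r.id == row_id:
                return r.seq.replace(self.gap, "")
        raise KeyError(row_id)


# Alignment rows may legitimately contain '-', which DegenerateSequence
# rejects; patch validation by pre-stripping gaps for the check.
def _validate_row(seq: str, rid: str) -> str:
    seq = _normalize(seq)
    for i, b in enumerate(seq):
        if b != GAP and b not in IUPAC_CODES:
            raise SequenceError(f"invalid character {b!r} at position {i + 1} in {rid!r}")
    return seq


@dataclass
class _AlignedRecord(SequenceRecord):
    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        self.seq = _validate_row(self.seq, self.id)


# ---------------------------------------------------------------------------
# Design thresholds
# ---------------------------------------------------------------------------


@dataclass
class DesignRules:
    """All numeric thresholds of the primer-design guidelines in one record.

    Binding-region guidelines: length 17-22 bp, Tm 50-65 °C, GC < 50 %,
    no long homopolymers, no hairpin/dimer-prone self-complementarity,
    paired regions within ±4 °C.  Degeneracy rules: at most `max_degenerate`
    degenerate positions per primer, never consecutive, as far apart as
    possible, and as few as possible.
    """

    primer_len_min: int = 17
    primer_len_max: int = 22
    tm_min: float = 50.0
    tm_max: float = 65.0
    gc_max: float = 0.50
    conservation_threshold: float = 0.75
    max_degenerate: int = 4
    pair_tm_delta_max: float = 4.0
    polyN_max_run: int = 4
    hairpin_stem_min: int = 4
    hairpin_loop_min: int = 3
    dimer_run_max: int = 4

    def __post_init__(self) -> None:
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("primer_len_min > primer_len_max")
        if not self.tm_min < self.tm_max:
            raise ValueError("tm_min must be < tm_max")
        if not 0 < self.conservation_threshold <= 1:
            raise ValueError("conservation_threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# FASTA and table I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (plain, ungapped) FASTA file into SequenceRecords."""
    records = [
        SequenceRecord(id=r.id, seq=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA ('-' gaps) and validate equal row lengths."""
    records = [
        _AlignedRecord(id=r.id, seq=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids(records)
    return Alignment(records)  # raises on ragged rows


def _check_unique_ids(records: list[SequenceRecord]) -> None:
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"duplicate record ids: {dupes}")


PRIMER_TABLE_COLUMNS = ["name", "sequence", "region_start", "region_end", "orientation", "mix"]


def read_primer_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV primer table.

    Required columns: name, sequence, region_start, region_end, orientation
    (fw|rv).  An optional `mix` column assigns each variant to one or more
    mixes (semicolon-separated); absent, the mix is the name prefix before
    the last underscore (Fw1_G3 -> Fw1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = PRIMER_TABLE_COLUMNS[:5]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SequenceError(f"primer table missing columns: {missing}")
    if "mix" not in df.columns:
        df["mix"] = [n.rsplit("_", 1)[0] for n in df["name"]]
    for s in df["sequence"]:
        DegenerateSequence(s)
    bad = df[~df["orientation"].isin(["fw", "rv"])]
    if len(bad):
        raise SequenceError(f"bad orientation values: {sorted(set(bad['orientation']))}")
    df["region_start"] = df["region_start"].astype(int)
    df["region_end"] = df["region_end"].astype(int)
    return df


def write_primer_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def mixes_from_table(df: pd.DataFrame) -> dict[str, list[DegenerateSequence]]:
    """Group a primer table into named mixes of degenerate oligos."""
    mixes: dict[str, list[DegenerateSequence]] = {}
    for _, row in df.iterrows():
        oligo = DegenerateSequence(row["sequence"], name=row["name"])
        for mix in str(row["mix"]).split(";"):
            mixes.setdefault(mix.strip(), []).append(oligo)
    return mixes
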
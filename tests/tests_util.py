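"""Small shared helpers for the test suite."""

from degenmix.core import Alignment, SequenceRecord


class _GapRecord(SequenceRecord):
    """Test-only record that tolerates '-' (alignment rows)."""

    def __post_init__(self):
        self.seq = self.seq.upper()


def aln_from_rows(rows, prefix="row"):
    return Alignment(
        [_GapRecord(id=f"{prefix}{i + 1:02d}", seq=s) for i, s in enumerate(rows)]
    )
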
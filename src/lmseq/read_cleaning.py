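"""Raw-read cleaning: N removal, 3' quality trimming, minimum length.

The rule set mirrors the pre-mapping cleaning used for single-end Illumina
reads from both total-mycelium and laser-microdissected libraries:

1. reads containing an undetermined base (``N``) are discarded outright
   (checked on the untrimmed sequence);
2. bases are trimmed from the 3' end while the terminal base quality is
   below ``min_q`` (strict suffix trimming — it stops at the first base at
   or above the threshold, even if lower-quality bases remain further 5');
3. reads longer than 20 bases after trimming are kept (``>= min_len_keep``
   with the default of 21).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io_formats import read_fastq, write_fastq
from .models import ReadRecord

DEFAULT_MIN_Q = 10
DEFAULT_MIN_LEN_KEEP = 21


@dataclass
class CleaningReport:
    """Tallies for one cleaning pass; input == kept + discarded_N + discarded_short."""

    input: int = 0
    kept: int = 0
    discarded_N: int = 0
    discarded_short: int = 0
    bases_trimmed: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "kept": self.kept,
            "discarded_N": self.discarded_N,
            "discarded_short": self.discarded_short,
            "bases_trimmed": self.bases_trimmed,
        }


def clean_read(
    record: ReadRecord,
    min_q: int = DEFAULT_MIN_Q,
    min_len_keep: int = DEFAULT_MIN_LEN_KEEP,
    report: Optional[CleaningReport] = None,
) -> Optional[ReadRecord]:
    """Clean one read; returns the (possibly trimmed) read or None if discarded.

    When ``report`` is given, the discard cause and trimmed-base count are
    tallied into it.
    """
    if report is not None:
        report.input += 1
    if "N" in record.sequence:
        if report is not None:
            report.discarded_N += 1
        return None
    end = len(record.qualities)
    while end > 0 and record.qualities[end - 1] < min_q:
        end -= 1
    if report is not None:
        report.bases_trimmed += len(record.qualities) - end
    if end < min_len_keep:
        if report is not None:
            report.discarded_short += 1
        return None
    if report is not None:
        report.kept += 1
    if end == len(record.sequence):
        return record
    return ReadRecord(
        read_id=record.read_id,
        sequence=record.sequence[:end],
        qualities=record.qualities[:end],
    )


def clean_fastq(
    path_in: str,
    path_out: str,
    min_q: int = DEFAULT_MIN_Q,
    min_len_keep: int = DEFAULT_MIN_LEN_KEEP,
) -> CleaningReport:
    """Clean a FASTQ file, writing kept reads and returning the tallies."""
    report = CleaningReport()

    def _kept():
        for record in read_fastq(path_in):
            cleaned = clean_read(record, min_q, min_len_keep, report)
            if cleaned is not None:
                yield cleaned

    write_fastq(_kept(), path_out)
    return report
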
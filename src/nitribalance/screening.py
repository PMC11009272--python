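"""Occurrence screening of amplicon read sets against a query 16S sequence.

A read counts as matching when it is longer than ``min_read_length_bp`` AND
its overlap-alignment identity to the query (best of both orientations)
exceeds ``min_identity_percent``. A sample is discarded when it has fewer
than ``min_matching_reads`` matches, and dropped from mapping when its
matching-read relative abundance does not exceed
``min_relative_abundance_percent``. All thresholds are strict inequalities
except the matching-read count (keep iff matches >= 10), mirroring how such
screens are usually phrased ("longer than 200 bp", ">95% identity",
"less than 10 matching reads were discarded", ">0.1% retained").
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ParameterError
from .guilds import AlignmentScoring, pairwise_identity

STATUS_RETAINED = "retained"
STATUS_LOW_HITS = "discarded_low_hits"
STATUS_BELOW_ABUNDANCE = "below_abundance"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class ScreeningThresholds:
    min_read_length_bp: int = 200          # reads must be longer than this
    min_identity_percent: float = 95.0     # identity must exceed this
    min_matching_reads: int = 10           # keep iff matches >= this
    min_relative_abundance_percent: float = 0.1  # abundance must exceed this

    def validate(self) -> None:
        for field in dataclasses.fields(self):
            if getattr(self, field.name) <= 0:
                raise ParameterError(f"{field.name} must be positive")


@dataclasses.dataclass
class SampleScreenResult:
    sample_id: str
    n_reads_total: int
    n_matching_reads: int
    relative_abundance_percent: float
    status: str


def load_reads(path: str | Path) -> list[tuple[str, str]]:
    """Load (id, sequence) pairs from FASTA or FASTQ (picked by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def _normalize(reads: Iterable) -> list[tuple[str, str]]:
    out = []
    for i, read in enumerate(reads):
        if isinstance(read, str):
            out.append((f"read_{i}", read))
        elif isinstance(read, tuple):
            out.append((str(read[0]), str(read[1])))
        else:  # SeqRecord
            out.append((read.id, str(read.seq)))
    return out


def screen_sample(
    reads: Iterable,
    query_16s: str,
    thresholds: ScreeningThresholds | None = None,
    sample_id: str = "sample",
    scoring: AlignmentScoring | None = None,
) -> SampleScreenResult:
    """Screen one sample's reads against the query 16S sequence.

    Reads failing the length cutoff are rejected without alignment; the rest
    are aligned in both orientations and the better identity is used. The
    result is independent of read order.
    """
    thresholds = thresholds or ScreeningThresholds()
    thresholds.validate()
    if not query_16s:
        raise ParameterError("query_16s must be a non-empty sequence")
    records = _normalize(reads)
    if not records:
        raise ParameterError(f"sample {sample_id!r}: empty read set")

    n_matching = 0
    for _, seq in records:
        if len(seq) <= thresholds.min_read_length_bp:
            continue
        fwd = pairwise_identity(seq, query_16s, scoring).identity_percent
        if fwd > thresholds.min_identity_percent:
            n_matching += 1
            continue
        rev = pairwise_identity(reverse_complement(seq), query_16s, scoring).identity_percent
        if rev > thresholds.min_identity_percent:
            n_matching += 1

    n_total = len(records)
    rel_percent = 100.0 * n_matching / n_total
    if n_matching < thresholds.min_matching_reads:
        status = STATUS_LOW_HITS
    elif rel_percent <= thresholds.min_relative_abundance_percent:
        status = STATUS_BELOW_ABUNDANCE
    else:
        status = STATUS_RETAINED
    return SampleScreenResult(
        sample_id=sample_id,
        n_reads_total=n_total,
        n_matching_reads=n_matching,
        relative_abundance_percent=rel_percent,
        status=status,
    )


def retain_for_mapping(results: Sequence[SampleScreenResult]) -> list[SampleScreenResult]:
    """Subset of samples retained for spatial mapping, in stable input order."""
    return [r for r in results if r.status == STATUS_RETAINED]
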
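"""ORF enumeration and the ribosome release score (RRS).

The RRS detects ribosome disassociation at the stop codon of a putative
coding region. A putative coding region (ORF) runs from an ATG to the first
in-frame stop codon, stop included; its putative 3'-UTR runs from the base
after the stop to the next ATG in any frame (or the transcript end). The
score is a ratio of ratios:

    RRS = (F_cds / F_utr) / (R_cds / R_utr)

with F the ribosome-footprint coverage sums and R the total-RNA coverage
sums over the CDS and 3'-UTR spans. High values indicate translation
(ribosomes drop off after the stop); bona fide noncoding transcripts score
near 1. Per transcript the maximum over all enumerated ORFs is reported.

Counting is per-position coverage sums; whether the original screen counted
reads by overlap or by 5'-end position is not specified upstream, so this
choice is documented rather than asserted as canonical.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .io_formats import TranscriptRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfCall:
    """ORF span on a transcript; ``cds_end`` is one past the stop codon."""

    transcript_id: str
    cds_start: int
    cds_end: int
    utr3_end: int

    def __post_init__(self) -> None:
        length = self.cds_end - self.cds_start
        if length < 6 or length % 3 != 0:
            raise ValueError(
                f"CDS length {length} must be >=6 and divisible by 3 "
                f"({self.transcript_id})"
            )
        if self.utr3_end < self.utr3_start:
            raise ValueError("utr3_end must be >= utr3_start")

    @property
    def utr3_start(self) -> int:
        return self.cds_end


@dataclass
class RibosomeProfile:
    """Per-position footprint and total-RNA counts on one transcript."""

    transcript_id: str
    footprint_counts: np.ndarray
    rna_counts: np.ndarray

    def __post_init__(self) -> None:
        self.footprint_counts = np.asarray(self.footprint_counts, dtype=np.int64)
        self.rna_counts = np.asarray(self.rna_counts, dtype=np.int64)
        if self.footprint_counts.shape != self.rna_counts.shape:
            raise ValueError("footprint and RNA tracks differ in length")
        if (self.footprint_counts < 0).any() or (self.rna_counts < 0).any():
            raise ValueError("coverage counts must be non-negative")

    def __len__(self) -> int:
        return int(self.footprint_counts.shape[0])


@dataclass
class RrsResult:
    """Per-ORF RRS values and their maximum for one transcript.

    ``max_rrs``/``best_orf`` are None when no ORF has a computable score.
    Ties at the maximum resolve to the 5'-most ORF.
    """

    transcript_id: str
    per_orf: List[Tuple[OrfCall, Optional[float]]]
    max_rrs: Optional[float]
    best_orf: Optional[OrfCall]

    @property
    def defined(self) -> bool:
        return self.max_rrs is not None


def enumerate_orfs(transcript: TranscriptRecord) -> List[OrfCall]:
    """Every ATG with a downstream in-frame stop yields one ORF call.

    Codons containing N never match start or stop codons. The 3'-UTR ends at
    the next ATG at any offset >= cds_end (any frame) or at the transcript
    end. Calls are sorted by cds_start.
    """
    seq = transcript.sequence
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    atg_positions = [i for i in range(n - 2) if seq[i : i + 3] == START_CODON]
    calls: List[OrfCall] = []
    for start in atg_positions:
        stop_end = None
        for j in range(start + 3, n - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                stop_end = j + 3
                break
        if stop_end is None:
            continue
        # next ATG in any frame at or after the stop; transcript end otherwise
        k = bisect_left(atg_positions, stop_end)
        utr3_end = atg_positions[k] if k < len(atg_positions) else n
        calls.append(
            OrfCall(
                transcript_id=transcript.id,
                cds_start=start,
                cds_end=stop_end,
                utr3_end=utr3_end,
            )
        )
    return calls


def compute_rrs(profile: RibosomeProfile, orf: OrfCall) -> Optional[float]:
    """RRS for one ORF, or None when undefined.

    Undefined (not an error) when the 3'-UTR span is empty or any of the
    coverage sums entering a denominator is zero. Spans beyond the profile
    raise instead.
    """
    if orf.utr3_end > len(profile):
        raise ValueError(
            f"ORF span [{orf.cds_start}, {orf.utr3_end}) exceeds profile "
            f"length {len(profile)}"
        )
    if orf.utr3_end == orf.utr3_start:
        return None
    fp, rna = profile.footprint_counts, profile.rna_counts
    f_cds = int(fp[orf.cds_start : orf.cds_end].sum())
    f_utr = int(fp[orf.utr3_start : orf.utr3_end].sum())
    r_cds = int(rna[orf.cds_start : orf.cds_end].sum())
    r_utr = int(rna[orf.utr3_start : orf.utr3_end].sum())
    if f_utr == 0 or r_utr == 0 or r_cds == 0:
        return None
    return (f_cds / f_utr) / (r_cds / r_utr)


def max_rrs(profile: RibosomeProfile, transcript: TranscriptRecord) -> RrsResult:
    """Score every enumerated ORF and report the maximum defined RRS."""
    per_orf: List[Tuple[OrfCall, Optional[float]]] = []
    best: Optional[float] = None
    best_orf: Optional[OrfCall] = None
    for orf in enumerate_orfs(transcript):
        score = compute_rrs(profile, orf)
        per_orf.append((orf, score))
        if score is not None and (best is None or score > best):
            best, best_orf = score, orf
    return RrsResult(
        transcript_id=transcript.id, per_orf=per_orf, max_rrs=best, best_orf=best_orf
    )
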
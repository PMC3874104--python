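"""The knockout-candidate filter cascade and the temporal induction filter.

Candidate lincRNAs pass, in order: (1) exclusion of loci overlapping any
non-lncRNA annotation (protein-coding genes, miRNAs, tRNAs, pseudogenes;
strand-agnostic, any >=1 bp overlap); (2) a codon-substitution-frequency
(CSF) cut keeping only strongly noncoding scores (strictly below -200);
(3) a mass-spectrometry cut keeping transcripts with at most two mapped
peptide tags; (4) a ribosome-release-score screen flagging candidates whose
best ORF scores like known coding genes; (5) boolean criteria (human
syntenic ortholog, active-transcription chromatin signature). CSF scores,
tag counts and chromatin/synteny flags are consumed as precomputed inputs —
computing them is upstream work, not this package's.

The temporal induction filter reproduces the neural-differentiation
time-course selection: genes significantly differentially expressed between
any two adjacent time points, and the subset also significantly induced
relative to day 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import ChromSizes, GenomicInterval

LNCRNA_BIOTYPES = frozenset({"lincRNA", "lncRNA", "lincrna", "lncrna"})

CSF_THRESHOLD = -200.0
MAX_MASSPEC_TAGS = 2
RRS_CODING_PERCENTILE = 5.0


@dataclass
class CandidateRecord:
    """One candidate lincRNA with the evidence the filters consume."""

    gene_id: str
    locus: GenomicInterval
    csf_score: Optional[float] = None
    masspec_tags: Optional[int] = None
    max_rrs: Optional[float] = None
    has_human_synteny: bool = False
    has_k4me3_k36me3: bool = False
    has_enhancer_signature: bool = False
    filter_trace: List[Tuple[str, str]] = field(default_factory=list)

    def record(self, filter_name: str, passed: bool) -> None:
        if any(name == filter_name for name, _ in self.filter_trace):
            raise ValueError(f"filter {filter_name!r} applied twice to {self.gene_id}")
        self.filter_trace.append((filter_name, "pass" if passed else "fail"))


Partition = Tuple[List[CandidateRecord], List[CandidateRecord]]


def filter_annotation_overlap(
    candidates: Sequence[CandidateRecord],
    annotations: Sequence[Tuple[GenomicInterval, str]],
    chrom_sizes: Optional[ChromSizes] = None,
) -> Partition:
    """Exclude candidates overlapping >=1 bp of any non-lncRNA annotation.

    Annotation names are biotype labels; lncRNA-type annotations never
    exclude. Overlap is strand-agnostic on half-open intervals, so abutting
    features do not collide. Candidates on a chromosome absent from both the
    annotation set and ``chrom_sizes`` are an error.
    """
    trees: Dict[str, IntervalTree] = {}
    known_chroms: Set[str] = set(chrom_sizes) if chrom_sizes else set()
    for iv, biotype in annotations:
        known_chroms.add(iv.chrom)
        if biotype in LNCRNA_BIOTYPES:
            continue
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept: List[CandidateRecord] = []
    excluded: List[CandidateRecord] = []
    for cand in candidates:
        if cand.locus.chrom not in known_chroms:
            raise ValueError(
                f"candidate {cand.gene_id!r} on unknown chromosome "
                f"{cand.locus.chrom!r}"
            )
        tree = trees.get(cand.locus.chrom)
        hit = bool(tree.overlap(cand.locus.start, cand.locus.end)) if tree else False
        cand.record("annotation_overlap", not hit)
        (excluded if hit else kept).append(cand)
    return kept, excluded


def filter_csf(
    candidates: Sequence[CandidateRecord], threshold: float = CSF_THRESHOLD
) -> Partition:
    """Keep candidates with CSF score strictly below the threshold.

    The boundary value itself is excluded (strict '<'); a missing score
    routes the candidate to excluded rather than erroring.
    """
    kept: List[CandidateRecord] = []
    excluded: List[CandidateRecord] = []
    for cand in candidates:
        ok = cand.csf_score is not None and cand.csf_score < threshold
        cand.record("csf", ok)
        (kept if ok else excluded).append(cand)
    return kept, excluded


def filter_masspec(
    candidates: Sequence[CandidateRecord], max_tags: int = MAX_MASSPEC_TAGS
) -> Partition:
    """Keep candidates with at most ``max_tags`` mass-spectrometry tags."""
    kept: List[CandidateRecord] = []
    excluded: List[CandidateRecord] = []
    for cand in candidates:
        if cand.masspec_tags is not None and cand.masspec_tags < 0:
            raise ValueError(f"negative mass-spec tag count for {cand.gene_id}")
        ok = cand.masspec_tags is not None and cand.masspec_tags <= max_tags
        cand.record("masspec", ok)
        (kept if ok else excluded).append(cand)
    return kept, excluded


def filter_rrs(
    candidates: Sequence[CandidateRecord],
    coding_rrs: Sequence[float],
    percentile: float = RRS_CODING_PERCENTILE,
) -> Partition:
    """Flag candidates whose max RRS looks coding-like.

    A candidate fails when its max RRS exceeds the given percentile of a
    user-supplied coding-gene RRS distribution (default 5th percentile, i.e.
    scoring above all but the bottom 5% of coding genes). An undefined RRS
    (no scoreable ORF) is kept: no evidence of translation.
    """
    coding_rrs = np.asarray(list(coding_rrs), dtype=float)
    if coding_rrs.size == 0:
        raise ValueError("coding RRS distribution is empty")
    cutoff = float(np.percentile(coding_rrs, percentile))
    kept: List[CandidateRecord] = []
    excluded: List[CandidateRecord] = []
    for cand in candidates:
        coding_like = cand.max_rrs is not None and cand.max_rrs > cutoff
        cand.record("rrs", not coding_like)
        (excluded if coding_like else kept).append(cand)
    return kept, excluded


def filter_boolean_criteria(
    candidates: Sequence[CandidateRecord],
    require_synteny: bool = True,
    require_chromatin: bool = True,
) -> Partition:
    """Keep candidates with the required human-synteny / chromatin flags.

    The enhancer-signature flag is descriptive (a feature of interest), not
    a pass/fail criterion.
    """
    kept: List[CandidateRecord] = []
    excluded: List[CandidateRecord] = []
    for cand in candidates:
        ok = (not require_synteny or cand.has_human_synteny) and (
            not require_chromatin or cand.has_k4me3_k36me3
        )
        cand.record("boolean_criteria", ok)
        (kept if ok else excluded).append(cand)
    return kept, excluded


@dataclass
class SelectionConfig:
    csf_threshold: float = CSF_THRESHOLD
    max_masspec_tags: int = MAX_MASSPEC_TAGS
    rrs_percentile: float = RRS_CODING_PERCENTILE
    require_synteny: bool = True
    require_chromatin: bool = True


def run_selection_pipeline(
    candidates: Sequence[CandidateRecord],
    annotations: Sequence[Tuple[GenomicInterval, str]],
    rrs_results: Dict[str, Optional[float]],
    coding_rrs: Sequence[float],
    config: Optional[SelectionConfig] = None,
    chrom_sizes: Optional[ChromSizes] = None,
) -> Tuple[List[CandidateRecord], pd.DataFrame]:
    """Full cascade: annotation -> CSF -> mass-spec -> RRS -> boolean flags.

    ``rrs_results`` maps every candidate gene id to its max RRS (None when
    undefined); missing ids are an error. Returns the surviving candidates
    and a per-filter attrition table; each candidate carries a trace of the
    filters actually applied to it (the cascade short-circuits, so a
    candidate failing CSF has no mass-spec entry). Because every filter is a
    pure predicate, cascade membership equals the intersection of the
    individual keeps.
    """
    cfg = config or SelectionConfig()
    missing = [c.gene_id for c in candidates if c.gene_id not in rrs_results]
    if missing:
        raise ValueError(f"candidates missing from rrs_results: {missing}")
    for cand in candidates:
        cand.max_rrs = rrs_results[cand.gene_id]

    attrition = []
    current = list(candidates)

    def stage(name: str, kept: List[CandidateRecord]) -> List[CandidateRecord]:
        attrition.append(
            {
                "filter": name,
                "n_in": len(current),
                "n_kept": len(kept),
                "n_excluded": len(current) - len(kept),
            }
        )
        return kept

    kept, _ = filter_annotation_overlap(current, annotations, chrom_sizes=chrom_sizes)
    current = stage("annotation_overlap", kept)
    kept, _ = filter_csf(current, threshold=cfg.csf_threshold)
    current = stage("csf", kept)
    kept, _ = filter_masspec(current, max_tags=cfg.max_masspec_tags)
    current = stage("masspec", kept)
    kept, _ = filter_rrs(current, coding_rrs, percentile=cfg.rrs_percentile)
    current = stage("rrs", kept)
    kept, _ = filter_boolean_criteria(
        current,
        require_synteny=cfg.require_synteny,
        require_chromatin=cfg.require_chromatin,
    )
    current = stage("boolean_criteria", kept)
    return current, pd.DataFrame(attrition)


# ---------------------------------------------------------------------------
# candidate-table TSV dialect
# ---------------------------------------------------------------------------

def read_candidates(path) -> List[CandidateRecord]:
    """Candidate TSV: gene_id, locus, csf_score, masspec_tags + flag columns."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "locus": str})
    for col in ("gene_id", "locus"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: List[CandidateRecord] = []
    for row in df.itertuples(index=False):
        chrom, span = getattr(row, "locus").split(":")
        start, end = (int(x) for x in span.split("-"))
        csf = getattr(row, "csf_score", None)
        tags = getattr(row, "masspec_tags", None)
        out.append(
            CandidateRecord(
                gene_id=str(getattr(row, "gene_id")),
                locus=GenomicInterval(chrom, start, end),
                csf_score=None if csf is None or pd.isna(csf) else float(csf),
                masspec_tags=None if tags is None or pd.isna(tags) else int(tags),
                has_human_synteny=bool(getattr(row, "has_human_synteny", False)),
                has_k4me3_k36me3=bool(getattr(row, "has_k4me3_k36me3", False)),
                has_enhancer_signature=bool(
                    getattr(row, "has_enhancer_signature", False)
                ),
            )
        )
    return out


def write_candidates(candidates: Sequence[CandidateRecord], path) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "locus": f"{c.locus.chrom}:{c.locus.start}-{c.locus.end}",
            "csf_score": c.csf_score,
            "masspec_tags": c.masspec_tags,
            "max_rrs": c.max_rrs,
            "has_human_synteny": c.has_human_synteny,
            "has_k4me3_k36me3": c.has_k4me3_k36me3,
            "has_enhancer_signature": c.has_enhancer_signature,
            "filter_trace": ";".join(f"{n}={s}" for n, s in c.filter_trace),
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# temporal induction filter (human ortholog time course)
# ---------------------------------------------------------------------------

CONTRAST_TYPES = ("adjacent", "vs_day0")


@dataclass(frozen=True)
class TimecoursePair:
    """One gene x contrast differential-expression call."""

    gene_id: str
    contrast_type: str  # "adjacent" (day i vs day i+1) or "vs_day0"
    q: float
    direction: int  # sign of the expression change

    def __post_init__(self) -> None:
        if self.contrast_type not in CONTRAST_TYPES:
            raise ValueError(
                f"unlabelled contrast {self.contrast_type!r} for {self.gene_id}"
            )
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q={self.q} outside [0, 1]")
        if self.direction not in (-1, 0, 1):
            raise ValueError("direction must be -1, 0 or +1")


def temporal_induction_filter(
    timecourse: Iterable[TimecoursePair], q_threshold: float = 0.01
) -> Tuple[Set[str], Set[str]]:
    """Genes DE between adjacent time points, and the induced subset.

    Returns (de_any_adjacent, induced_vs_day0): genes with q < threshold in
    at least one adjacent-pair contrast, and the subset that is additionally
    significant AND upregulated in at least one vs-day-0 contrast.
    """
    de_adjacent: Set[str] = set()
    induced: Set[str] = set()
    for pair in timecourse:
        if pair.q < q_threshold:
            if pair.contrast_type == "adjacent":
                de_adjacent.add(pair.gene_id)
            elif pair.direction > 0:
                induced.add(pair.gene_id)
    return de_adjacent, de_adjacent & induced
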
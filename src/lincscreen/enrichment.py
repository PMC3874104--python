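"""Rank-based Mann-Whitney gene-set enrichment and guilt-by-association.

Genes are rank-ordered by a signed differential test statistic; each gene set
is compared against the remaining genes with a two-sided Mann-Whitney U-test,
p-values are Benjamini-Hochberg corrected across the collection, and each set
receives a z-score standardising its mean statistic against all genes:

    z = (mean_set - mean_all) / (sd_all / sqrt(|set|))

with sd_all the population standard deviation over all genes. The sign of z
reports the direction (enrichment vs depletion). The Kolmogorov-Smirnov
weighted-enrichment flavour of GSEA is deliberately out of scope.

Guilt-by-association ranks protein-coding genes by their Pearson correlation
with a focal lincRNA's expression profile across a sample compendium and
feeds those correlations to the same set test; sets are called significant at
a raw p threshold (default 1e-6) while BH q-values are always reported too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import DiffRecord, ExpressionMatrix, GeneSetCollection

EXACT_PRODUCT_LIMIT = 10_000  # exact mode when |set| * |complement| <= this
_ENUM_LIMIT = 200_000  # full enumeration bound for tied exact tests


@dataclass
class RankedList:
    """Gene ids in descending score order with the scores themselves."""

    gene_ids: List[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranking")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    n_in_set: int
    U: Optional[float]
    p: Optional[float]
    q: Optional[float]
    z: Optional[float]
    significant: bool = False
    skipped_reason: Optional[str] = None

    @property
    def direction(self) -> int:
        if self.z is None or self.z == 0:
            return 0
        return 1 if self.z > 0 else -1


@dataclass
class CorrelationProfile:
    """Pearson r of one focal gene against every coding gene."""

    focal_id: str
    r: pd.Series
    n_samples: int
    excluded: Dict[str, str]


def rank_by_statistic(diff_table: Sequence[DiffRecord]) -> RankedList:
    """Descending by test statistic; ties broken by gene id; NOTEST dropped."""
    ok = [r for r in diff_table if r.status == "OK"]
    if not ok:
        raise ValueError("no OK-status records to rank")
    ok.sort(key=lambda r: (-r.test_statistic, r.gene_id))
    return RankedList(
        gene_ids=[r.gene_id for r in ok],
        scores=np.array([r.test_statistic for r in ok], dtype=float),
    )


def _exact_permutation_p(values: np.ndarray, k: int, u_obs: float) -> float:
    """Two-sided p over all C(n, k) member labelings (handles ties).

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1, the same two-sided
    convention as the tie-free exact distribution.
    """
    n = len(values)
    ranks = stats.rankdata(values)
    base = k * (k + 1) / 2.0
    lo = hi = 0
    total = 0
    for combo in combinations(range(n), k):
        u = ranks[list(combo)].sum() - base
        lo += u <= u_obs + 1e-12
        hi += u >= u_obs - 1e-12
        total += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


def mannwhitney_set_test(
    values: Sequence[float], membership: Sequence[bool]
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U of member vs non-member values.

    U is the statistic of the member sample. The exact permutation
    distribution is used when |set| * |complement| <= 10,000 (tie-free via
    the exact U distribution; with ties via full enumeration when C(n, k) is
    small enough); otherwise the normal approximation with tie and continuity
    corrections. Degenerate input (all values identical) returns p = 1.
    """
    values = np.asarray(values, dtype=float)
    membership = np.asarray(membership, dtype=bool)
    if values.shape != membership.shape:
        raise ValueError("values and membership differ in length")
    k = int(membership.sum())
    m = int((~membership).sum())
    if k < 1 or m < 1:
        raise ValueError("need at least one member and one non-member")
    x, y = values[membership], values[~membership]
    if np.all(values == values[0]):
        return k * m / 2.0, 1.0

    has_ties = len(np.unique(values)) < len(values)
    if k * m <= EXACT_PRODUCT_LIMIT:
        if not has_ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return float(res.statistic), float(res.pvalue)
        if math.comb(k + m, k) <= _ENUM_LIMIT:
            ranks = stats.rankdata(values)
            u_obs = float(ranks[membership].sum() - k * (k + 1) / 2.0)
            return u_obs, _exact_permutation_p(values, k, u_obs)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def set_zscore(
    values: Sequence[float], membership: Sequence[bool]
) -> Optional[float]:
    """Standardised set mean; None when the background sd is zero."""
    values = np.asarray(values, dtype=float)
    membership = np.asarray(membership, dtype=bool)
    k = int(membership.sum())
    if k < 1:
        raise ValueError("set must have >= 1 member")
    sd_all = float(values.std(ddof=0))
    if sd_all == 0.0:
        return None
    return float((values[membership].mean() - values.mean()) / (sd_all / math.sqrt(k)))


def _enrich_ranked(
    gene_ids: List[str],
    scores: np.ndarray,
    collection: GeneSetCollection,
    min_set_size: int,
) -> List[EnrichmentResult]:
    index = {g: i for i, g in enumerate(gene_ids)}
    tested: List[EnrichmentResult] = []
    skipped: List[EnrichmentResult] = []
    for gs in collection:
        member_idx = [index[m] for m in gs.members if m in index]
        n_in = len(member_idx)
        if n_in < min_set_size or n_in == len(gene_ids):
            skipped.append(
                EnrichmentResult(
                    set_name=gs.name, n_in_set=n_in, U=None, p=None, q=None, z=None,
                    skipped_reason=(
                        "fewer than min_set_size mapped members"
                        if n_in < min_set_size
                        else "set covers the whole ranking"
                    ),
                )
            )
            continue
        membership = np.zeros(len(gene_ids), dtype=bool)
        membership[member_idx] = True
        u, p = mannwhitney_set_test(scores, membership)
        z = set_zscore(scores, membership)
        tested.append(
            EnrichmentResult(set_name=gs.name, n_in_set=n_in, U=u, p=p, q=None, z=z)
        )
    if not tested:
        raise ValueError("no gene set overlaps the ranking")
    q = bh_correct([r.p for r in tested])
    for r, qv in zip(tested, q):
        r.q = float(qv)
    results = tested + skipped
    results.sort(key=lambda r: r.set_name)
    return results


def gsea(
    diff_table: Sequence[DiffRecord],
    collection: GeneSetCollection,
    q_threshold: float = 0.001,
    min_set_size: int = 5,
) -> List[EnrichmentResult]:
    """Mann-Whitney set enrichment over a differential ranking.

    Returns one result per set (sorted by name) with ``significant`` marking
    q < q_threshold; undersized sets are returned with a skipped reason and
    take no part in the BH correction.
    """
    ranking = rank_by_statistic(diff_table)
    results = _enrich_ranked(
        ranking.gene_ids, ranking.scores, collection, min_set_size
    )
    for r in results:
        r.significant = r.q is not None and r.q < q_threshold
    return results


def correlation_profile(
    expression: ExpressionMatrix, focal_id: str
) -> CorrelationProfile:
    """Pearson r of the focal gene against every coding gene.

    Coding genes are those labelled "coding" when biotype labels exist, else
    every other gene. Zero-variance rows are excluded with a reason; a
    zero-variance focal profile is an error.
    """
    df = expression.values
    if focal_id not in df.index:
        raise ValueError(f"focal gene {focal_id!r} not in expression matrix")
    if df.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation profiles")
    focal = df.loc[focal_id].to_numpy(dtype=float)
    if focal.std() == 0.0:
        raise ValueError(f"focal profile {focal_id!r} has zero variance")
    if expression.biotype is not None:
        coding = df.index[(expression.biotype == "coding") & (df.index != focal_id)]
    else:
        coding = df.index[df.index != focal_id]
    mat = df.loc[coding].to_numpy(dtype=float)
    sds = mat.std(axis=1)
    excluded = {g: "zero variance" for g, sd in zip(coding, sds) if sd == 0.0}
    keep = sds > 0.0
    mat, kept_ids = mat[keep], coding[keep]
    fz = (focal - focal.mean()) / focal.std()
    mz = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
    r = (mz @ fz) / len(focal)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationProfile(
        focal_id=focal_id,
        r=pd.Series(r, index=kept_ids, name="pearson_r"),
        n_samples=df.shape[1],
        excluded=excluded,
    )


def gba(
    expression: ExpressionMatrix,
    focal_id: str,
    collection: GeneSetCollection,
    p_threshold: float = 1e-6,
    min_set_size: int = 5,
) -> Tuple[CorrelationProfile, List[EnrichmentResult]]:
    """Guilt-by-association: correlation profile + set enrichment on r values.

    Significance is called on the raw Mann-Whitney p (p < p_threshold); BH
    q-values are computed and reported alongside for stricter use.
    """
    profile = correlation_profile(expression, focal_id)
    ranked = profile.r.reset_index()
    ranked.columns = ["gene_id", "r"]
    ranked = ranked.sort_values(["r", "gene_id"], ascending=[False, True])
    results = _enrich_ranked(
        ranked["gene_id"].tolist(),
        ranked["r"].to_numpy(dtype=float),
        collection,
        min_set_size,
    )
    for res in results:
        res.significant = res.p is not None and res.p < p_threshold
    return profile, results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "set": r.set_name,
            "n": r.n_in_set,
            "U": r.U,
            "p": r.p,
            "q": r.q,
            "z": r.z,
            "direction": r.direction,
            "significant": r.significant,
            "skipped_reason": r.skipped_reason or "",
        }
        for r in results
    ]
    return pd.DataFrame(rows)
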
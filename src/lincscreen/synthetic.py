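"""Seeded generators emulating the downstream products of a knockout study.

Each generator is a pure function of its arguments and a seed, and draws its
randomness from its own counter-based substream of the global seed, so adding
a generator never perturbs the output of another. The generators produce the
statistical structure each analysis stage assumes — FPKM compendia with a
planted co-expression module, differential tables with planted local/global
significant genes, ribosome profiles with a stop-codon coverage drop,
intercross genotype counts thinned by a lethality penetrance, and normal
morphometry measurements — never raw sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import coding_potential
from .io_formats import (
    ChromSizes,
    ExpressionMatrix,
    DiffRecord,
    GenomicInterval,
    TranscriptRecord,
    tss_of,
)

# fixed substream ids: adding one must not renumber the others
_STREAMS = {
    "genome": 0,
    "transcript": 1,
    "ribosome": 2,
    "expression": 3,
    "diff": 4,
    "cross": 5,
    "morphometry": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    biotype: str  # "coding" or "lincRNA"

    @property
    def tss(self) -> int:
        return tss_of(self.interval)


# ---------------------------------------------------------------------------
# genome and gene catalog
# ---------------------------------------------------------------------------

def gen_genome(
    n_chroms: int,
    mean_length: int,
    n_genes: int,
    seed: int,
    linc_fraction: float = 0.15,
    mean_gene_length: int = 20_000,
) -> Tuple[ChromSizes, List[GeneRecord]]:
    """Random chromosome sizes plus a non-overlapping gene catalog.

    Genes never overlap within a strand; each is labelled coding or lincRNA.
    The TSS is the interval start on '+' and the end on '-'.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed, "genome")
    lengths = np.maximum(
        (mean_length * rng.uniform(0.7, 1.3, size=n_chroms)).astype(np.int64),
        10 * mean_gene_length,
    )
    sizes: ChromSizes = {f"chr{i + 1}": int(lengths[i]) for i in range(n_chroms)}

    # allocate gene counts to chromosomes proportional to length
    probs = lengths / lengths.sum()
    alloc = rng.multinomial(n_genes, probs)
    genes: List[GeneRecord] = []
    gi = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        length = int(lengths[c])
        k = int(alloc[c])
        if k == 0:
            continue
        # lay genes strand by strand with random gaps; error if they don't fit
        strands = rng.choice(["+", "-"], size=k)
        for strand in ("+", "-"):
            idx = np.flatnonzero(strands == strand)
            if idx.size == 0:
                continue
            gene_lens = rng.integers(
                max(200, mean_gene_length // 10), 2 * mean_gene_length, size=idx.size
            )
            budget = length - int(gene_lens.sum())
            if budget < idx.size:
                raise ValueError(
                    f"requested genes exceed capacity of {chrom} ({length} bp)"
                )
            cuts = np.sort(rng.choice(budget, size=idx.size, replace=False))
            start = 0
            prev_cut = 0
            for j, cut in enumerate(cuts):
                start += int(cut - prev_cut)
                prev_cut = int(cut)
                end = start + int(gene_lens[j])
                biotype = "lincRNA" if rng.random() < linc_fraction else "coding"
                genes.append(
                    GeneRecord(
                        gene_id=f"g{gi:05d}",
                        interval=GenomicInterval(chrom, start, end, strand),
                        biotype=biotype,
                    )
                )
                gi += 1
                start = end
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return sizes, genes


def catalog_to_bed(genes: Sequence[GeneRecord]) -> List[Tuple[GenomicInterval, str]]:
    """BED rows (interval, "gene_id|biotype") for a generated catalog."""
    return [(g.interval, f"{g.gene_id}|{g.biotype}") for g in genes]


# ---------------------------------------------------------------------------
# transcripts and ribosome profiles
# ---------------------------------------------------------------------------

def gen_transcript(
    seed: int,
    orf_codons: int = 40,
    utr_length: int = 120,
    leader_length: int = 30,
    transcript_id: str = "t1",
) -> TranscriptRecord:
    """A transcript with one clean ORF: leader + ATG..stop + ATG-free 3'-UTR."""
    rng = _rng(seed, "transcript")

    def codons(k: int) -> str:
        # sense codons only: no start, no stop, so the planted ORF is unique
        banned = {"ATG", "TAA", "TAG", "TGA"}
        alphabet = np.array(list("ACGT"))
        out = []
        while len(out) < k:
            c = "".join(rng.choice(alphabet, size=3))
            if c not in banned:
                out.append(c)
        return "".join(out)

    def atg_stop_free(k: int) -> str:
        alphabet = np.array(list("ACGT"))
        while True:
            s = "".join(rng.choice(alphabet, size=k))
            if "ATG" not in s and all(
                s[i : i + 3] not in {"TAA", "TAG", "TGA"} for i in range(0, k - 2, 3)
            ):
                return s

    leader = atg_stop_free(leader_length)
    cds = "ATG" + codons(max(1, orf_codons - 2)) + "TAA"
    utr = atg_stop_free(utr_length)
    return TranscriptRecord(id=transcript_id, sequence=leader + cds + utr)


def gen_ribosome_profile(
    transcript: TranscriptRecord,
    coding: bool,
    depth: float,
    drop_factor: float,
    seed: int,
) -> coding_potential.RibosomeProfile:
    """Poisson coverage tracks emulating ribosome drop-off at the stop codon.

    Coding profiles draw footprint counts with mean ``depth`` inside the first
    ORF and mean ``depth / drop_factor`` everywhere else (in particular after
    the stop); noncoding profiles are uniform at ``depth``. The total-RNA
    track is uniform at ``depth`` in both cases.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if drop_factor <= 0:
        raise ValueError("drop_factor must be > 0")
    rng = _rng(seed, "ribosome")
    n = len(transcript.sequence)
    if coding:
        orfs = coding_potential.enumerate_orfs(transcript)
        if not orfs:
            raise ValueError(f"coding=True but {transcript.id!r} contains no ORF")
        orf = orfs[0]
        rate = np.full(n, depth / drop_factor)
        rate[orf.cds_start : orf.cds_end] = depth
    else:
        rate = np.full(n, float(depth))
    footprint = rng.poisson(rate)
    rna = rng.poisson(np.full(n, float(depth)))
    return coding_potential.RibosomeProfile(
        transcript_id=transcript.id, footprint_counts=footprint, rna_counts=rna
    )


# ---------------------------------------------------------------------------
# expression compendium with a planted co-expression module
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedModule:
    lincrna_id: str
    members: Tuple[str, ...]
    r: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("planted module needs >= 2 members")
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("planted correlation r must lie in [0, 1]")


def gen_expression_compendium(
    n_genes: int,
    n_samples: int,
    planted: Optional[PlantedModule] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_fpkm: float = 12.0,
    profile_sd: float = 2.0,
) -> ExpressionMatrix:
    """FPKM matrix of coding genes plus (optionally) one planted lincRNA.

    The planted lincRNA and module members share a latent per-sample profile:
    member = baseline + profile_sd*(r*z + sqrt(1-r^2)*eps) + noise_sd*eta, so
    their sample Pearson correlation with the lincRNA approaches r as
    n_samples grows. Values are truncated at zero (baseline_fpkm is chosen
    several profile-sds above zero so truncation is rare).
    """
    rng = _rng(seed, "expression")
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    means = rng.uniform(2.0, 2.0 + baseline_fpkm, size=n_genes)
    values = means[:, None] + profile_sd * rng.standard_normal((n_genes, n_samples))
    biotype = pd.Series("coding", index=pd.Index(gene_ids, name="gene_id"))

    if planted is not None:
        missing = [m for m in planted.members if m not in set(gene_ids)]
        if missing:
            raise ValueError(f"planted members not in catalog: {missing}")
        z = rng.standard_normal(n_samples)
        focal = baseline_fpkm + profile_sd * z
        if noise_sd > 0:
            focal = focal + noise_sd * rng.standard_normal(n_samples)
        index = {g: i for i, g in enumerate(gene_ids)}
        rmix = planted.r
        for m in planted.members:
            eps = rng.standard_normal(n_samples)
            row = baseline_fpkm + profile_sd * (
                rmix * z + np.sqrt(1.0 - rmix**2) * eps
            )
            if noise_sd > 0:
                row = row + noise_sd * rng.standard_normal(n_samples)
            values[index[m]] = row
        values = np.vstack([values, focal[None, :]])
        gene_ids = gene_ids + [planted.lincrna_id]
        biotype = pd.concat(
            [biotype, pd.Series({planted.lincrna_id: "lincRNA"})]
        )

    values = np.maximum(values, 0.0)  # FPKM truncation, not re-draw
    df = pd.DataFrame(
        values,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    biotype.index = df.index
    return ExpressionMatrix(values=df, biotype=biotype)


# ---------------------------------------------------------------------------
# differential table with planted local / global significant genes
# ---------------------------------------------------------------------------

def gen_diff_table(
    catalog: Sequence[GeneRecord],
    focal_gene_id: str,
    n_local_de: int,
    n_global_de: int,
    q_sig: float = 0.05,
    seed: int = 0,
    half_width: int = 1_000_000,
) -> List[DiffRecord]:
    """Differential table with exactly ``n_local_de`` significant genes whose
    TSS lies within +-half_width of the focal TSS and ``n_global_de``
    significant genes elsewhere; everything else gets q >= q_sig. Test
    statistics are drawn consistent with the significance labels. The focal
    gene itself is always emitted as strongly significant (its locus was
    deleted) and is excluded from the local count by downstream counters.
    """
    by_id = {g.gene_id: g for g in catalog}
    if focal_gene_id not in by_id:
        raise ValueError(f"focal gene {focal_gene_id!r} not in catalog")
    focal = by_id[focal_gene_id]
    lo, hi = focal.tss - half_width, focal.tss + half_width
    local = [
        g.gene_id
        for g in catalog
        if g.gene_id != focal_gene_id
        and g.interval.chrom == focal.interval.chrom
        and lo <= g.tss <= hi
    ]
    distant = [
        g.gene_id
        for g in catalog
        if g.gene_id != focal_gene_id and g.gene_id not in set(local)
    ]
    if n_local_de > len(local):
        raise ValueError(
            f"n_local_de={n_local_de} exceeds the {len(local)} genes within "
            f"+-{half_width} bp of the focal TSS"
        )
    if n_global_de > len(distant):
        raise ValueError("n_global_de exceeds the number of distant genes")
    rng = _rng(seed, "diff")
    sig = set(rng.choice(local, size=n_local_de, replace=False)) | set(
        rng.choice(distant, size=n_global_de, replace=False)
    )
    records: List[DiffRecord] = []
    for g in catalog:
        if g.gene_id == focal_gene_id:
            q = 1e-8
            stat = -12.0
        elif g.gene_id in sig:
            q = float(rng.uniform(0.0, q_sig) * 0.999)
            stat = float(rng.choice([-1.0, 1.0]) * rng.normal(5.0, 1.0))
        else:
            q = float(rng.uniform(q_sig, 1.0))
            stat = float(rng.normal(0.0, 1.0))
        p = q * float(rng.uniform(0.2, 1.0))  # q never below its p
        records.append(
            DiffRecord(
                gene_id=g.gene_id,
                locus=g.interval,  # strand kept so the TSS stays strand-aware
                test_statistic=stat,
                log2fc=float(np.sign(stat) * abs(rng.normal(1.0, 0.5))),
                p=p,
                q=q,
                status="OK",
            )
        )
    return records


# ---------------------------------------------------------------------------
# intercross genotype counts
# ---------------------------------------------------------------------------

def gen_cross_counts(
    n_offspring: int,
    lethality_penetrance: float,
    cross_type: str,
    seed: int = 0,
    stage: str = "weaning",
):
    """Multinomial genotypes at Mendelian proportions, then the mutant-null
    class is thinned: each null individual dies independently with
    probability = penetrance before the census."""
    from .phenotype import CROSS_PROPORTIONS, NULL_CLASS, CrossCounts

    if not (0.0 <= lethality_penetrance <= 1.0):
        raise ValueError("penetrance must lie in [0, 1]")
    if cross_type not in CROSS_PROPORTIONS:
        raise ValueError(f"unknown cross_type {cross_type!r}")
    rng = _rng(seed, "cross")
    classes = list(CROSS_PROPORTIONS[cross_type])
    probs = np.array([CROSS_PROPORTIONS[cross_type][c] for c in classes])
    born = rng.multinomial(n_offspring, probs)
    counts = dict(zip(classes, (int(x) for x in born)))
    null_class = NULL_CLASS[cross_type]
    counts[null_class] = int(
        rng.binomial(counts[null_class], 1.0 - lethality_penetrance)
    )
    return CrossCounts(cross_type=cross_type, counts=counts, stage=stage)


# ---------------------------------------------------------------------------
# morphometry measurements
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> Dict:
    """Default simulation conditions for a full-pipeline demo.

    Sizes mirror the downstream stages' assumptions: a compendium of 200
    samples with a planted co-expression module at r = 0.9, an intercross of
    128 weanlings with 65% lethality penetrance, a 10x footprint drop after
    the stop codon, and morphometry groups matching the printed
    corticothalamic cell-count means.
    """
    return {
        "seed": int(seed),
        "genome": {"n_chroms": 4, "mean_length": 40_000_000, "n_genes": 1500},
        "expression": {
            "n_genes": 800,
            "n_samples": 200,
            "module_size": 30,
            "r": 0.9,
            "noise_sd": 0.0,
            "n_random_sets": 20,
            "set_size": 30,
        },
        "diff": {"n_local_de": 5, "n_global_de": 150, "q_sig": 0.05},
        "ribosome": {"depth": 50.0, "drop_factor": 10.0, "n_coding": 3, "n_noncoding": 3},
        "cross": {"n_offspring": 128, "penetrance": 0.65, "cross_type": "autosomal_het_x_het"},
        "morphometry": {
            "means": {"mutant": 1432.0, "wild_type": 1176.0},
            "sd": 100.0,
            "n_per_group": 10,
        },
    }


def simulate_study(config: Dict, outdir) -> Dict[str, str]:
    """Write every fixture the pipeline stages consume, honouring one seed.

    Produces genome.sizes, genes.bed, transcripts.fa, footprints.tsv,
    rna.tsv, expression.tsv, sets.gmt, diff.tsv, candidates.tsv,
    annotations.bed, coding_rrs.tsv, cross_counts.tsv and morphometry.tsv
    under ``outdir``; returns the path map.
    """
    import pandas as pd
    from pathlib import Path

    from . import io_formats
    from .coding_potential import max_rrs as _max_rrs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    paths: Dict[str, str] = {}

    def path_for(name: str) -> str:
        p = str(outdir / name)
        paths[name] = p
        return p

    # genome + gene catalog
    g = config["genome"]
    sizes, catalog = gen_genome(g["n_chroms"], g["mean_length"], g["n_genes"], seed)
    io_formats.write_chrom_sizes(sizes, path_for("genome.sizes"))
    io_formats.write_bed(catalog_to_bed(catalog), path_for("genes.bed"))

    # transcripts + ribosome profiles
    r = config["ribosome"]
    transcripts, fp_tracks, rna_tracks = [], {}, {}
    for i in range(int(r["n_coding"]) + int(r["n_noncoding"])):
        coding = i < int(r["n_coding"])
        label = "coding" if coding else "linc"
        t = gen_transcript(seed + i, transcript_id=f"t_{label}{i}")
        transcripts.append(t)
        prof = gen_ribosome_profile(
            t, coding=coding, depth=r["depth"], drop_factor=r["drop_factor"],
            seed=seed + i,
        )
        fp_tracks[t.id] = prof.footprint_counts
        rna_tracks[t.id] = prof.rna_counts
    io_formats.write_fasta(transcripts, path_for("transcripts.fa"))
    io_formats.write_coverage(fp_tracks, path_for("footprints.tsv"))
    io_formats.write_coverage(rna_tracks, path_for("rna.tsv"))

    # coding-gene RRS reference distribution from extra simulated coding genes
    coding_scores = []
    for j in range(30):
        t = gen_transcript(seed + 1000 + j, transcript_id=f"ref{j}")
        prof = gen_ribosome_profile(
            t, coding=True, depth=r["depth"], drop_factor=r["drop_factor"],
            seed=seed + 1000 + j,
        )
        res = _max_rrs(prof, t)
        if res.max_rrs is not None:
            coding_scores.append(res.max_rrs)
    pd.DataFrame({"rrs": coding_scores}).to_csv(
        path_for("coding_rrs.tsv"), sep="\t", index=False
    )

    # expression compendium with a planted module + gene sets
    e = config["expression"]
    rng = _rng(seed, "expression")
    member_pool = [f"g{i:05d}" for i in range(int(e["n_genes"]))]
    members = tuple(
        sorted(rng.choice(member_pool, size=int(e["module_size"]), replace=False))
    )
    planted = PlantedModule(lincrna_id="linc_focal", members=members, r=float(e["r"]))
    expr = gen_expression_compendium(
        int(e["n_genes"]), int(e["n_samples"]), planted=planted,
        noise_sd=float(e["noise_sd"]), seed=seed,
    )
    io_formats.write_expression(expr, path_for("expression.tsv"))
    collection = io_formats.GeneSetCollection()
    collection.add(
        io_formats.GeneSet(name="PLANTED_MODULE", members=members, description="planted")
    )
    for s in range(int(e["n_random_sets"])):
        picks = tuple(
            sorted(rng.choice(member_pool, size=int(e["set_size"]), replace=False))
        )
        collection.add(
            io_formats.GeneSet(name=f"RANDOM_{s:02d}", members=picks, description="random")
        )
    io_formats.write_gmt(collection, path_for("sets.gmt"))

    # differential table around a focal lincRNA
    d = config["diff"]
    lincs = [x for x in catalog if x.biotype == "lincRNA"]
    focal = lincs[len(lincs) // 2] if lincs else catalog[0]
    diff = gen_diff_table(
        catalog, focal.gene_id, int(d["n_local_de"]), int(d["n_global_de"]),
        q_sig=float(d["q_sig"]), seed=seed,
    )
    io_formats.write_diff_table(diff, path_for("diff.tsv"))
    with open(path_for("focal_tss.txt"), "w") as fh:
        fh.write(f"{focal.interval.chrom}:{focal.tss}\t{focal.gene_id}\n")

    # candidate table + annotations for the selection cascade
    from .selection import CandidateRecord, write_candidates

    cands, annotations = [], []
    crng = _rng(seed, "genome")  # reuse genome stream for catalog-derived labels
    for x in catalog:
        if x.biotype == "lincRNA":
            cands.append(
                CandidateRecord(
                    gene_id=x.gene_id,
                    locus=x.interval,
                    csf_score=float(-crng.uniform(150, 2000)),
                    masspec_tags=int(crng.integers(0, 5)),
                    has_human_synteny=bool(crng.random() < 0.7),
                    has_k4me3_k36me3=bool(crng.random() < 0.8),
                    has_enhancer_signature=bool(crng.random() < 0.3),
                )
            )
        else:
            annotations.append((x.interval, "coding"))
    write_candidates(cands, path_for("candidates.tsv"))
    io_formats.write_bed(annotations, path_for("annotations.bed"))

    # intercross counts and morphometry
    c = config["cross"]
    cross = gen_cross_counts(
        int(c["n_offspring"]), float(c["penetrance"]), c["cross_type"], seed=seed
    )
    pd.DataFrame(
        [{"genotype": k, "count": v} for k, v in cross.counts.items()]
    ).to_csv(path_for("cross_counts.tsv"), sep="\t", index=False)

    m = config["morphometry"]
    gen_morphometry(
        {k: float(v) for k, v in m["means"].items()},
        float(m["sd"]), int(m["n_per_group"]), seed=seed,
    ).to_csv(path_for("morphometry.tsv"), sep="\t", index=False)

    return paths


def gen_morphometry(
    group_means: Dict[str, float],
    group_sd: float,
    n_per_group: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Normal draws per group as a two-column (group, value) table."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if group_sd < 0:
        raise ValueError("group_sd must be >= 0")
    rng = _rng(seed, "morphometry")
    rows = []
    for group, mean in group_means.items():
        vals = mean + group_sd * rng.standard_normal(n_per_group)
        rows.extend({"group": group, "value": float(v)} for v in vals)
    return pd.DataFrame(rows)
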
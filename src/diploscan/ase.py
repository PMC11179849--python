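"""Allele-specific expression: informative SNP selection, allele counting,
beta-binomial testing with FDR control, allelic-profile clustering, and
association of ASE with nearby heterozygous structural variation.

The ASE test compares each gene's P0 read fraction against 0.5 with a
beta-binomial whose overdispersion is estimated per organ by a method of
moments on within-gene replicate variation, then controls the FDR per organ
with Benjamini-Hochberg at 5%.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .models import GeneModel, Variant


@dataclass
class InformativeSnp:
    chrom: str
    pos: int
    gene_id: str
    p0_base: str
    p1_base: str
    indel_distance: float  # bp to the nearest indel edge (inf if none)
    multi_gene: bool = False


def select_informative_snps(
    snps: list[Variant],
    indels: list[Variant],
    genes: list[GeneModel],
    min_indel_distance: int = 50,
) -> list[InformativeSnp]:
    """Coding SNPs usable for allele counting: inside a CDS and with no indel
    edge closer than ``min_indel_distance`` bp (SNPs at exactly the threshold
    are kept).  SNPs in overlapping genes are reported once per gene and
    flagged."""
    cds_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        for s, e in g.cds:
            cds_tree[g.chrom].addi(s, e, g.id)
    indel_pos: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for v in indels:
        if v.var_class == "SNP":
            continue
        indel_pos[v.chrom].append((v.pos, max(v.end, v.pos + 1)))
    for chrom in indel_pos:
        indel_pos[chrom].sort()

    out: list[InformativeSnp] = []
    for v in snps:
        if v.var_class != "SNP":
            continue
        gene_ids = sorted({iv.data for iv in cds_tree[v.chrom].overlap(v.pos, v.pos + 1)})
        if not gene_ids:
            continue
        dist = math.inf
        for s, e in indel_pos.get(v.chrom, []):
            if s <= v.pos < e:
                dist = 0.0
            elif v.pos < s:
                dist = min(dist, s - v.pos)
            else:
                dist = min(dist, v.pos - (e - 1))
        if dist < min_indel_distance:
            continue
        for gid in gene_ids:
            out.append(
                InformativeSnp(v.chrom, v.pos, gid, v.ref_allele, v.alt_allele,
                               dist, multi_gene=len(gene_ids) > 1)
            )
    return out


PILEUP_COLUMNS = ["chrom", "pos", "organ", "replicate", "base", "count"]


def count_alleles(pileups: pd.DataFrame,
                  snps: list[InformativeSnp]) -> pd.DataFrame:
    """Aggregate per-site base counts into per-gene allele-count records.

    ``pileups`` has columns chrom, pos (0-based), organ, replicate, base,
    count.  Reads matching the P0 base count to P0, the P1 base to P1; other
    bases are discarded.  Sites with no coverage contribute (0, 0).
    """
    missing = set(PILEUP_COLUMNS) - set(pileups.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    by_site: dict[tuple[str, int], list[InformativeSnp]] = defaultdict(list)
    for s in snps:
        by_site[(s.chrom, s.pos)].append(s)

    acc: dict[tuple[str, str, object], list[int]] = defaultdict(lambda: [0, 0])
    samples = pileups[["organ", "replicate"]].drop_duplicates()
    for s in snps:
        for _, row in samples.iterrows():
            acc[(s.gene_id, row.organ, row.replicate)]  # ensure (0,0) records
    for row in pileups.itertuples(index=False):
        for s in by_site.get((row.chrom, row.pos), []):
            key = (s.gene_id, row.organ, row.replicate)
            if row.base == s.p0_base:
                acc[key][0] += row.count
            elif row.base == s.p1_base:
                acc[key][1] += row.count
    rows = [
        {"gene": g, "organ": o, "replicate": r, "count_p0": c0, "count_p1": c1}
        for (g, o, r), (c0, c1) in sorted(acc.items(), key=lambda kv: kv[0])
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- testing


def estimate_rho(records: pd.DataFrame) -> float:
    """Method-of-moments beta-binomial overdispersion from within-gene
    replicate variation (floored at 0)."""
    chi2_sum = 0.0
    df_sum = 0.0
    scale_sum = 0.0
    for _gene, grp in records.groupby("gene"):
        n = (grp.count_p0 + grp.count_p1).to_numpy(dtype=float)
        x = grp.count_p0.to_numpy(dtype=float)
        keep = n > 0
        n, x = n[keep], x[keep]
        m = len(n)
        if m < 2:
            continue
        pbar = x.sum() / n.sum()
        if pbar <= 0.0 or pbar >= 1.0:
            continue
        chi2_sum += float(np.sum((x - n * pbar) ** 2 / (n * pbar * (1 - pbar))))
        df_sum += m - 1
        scale_sum += float(np.sum(n - 1)) * (m - 1) / m
    if df_sum == 0 or scale_sum == 0:
        return 0.0
    return max(0.0, (chi2_sum - df_sum) / scale_sum)


def _betabinom_pvalue(x: int, n: int, rho: float) -> float:
    """Two-sided p for x successes of n against a symmetric null at 0.5."""
    if n == 0:
        return float("nan")
    if rho <= 0.0:
        return float(stats.binomtest(x, n, 0.5).pvalue)
    a = (1.0 - rho) / (2.0 * rho)
    dist = stats.betabinom(n, a, a)
    p = 2.0 * min(dist.cdf(x), dist.sf(x - 1))
    return float(min(1.0, p))


def test_ase(records: pd.DataFrame, fdr: float = 0.05,
             pseudocount: float = 1.0) -> pd.DataFrame:
    """Per gene x organ beta-binomial ASE test with BH correction per organ.

    Returns one row per gene x organ with total counts, log2 allelic ratio
    (P0/P1 with pseudocount), p, q, is_ase (q <= fdr) and a testable flag
    (False when the gene x organ has zero reads).
    """
    out_rows = []
    for organ, org_rec in records.groupby("organ"):
        rho = estimate_rho(org_rec)
        per_gene = org_rec.groupby("gene")[["count_p0", "count_p1"]].sum()
        pvals, meta = [], []
        for gene, row in per_gene.iterrows():
            x, n = int(row.count_p0), int(row.count_p0 + row.count_p1)
            pvals.append(_betabinom_pvalue(x, n, rho))
            meta.append((gene, x, n))
        pvals = np.asarray(pvals, dtype=float)
        testable = ~np.isnan(pvals)
        qvals = np.full_like(pvals, np.nan)
        if testable.any():
            qvals[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
        for (gene, x, n), p, q in zip(meta, pvals, qvals):
            out_rows.append(
                {
                    "gene": gene,
                    "organ": organ,
                    "count_p0": x,
                    "count_p1": n - x,
                    "log2_ratio": math.log2((x + pseudocount) / (n - x + pseudocount)),
                    "rho": rho,
                    "p_value": p,
                    "q_value": q,
                    "testable": bool(not math.isnan(p)),
                    "is_ase": bool(not math.isnan(q) and q <= fdr),
                }
            )
    return pd.DataFrame(out_rows)


def ase_gene_set(results: pd.DataFrame) -> set[str]:
    """Genes called ASE in at least one organ."""
    return set(results.loc[results.is_ase, "gene"])


def ase_fraction(n_ase: int, n_expressed: int) -> float:
    """Percentage of expressed genes with ASE, truncated (not rounded) to one
    decimal place."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be > 0")
    if n_ase > n_expressed:
        raise ValueError("n_ase cannot exceed n_expressed")
    return math.floor(1000.0 * n_ase / n_expressed) / 10.0


# ---------------------------------------------------------------- clustering


def cluster_ase_profiles(results: pd.DataFrame, records: pd.DataFrame,
                         min_reads: int = 10, k: int = 4,
                         ase_only: bool = True) -> pd.DataFrame:
    """Ward hierarchical clustering of per-organ mean P0 proportions.

    Only genes with at least ``min_reads`` total mapped reads in every
    replicate of every organ are clustered (and, by default, only genes
    called ASE in at least one organ).
    """
    eligible = set(records.gene)
    if ase_only:
        eligible &= ase_gene_set(results)
    totals = records.assign(total=records.count_p0 + records.count_p1)
    min_per_gene = totals.groupby("gene")["total"].min()
    eligible &= set(min_per_gene[min_per_gene >= min_reads].index)
    eligible = sorted(eligible)
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} genes pass the read filter; choose k <= that"
        )
    sub = totals[totals.gene.isin(eligible)].copy()
    sub["prop_p0"] = sub.count_p0 / sub.total
    mat = (
        sub.groupby(["gene", "organ"])["prop_p0"].mean().unstack("organ")
        .loc[eligible]
    )
    if len(mat) == 1:
        labels = np.array([1])
    else:
        Z = linkage(mat.to_numpy(), method="ward", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    out = mat.copy()
    out.columns = [f"mean_p0_{c}" for c in out.columns]
    out.insert(0, "cluster", labels)
    return out.reset_index()


# ---------------------------------------------------------------- association


@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    percent_ase: float
    percent_non_ase: float
    p_value: float
    testable: bool = True


def sv_ase_enrichment(ase_genes: set[str], all_tested_genes: set[str],
                      het_svs: list[Variant], genes: list[GeneModel],
                      window_bp: int = 1000) -> EnrichmentResult:
    """2x2 Fisher test of heterozygous-SV proximity (gene span +- window)
    against ASE status."""
    by_id = {g.id: g for g in genes}
    tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for v in het_svs:
        tree[v.chrom].addi(v.pos, max(v.end, v.pos + 1))
    non_ase = set(all_tested_genes) - set(ase_genes)
    if not ase_genes:
        return EnrichmentResult(((0, 0), (0, len(non_ase))), 0.0, 0.0,
                                float("nan"), testable=False)

    def near_sv(gid: str) -> bool:
        g = by_id[gid]
        return bool(tree[g.chrom].overlap(max(0, g.start - window_bp),
                                          g.end + window_bp))

    a = sum(near_sv(g) for g in ase_genes)
    b = len(ase_genes) - a
    c = sum(near_sv(g) for g in non_ase)
    d = len(non_ase) - c
    return fisher_enrichment(a, b, c, d)


def fisher_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Exact two-sided Fisher test on ((ASE near, ASE far), (non near, non far))."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    pct_ase = round(100.0 * a / (a + b), 1) if a + b else 0.0
    pct_non = round(100.0 * c / (c + d), 1) if c + d else 0.0
    return EnrichmentResult(((a, b), (c, d)), pct_ase, pct_non, float(p))


def expression_matrix(records: pd.DataFrame) -> pd.Series:
    """Per-gene expression on a log scale: mean over samples of
    log2(1 + counts-per-million) of total (P0+P1) gene counts."""
    df = records.assign(total=records.count_p0 + records.count_p1)
    df["sample"] = df.organ.astype(str) + ":" + df.replicate.astype(str)
    mat = df.pivot_table(index="gene", columns="sample", values="total",
                         aggfunc="sum").fillna(0.0)
    cpm = mat / mat.sum(axis=0).replace(0, np.nan) * 1e6
    return np.log2(1.0 + cpm).mean(axis=1)


def te_expression_association(
    gene_expression: pd.Series, te_group: dict[str, str]
) -> pd.DataFrame:
    """Compare expression of genes grouped by upstream TE presence/zygosity.

    ``te_group`` maps gene id to one of {"none", "hom", "het"}.  Returns one
    row per group with n, median, and the two-sided Wilcoxon rank-sum p-value
    against the no-TE group (NaN when either group has n < 3).
    """
    groups: dict[str, list[float]] = {"none": [], "hom": [], "het": []}
    for gene, value in gene_expression.items():
        groups.setdefault(te_group.get(gene, "none"), []).append(float(value))
    rows = []
    for name in ("none", "hom", "het"):
        vals = groups[name]
        p = float("nan")
        if name != "none" and len(vals) >= 3 and len(groups["none"]) >= 3:
            p = float(stats.mannwhitneyu(groups["none"], vals,
                                         alternative="two-sided").pvalue)
        rows.append({"group": name, "n": len(vals),
                     "median": float(np.median(vals)) if vals else float("nan"),
                     "p_vs_none": p})
    return pd.DataFrame(rows)


def upstream_te_groups(genes: list[GeneModel], tes, zygosity_labels: dict[str, str],
                       window_bp: int = 1000) -> dict[str, str]:
    """Partition genes by TE presence in the 1-kb proximal upstream region;
    heterozygous beats homozygous when both occur."""
    tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for t in tes:
        lab = zygosity_labels.get(t.id, "")
        if lab in ("heterozygous", "homozygous"):
            tree[t.chrom].addi(t.start, t.end, lab)
    out: dict[str, str] = {}
    for g in genes:
        if g.strand == "+":
            up = (max(0, g.start - window_bp), g.start)
        else:
            up = (g.end, g.end + window_bp)
        labs = {iv.data for iv in tree[g.chrom].overlap(*up)} if up[1] > up[0] else set()
        if "heterozygous" in labs:
            out[g.id] = "het"
        elif "homozygous" in labs:
            out[g.id] = "hom"
        else:
            out[g.id] = "none"
    return out
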
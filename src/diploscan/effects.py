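"""Coding-impact classification of variants against gene models.

SNPs inside CDS are translated in frame and compared codon-by-codon;
CDS indels are frameshift or in-frame purely by length modulo 3; genes whose
whole span lies inside one SV deletion are presence/absence (PAV) genes.
Impact levels follow the usual annotation convention: frameshift and stop
gain/loss are HIGH, missense and in-frame indels MODERATE, synonymous LOW,
and non-coding regions MODIFIER.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .models import IMPACT_BY_EFFECT, EffectCall, GeneModel, Variant, revcomp


def cds_sequence(gene: GeneModel, seqs: dict[str, str]) -> str:
    """Spliced CDS in transcript orientation."""
    chunks = [seqs[gene.chrom][s:e] for s, e in sorted(gene.cds)]
    cds = "".join(chunks)
    return revcomp(cds) if gene.strand == "-" else cds


def translate(cds: str) -> str:
    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """Offset of a genomic position within the spliced CDS (transcript
    orientation), or None if the position is not coding."""
    off = 0
    total = gene.cds_len()
    for s, e in sorted(gene.cds):
        if s <= pos < e:
            fwd = off + (pos - s)
            return fwd if gene.strand == "+" else total - 1 - fwd
        off += e - s
    return None


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _region_of(variant: Variant, gene: GeneModel, flank: int) -> str:
    """Most severe region touched by the variant interval, by the priority
    CDS > intron > upstream > downstream > intergenic."""
    iv = (variant.pos, max(variant.end, variant.pos + 1))
    if any(_overlap(iv, c) for c in gene.cds):
        return "CDS"
    exonic = sorted(gene.exons)
    for (s1, e1), (s2, _) in zip(exonic, exonic[1:]):
        if s2 > e1 and _overlap(iv, (e1, s2)):
            return "intron"
    if gene.strand == "+":
        up, down = (gene.start - flank, gene.start), (gene.end, gene.end + flank)
    else:
        up, down = (gene.end, gene.end + flank), (gene.start - flank, gene.start)
    if _overlap(iv, up):
        return "upstream"
    if _overlap(iv, down):
        return "downstream"
    if _overlap(iv, (gene.start, gene.end)):
        return "intron"  # genic but neither CDS nor between-exon (e.g. UTR gap)
    return "intergenic"


def classify_effect(variant: Variant, gene: GeneModel,
                    seqs: dict[str, str], flank: int = 1000) -> EffectCall:
    """snpEff-style effect for one variant against one gene model."""
    if variant.chrom != gene.chrom:
        raise ValueError(
            f"variant on {variant.chrom} vs gene {gene.id} on {gene.chrom}"
        )

    def call(effect: str) -> EffectCall:
        return EffectCall(variant.id, gene.id, region, effect,
                          IMPACT_BY_EFFECT[effect], variant.var_class)

    # whole-gene deletion dominates everything else
    if variant.is_deletion() and variant.pos <= gene.start and variant.end >= gene.end:
        region = "CDS"
        return call("gene_deleted")

    region = _region_of(variant, gene, flank)
    if region != "CDS":
        return call(f"{region}_variant")

    if variant.var_class == "SNP":
        off = _cds_offset(gene, variant.pos)
        if off is None:  # SNP touches CDS boundary bookkeeping; treat as intron
            region = "intron"
            return call("intron_variant")
        cds = cds_sequence(gene, seqs)
        base = variant.alt_allele if gene.strand == "+" else revcomp(variant.alt_allele)
        ci = off // 3
        ref_codon = cds[ci * 3 : ci * 3 + 3]
        alt_codon = ref_codon[: off % 3] + base + ref_codon[off % 3 + 1 :]
        if len(ref_codon) < 3:
            return call("synonymous_variant")  # trailing partial codon
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            return call("synonymous_variant")
        if alt_aa == "*":
            return call("stop_gained")
        if ref_aa == "*":
            return call("stop_lost")
        return call("missense_variant")

    # indel / SV touching CDS: frame decided by the coding bases affected
    if variant.is_insertion():
        changed = len(variant.alt_allele)
        kind = "insertion"
    else:
        changed = sum(_overlap((variant.pos, variant.end), c) for c in gene.cds)
        kind = "deletion"
    if changed % 3 != 0:
        return call("frameshift_variant")
    return call(f"inframe_{kind}")


def classify_effects(variants: list[Variant], genes: list[GeneModel],
                     seqs: dict[str, str], flank: int = 1000) -> list[EffectCall]:
    """Effect calls for every variant against every gene it is within
    ``flank`` of; variants near no gene get a single intergenic call."""
    tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, g in enumerate(genes):
        tree[g.chrom].addi(max(0, g.start - flank), g.end + flank, i)
    calls: list[EffectCall] = []
    for v in variants:
        hits = sorted(tree[v.chrom].overlap(v.pos, max(v.end, v.pos + 1)),
                      key=lambda iv: iv.data)
        if not hits:
            calls.append(EffectCall(v.id, "", "intergenic", "intergenic_variant",
                                    "MODIFIER", v.var_class))
            continue
        for iv in hits:
            calls.append(classify_effect(v, genes[iv.data], seqs, flank))
    return calls


def find_pav_genes(genes: list[GeneModel], deletions: list[Variant]) -> list[str]:
    """Genes whose full span lies within a single SV deletion."""
    tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for d in deletions:
        if d.is_deletion():
            tree[d.chrom].addi(d.pos, d.end)
    out = []
    for g in genes:
        if any(iv.begin <= g.start and g.end <= iv.end
               for iv in tree[g.chrom].overlap(g.start, g.end)):
            out.append(g.id)
    return out


def impact_summary(calls: list[EffectCall]) -> tuple[pd.DataFrame, int]:
    """Percentage of calls at each impact level per variant class (2 decimals),
    plus the number of distinct genes carrying at least one HIGH call."""
    if not calls:
        raise ValueError("no effect calls to summarise")
    df = pd.DataFrame(
        [{"var_class": c.var_class, "impact": c.impact, "gene": c.gene_id}
         for c in calls]
    )
    out = df.groupby(["var_class", "impact"]).size().rename("count").reset_index()
    totals = out.groupby("var_class")["count"].transform("sum")
    out["percent"] = (100.0 * out["count"] / totals).round(2)
    n_high_genes = df.loc[(df.impact == "HIGH") & (df.gene != ""), "gene"].nunique()
    return out, int(n_high_genes)
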
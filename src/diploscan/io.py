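"""Readers and writers for the standard formats used across the pipeline.

FASTA is read through pyfaidx, VCF through cyvcf2 and GFF3 through gffutils;
the writers emit the plain-text dialects directly (1-based GFF3/VCF, 0-based
half-open BED).
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
import pyfaidx

from .models import GeneModel, TEAnnotation, Variant, ZygosityCall

# ---------------------------------------------------------------- FASTA


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------- GFF3


def _attrs(**kv) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items() if v not in (None, ""))


def write_genes_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [g.chrom, "diploscan", "gene", str(g.start + 1), str(g.end), ".",
                     g.strand, ".", _attrs(ID=g.id)]
                )
                + "\n"
            )
            mrna = f"{g.id}.t1"
            fh.write(
                "\t".join(
                    [g.chrom, "diploscan", "mRNA", str(g.start + 1), str(g.end), ".",
                     g.strand, ".", _attrs(ID=mrna, Parent=g.id)]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [g.chrom, "diploscan", "exon", str(s + 1), str(e), ".",
                         g.strand, ".", _attrs(ID=f"{mrna}.exon{i}", Parent=mrna)]
                    )
                    + "\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    "\t".join(
                        [g.chrom, "diploscan", "CDS", str(s + 1), str(e), ".",
                         g.strand, "0", _attrs(ID=f"{mrna}.cds{i}", Parent=mrna)]
                    )
                    + "\n"
                )


def read_genes_gff3(path: str | os.PathLike) -> list[GeneModel]:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        exons, cds = [], []
        for child in db.children(g, featuretype="exon", order_by="start"):
            exons.append((child.start - 1, child.end))
        for child in db.children(g, featuretype="CDS", order_by="start"):
            cds.append((child.start - 1, child.end))
        gm = GeneModel(id=g.id, chrom=g.seqid, strand=g.strand, exons=exons, cds=cds)
        gm.validate()
        genes.append(gm)
    return genes


def write_tes_gff3(tes: list[TEAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tes:
            fh.write(
                "\t".join(
                    [t.chrom, "diploscan", "transposable_element", str(t.start + 1),
                     str(t.end), ".", "+", ".",
                     _attrs(ID=t.id, Order=t.order, Superfamily=t.superfamily,
                            Intact="true" if t.intact else "false",
                            Consensus=t.consensus_id)]
                )
                + "\n"
            )
            for name, ltr in (("five_prime", t.ltr5), ("three_prime", t.ltr3)):
                if ltr is not None:
                    fh.write(
                        "\t".join(
                            [t.chrom, "diploscan", "long_terminal_repeat",
                             str(ltr[0] + 1), str(ltr[1]), ".", "+", ".",
                             _attrs(ID=f"{t.id}.{name}_ltr", Parent=t.id)]
                        )
                        + "\n"
                    )


def read_tes_gff3(path: str | os.PathLike) -> list[TEAnnotation]:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    tes: list[TEAnnotation] = []
    for f in db.features_of_type("transposable_element", order_by="start"):
        ltrs = sorted(
            ((c.start - 1, c.end) for c in db.children(f, featuretype="long_terminal_repeat")),
            key=lambda x: x[0],
        )
        tes.append(
            TEAnnotation(
                id=f.id,
                chrom=f.seqid,
                start=f.start - 1,
                end=f.end,
                order=f.attributes.get("Order", ["?"])[0],
                superfamily=f.attributes.get("Superfamily", ["?"])[0],
                intact=f.attributes.get("Intact", ["false"])[0] == "true",
                ltr5=ltrs[0] if len(ltrs) == 2 else None,
                ltr3=ltrs[1] if len(ltrs) == 2 else None,
                consensus_id=f.attributes.get("Consensus", [""])[0],
            )
        )
    return tes


# ---------------------------------------------------------------- VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based, inclusive)">
##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted sequence for symbolic insertions">
##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant size class (SNP/INDEL/SV)">
##INFO=<ID=PHASE,Number=1,Type=String,Description="Phase carrying the variant allele">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Planted zygosity (truth files)">
##INFO=<ID=SRCTE,Number=1,Type=String,Description="Source TE id (truth files)">
##INFO=<ID=AGE,Number=1,Type=Float,Description="Planted LTR-RT insertion age in years (truth files)">
##INFO=<ID=LTRLEN,Number=1,Type=Integer,Description="LTR length of the inserted element (truth files)">
"""

_INFO_KEYS = ("ZYG", "SRCTE", "AGE", "LTRLEN")


def write_vcf(variants: list[Variant], seqs: dict[str, str],
              path: str | os.PathLike) -> None:
    """Write variants as VCF 4.2; SNP/INDEL with explicit alleles (left-aligned,
    anchor-base convention), SVs as symbolic records."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, seq in seqs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            seq = seqs[v.chrom]
            info = {"VCLASS": v.var_class, "PHASE": v.phase_of_presence}
            for k in _INFO_KEYS:
                if k.lower() in v.info:
                    info[k] = v.info[k.lower()]
            if v.var_class == "SNP":
                pos1, ref, alt = v.pos + 1, v.ref_allele, v.alt_allele
            elif v.var_class == "INDEL":
                anchor = seq[v.pos - 1] if v.pos > 0 else seq[v.end]
                pos1 = v.pos if v.pos > 0 else 1
                ref = anchor + v.ref_allele
                alt = anchor + v.alt_allele
            else:  # SV: symbolic
                anchor = seq[v.pos - 1] if v.pos > 0 else seq[0]
                pos1 = v.pos if v.pos > 0 else 1
                ref = anchor
                sym = {"DUP_TANDEM": "DUP:TANDEM", "DUP_INT": "DUP:INT"}.get(
                    v.svtype, v.svtype)
                alt = f"<{sym}>"
                info["SVTYPE"] = v.svtype
                info["SVLEN"] = v.length
                info["END"] = v.end  # == pos1 + ref-span for DEL/INV
                if v.alt_allele and v.is_insertion():
                    info["SEQ"] = v.alt_allele
            fh.write(
                "\t".join(
                    [v.chrom, str(pos1), v.id or ".", ref, alt, ".", "PASS",
                     ";".join(f"{k}={val}" for k, val in info.items())]
                )
                + "\n"
            )


def read_vcf(path: str | os.PathLike,
             seqs: dict[str, str] | None = None) -> list[Variant]:
    """Read a VCF written by :func:`write_vcf`.  When ``seqs`` is given, the
    reference allele of symbolic deletions/inversions is filled back in from
    the phase-0 sequence so the round trip is lossless."""
    from cyvcf2 import VCF

    out: list[Variant] = []
    for rec in VCF(str(path)):
        alt = rec.ALT[0]
        info = dict(rec.INFO)
        vclass = info.get("VCLASS", "")
        phase = info.get("PHASE", "both")
        extras = {k.lower(): info[k] for k in _INFO_KEYS if k in info}
        if alt.startswith("<"):
            svtype = info["SVTYPE"]
            length = int(info["SVLEN"])
            pos = rec.POS  # anchor base at POS (1-based) -> internal 0-based POS
            ref_allele, alt_allele = "", ""
            if svtype in ("INS", "DUP_TANDEM", "DUP_INT"):
                alt_allele = info.get("SEQ", "")
            elif seqs is not None and svtype in ("DEL", "INV"):
                ref_allele = seqs[rec.CHROM][pos : pos + length]
                if svtype == "INV":
                    from .models import revcomp

                    alt_allele = revcomp(ref_allele)
            out.append(Variant(rec.CHROM, pos, vclass or "SV", svtype, length,
                               ref_allele, alt_allele, phase, id=rec.ID or "",
                               info=extras))
        elif len(rec.REF) == 1 and len(alt) == 1:
            out.append(Variant(rec.CHROM, rec.POS - 1, "SNP", "none", 1,
                               rec.REF, alt, phase, id=rec.ID or "", info=extras))
        else:
            # explicit indel with anchor base
            ref, a = rec.REF[1:], alt[1:]
            pos = rec.POS  # internal 0-based position after anchor
            svtype = "INS" if len(a) > len(ref) else "DEL"
            length = abs(len(a) - len(ref))
            out.append(Variant(rec.CHROM, pos, vclass or "INDEL", svtype, length,
                               ref, a, phase, id=rec.ID or "", info=extras))
    return out


# ---------------------------------------------------------------- BED


def write_zygosity_bed(tes: list[TEAnnotation], calls: list[ZygosityCall],
                       path: str | os.PathLike) -> None:
    by_id = {t.id: t for t in tes}
    with open(path, "w") as fh:
        for c in calls:
            t = by_id[c.te_id]
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{c.te_id}|{c.label}\t0\t+\n")


def read_zygosity_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, _score, _strand = line.rstrip("\n").split("\t")
            te_id, label = name.rsplit("|", 1)
            rows.append((chrom, int(start), int(end), te_id, label))
    return rows


# ---------------------------------------------------------------- tables


COUNT_COLUMNS = ["gene", "organ", "replicate", "count_p0", "count_p1"]


def write_counts_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "organ": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-count table missing columns: {sorted(missing)}")
    return df


def write_bedgraph(track: dict[str, "list[tuple[int, int, float]]"],
                   path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            for start, end, value in track[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
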
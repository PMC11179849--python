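"""SNP/INDEL/SV extraction from phase-to-phase alignments.

Variants are produced by walking block CIGARs: mismatch columns become SNPs,
gap ops become insertions/deletions classified by the 40-bp size boundary
(INDEL < 40 bp <= SV), and minus-strand blocks framed by plus-strand
neighbours become inversions.  Indels are left-aligned before reporting, so
the representation matches VCF normalisation conventions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import pandas as pd
from intervaltree import IntervalTree

from .models import AlignmentBlock, GeneModel, Variant, left_align_indel

SV_MIN_LEN = 40


@dataclass
class DensityReport:
    span_bp: int
    counts: dict[str, int] = field(default_factory=dict)
    bp_per_variant: dict[str, int] = field(default_factory=dict)


def variant_density(variants_or_counts, span_bp: int) -> DensityReport:
    """Per-class variant counts and integer bp-per-variant over a span.

    Accepts either a list of Variant objects or a mapping class -> count.
    Classes with zero count are omitted from bp_per_variant rather than
    raising a division error.
    """
    if span_bp <= 0:
        raise ValueError("span_bp must be > 0")
    if isinstance(variants_or_counts, dict):
        counts = dict(variants_or_counts)
    else:
        counts = defaultdict(int)
        for v in variants_or_counts:
            counts[v.var_class] += 1
        counts = dict(counts)
    rep = DensityReport(span_bp, counts)
    for cls, n in counts.items():
        if n > 0:
            rep.bp_per_variant[cls] = span_bp // n
    return rep


def _classify_indel(length: int, sv_min: int) -> str:
    return "SV" if length >= sv_min else "INDEL"


def _is_tandem_dup(alt: str, chrom_seq: str, pos: int, max_div: float = 0.1,
                   min_cov: float = 0.9) -> bool:
    """Does the inserted sequence match the adjacent reference segment?"""
    L = len(alt)
    for s, e in ((pos, pos + L), (pos - L, pos)):
        if s < 0 or e > len(chrom_seq):
            continue
        seg = chrom_seq[s:e]
        if len(seg) < min_cov * L:
            continue
        res = edlib.align(alt, seg, mode="NW", task="distance")
        if res["editDistance"] <= max_div * L:
            return True
    return False


def _find_interspersed_dup(alt: str, chrom_seq: str, pos: int,
                           te_mask: list[tuple[int, int]] | None,
                           max_div: float = 0.1,
                           min_distance: int = 1000) -> bool:
    """Does the inserted sequence match a non-adjacent reference interval?"""
    L = len(alt)
    if L < 31:
        return False
    seed = alt[L // 2 - 15 : L // 2 + 16]
    off = L // 2 - 15
    start = 0
    hits = 0
    while hits < 20:
        j = chrom_seq.find(seed, start)
        if j == -1:
            break
        hits += 1
        start = j + 1
        cand_s = j - off
        if abs(cand_s - pos) <= min_distance:
            continue
        if cand_s < 0 or cand_s + L > len(chrom_seq):
            continue
        if te_mask and any(
            min(cand_s + L, e) - max(cand_s, s) > 0.5 * L for s, e in te_mask
        ):
            continue
        res = edlib.align(alt, chrom_seq[cand_s : cand_s + L], mode="NW",
                          task="distance")
        if res["editDistance"] <= max_div * L:
            return True
    return False


def _classify_and_emit(variants: list[Variant], vid, chrom: str, seq: str,
                       pos: int, del_len: int, ins_seq: str, sv_min: int,
                       classify_dups: bool,
                       te_mask: dict[str, list[tuple[int, int]]] | None) -> None:
    if del_len:
        npos, ref, alt = left_align_indel(seq, pos, del_len, "")
        cls = _classify_indel(del_len, sv_min)
        variants.append(
            Variant(chrom, npos, cls, "DEL", del_len, ref, alt, "P0",
                    id=vid("del"))
        )
    elif ins_seq:
        npos, ref, alt = left_align_indel(seq, pos, 0, ins_seq)
        L = len(ins_seq)
        cls = _classify_indel(L, sv_min)
        svtype = "INS"
        if cls == "SV" and classify_dups:
            if _is_tandem_dup(alt, seq, npos):
                svtype = "DUP_TANDEM"
            elif _find_interspersed_dup(alt, seq, npos,
                                        (te_mask or {}).get(chrom)):
                svtype = "DUP_INT"
        variants.append(
            Variant(chrom, npos, cls, svtype, L, ref, alt, "P1", id=vid("ins"))
        )


def extract_variants(
    blocks: list[AlignmentBlock],
    phase0: dict[str, str],
    phase1: dict[str, str],
    *,
    sv_min: int = SV_MIN_LEN,
    classify_dups: bool = True,
    te_mask: dict[str, list[tuple[int, int]]] | None = None,
) -> list[Variant]:
    """Walk block CIGARs and emit the variant set on phase-0 coordinates.

    Insertions are sequence "present in P1", deletions "present in P0".
    Adjacent insertion/deletion CIGAR runs are merged before the 40-bp size
    classification so one biological event split at an anchor seam is not
    reported twice.
    """
    variants: list[Variant] = []
    counter = [0]
    # raw (pos, del_len, ins_seq) gap events per chromosome, pre-normalisation
    raw_events: dict[str, list[tuple[int, int, str]]] = defaultdict(list)

    def vid(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]}"

    def emit_indel(chrom: str, pos: int, del_len: int, ins_seq: str) -> None:
        if pos + del_len > len(phase0[chrom]):
            raise ValueError("allele extraction outside sequence bounds")
        raw_events[chrom].append((pos, del_len, ins_seq))

    plus = sorted(
        (b for b in blocks if b.strand == "+"),
        key=lambda b: (b.ref_name, b.ref_start),
    )
    minus = [b for b in blocks if b.strand == "-"]

    for b in plus:
        seq0, seq1 = phase0[b.ref_name], phase1[b.query_name]
        r, q = b.ref_start, b.query_start
        pend_del, pend_ins = 0, ""
        pend_pos = -1

        def flush() -> None:
            nonlocal pend_del, pend_ins, pend_pos
            if pend_del or pend_ins:
                emit_indel(b.ref_name, pend_pos, pend_del, pend_ins)
            pend_del, pend_ins, pend_pos = 0, "", -1

        for op, n in b.cigar:
            if op in ("=", "M", "X"):
                if op != "=":
                    for i in range(n):
                        if seq0[r + i] != seq1[q + i]:
                            variants.append(
                                Variant(b.ref_name, r + i, "SNP", "none", 1,
                                        seq0[r + i], seq1[q + i], "both",
                                        id=vid("snp"))
                            )
                if n > 0:
                    flush()
                r += n
                q += n
            elif op == "D":
                if not (pend_del or pend_ins):
                    pend_pos = r
                pend_del += n
                r += n
            elif op == "I":
                if not (pend_del or pend_ins):
                    pend_pos = r
                pend_ins += seq1[q : q + n]
                q += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")
        flush()

    # Canonicalise gap events: alignment paths with equal edit cost can split
    # one indel around a coincidentally matching base.  Left-align every pure
    # event and merge runs that become adjacent, so the reported event set is
    # independent of which optimal alignment path was followed.
    for chrom, events in raw_events.items():
        seq = phase0[chrom]
        norm: list[list] = []  # [pos, del_len, ins_seq]
        for pos, dlen, ins in sorted(events):
            if dlen and ins:
                norm.append([pos, dlen, ins])
                continue
            npos, _ref, nins = left_align_indel(seq, pos, dlen, ins)
            norm.append([npos, dlen, nins])
        norm.sort(key=lambda e: e[0])
        changed = True
        while changed:
            changed = False
            merged: list[list] = []
            for ev in norm:
                if merged:
                    prev = merged[-1]
                    pure_prev = not (prev[1] and prev[2])
                    pure_ev = not (ev[1] and ev[2])
                    if (pure_prev and pure_ev and prev[1] and ev[1]
                            and not prev[2] and not ev[2]
                            and ev[0] == prev[0] + prev[1]):
                        prev[1] += ev[1]  # adjacent deletions
                        changed = True
                        continue
                merged.append(ev)
            norm = []
            for pos, dlen, ins in merged:
                if dlen and ins:
                    norm.append([pos, dlen, ins])
                else:
                    npos, _ref, nins = left_align_indel(seq, pos, dlen, ins)
                    norm.append([npos, dlen, nins])
            norm.sort(key=lambda e: e[0])

        for pos, dlen, ins in norm:
            if dlen and ins:
                # mixed run: report the deletion and the insertion separately
                _classify_and_emit(variants, vid, chrom, seq, pos, dlen, "",
                                   sv_min, classify_dups, te_mask)
                _classify_and_emit(variants, vid, chrom, seq, pos + dlen, 0,
                                   ins, sv_min, classify_dups, te_mask)
            else:
                _classify_and_emit(variants, vid, chrom, seq, pos, dlen, ins,
                                   sv_min, classify_dups, te_mask)

    # minus-strand blocks framed by plus-strand neighbours are inversions
    plus_by_chrom: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for b in plus:
        plus_by_chrom[b.ref_name].append(b)
    for b in minus:
        neighbours = plus_by_chrom.get(b.ref_name, [])
        has_left = any(nb.ref_end <= b.ref_start for nb in neighbours)
        has_right = any(nb.ref_start >= b.ref_end for nb in neighbours)
        if has_left and has_right:
            seg = phase0[b.ref_name][b.ref_start : b.ref_end]
            variants.append(
                Variant(b.ref_name, b.ref_start, "SV", "INV", b.ref_span(),
                        seg, "", "both", id=vid("inv"))
            )

    variants.sort(key=lambda v: (v.chrom, v.pos, v.svtype))
    return variants


def apply_variants(seq: str, variants: list[Variant]) -> str:
    """Apply a (non-overlapping, phase-0-sorted) variant set to a phase-0
    chromosome, reconstructing the phase-1 sequence."""
    from .models import revcomp

    parts = []
    cur = 0
    for v in sorted(variants, key=lambda v: v.pos):
        if v.var_class == "SNP":
            parts.append(seq[cur : v.pos])
            parts.append(v.alt_allele)
            cur = v.pos + 1
        elif v.is_insertion():
            parts.append(seq[cur : v.pos])
            parts.append(v.alt_allele)
            cur = v.pos
        elif v.is_deletion():
            parts.append(seq[cur : v.pos])
            cur = v.pos + v.length
        elif v.svtype == "INV":
            parts.append(seq[cur : v.pos])
            parts.append(revcomp(seq[v.pos : v.pos + v.length]))
            cur = v.pos + v.length
    parts.append(seq[cur:])
    return "".join(parts)


REGION_PRIORITY = ["CDS", "intron", "upstream", "downstream", "intergenic"]


def build_region_trees(
    genes: list[GeneModel], flank: int = 1000
) -> dict[str, dict[str, IntervalTree]]:
    """Interval trees per chromosome for CDS / intron / upstream / downstream."""
    trees: dict[str, dict[str, IntervalTree]] = defaultdict(
        lambda: {r: IntervalTree() for r in REGION_PRIORITY[:-1]}
    )
    for g in genes:
        t = trees[g.chrom]
        for s, e in g.cds:
            t["CDS"].addi(s, e, g.id)
        exonic = sorted(g.exons)
        for (s1, e1), (s2, _e2) in zip(exonic, exonic[1:]):
            if s2 > e1:
                t["intron"].addi(e1, s2, g.id)
        if g.strand == "+":
            up = (max(0, g.start - flank), g.start)
            down = (g.end, g.end + flank)
        else:
            up = (g.end, g.end + flank)
            down = (max(0, g.start - flank), g.start)
        if up[1] > up[0]:
            t["upstream"].addi(up[0], up[1], g.id)
        if down[1] > down[0]:
            t["downstream"].addi(down[0], down[1], g.id)
    return trees


def assign_region(chrom: str, pos: int,
                  trees: dict[str, dict[str, IntervalTree]]) -> str:
    t = trees.get(chrom)
    if t is None:
        return "intergenic"
    for region in REGION_PRIORITY[:-1]:
        if t[region].overlaps_point(pos):
            return region
    return "intergenic"


def feature_context(variants: list[Variant], genes: list[GeneModel],
                    flank: int = 1000) -> pd.DataFrame:
    """Count variants per (size class x genomic region) with within-class
    percentages; each variant is assigned one region by the priority
    CDS > intron > upstream > downstream > intergenic at its phase-0 start."""
    for g in genes:
        g.validate()
    trees = build_region_trees(genes, flank)
    rows = []
    for v in variants:
        rows.append({"var_class": v.var_class,
                     "region": assign_region(v.chrom, v.pos, trees)})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["var_class", "region", "count", "percent"])
    out = (
        df.groupby(["var_class", "region"]).size().rename("count").reset_index()
    )
    totals = out.groupby("var_class")["count"].transform("sum")
    out["percent"] = (100.0 * out["count"] / totals).round(2)
    return out
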
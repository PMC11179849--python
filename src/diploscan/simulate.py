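"""Synthetic phased-diploid generator with exact truth records.

The generator builds a reference chromosome set carrying gene models and
pre-existing TE copies, then derives the two phases: phase-0 is the
reference itself (after LTR aging), and phase-1 is the reference with all
planted edits applied — SNPs, short indels, structural variants, new
heterozygous TE insertions (with target-site duplications), and deletions of
reference TE copies (which realises "P0-specific" heterozygous insertions).
Every edit is recorded in a TruthSet on final phase-0 coordinates in the
same left-aligned representation the variant caller reports, so recovery
tests can demand exact breakpoints.

Allele-specific read counts are simulated per gene x organ x replicate with
negative-binomial totals split binomially by the gene's true P0 fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .models import (
    GeneModel,
    PlacementError,
    SizingError,
    TEAnnotation,
    Variant,
    left_align_indel,
    revcomp,
)
from .te import detect_tsd

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]


@dataclass
class TEConsensus:
    id: str
    order: str
    superfamily: str
    sequence: str
    ltr_len: int = 0
    weight: float = 1.0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def default_te_library() -> list[TEConsensus]:
    """A small deterministic consensus library (LTR elements carry identical
    terminal repeats at both ends, as freshly inserted copies would)."""
    rng = np.random.default_rng(987654321)

    def ltr_element(name, superfamily, ltr_len, internal_len, weight):
        ltr = _random_seq(rng, ltr_len)
        return TEConsensus(name, "LTR", superfamily,
                           ltr + _random_seq(rng, internal_len) + ltr,
                           ltr_len=ltr_len, weight=weight)

    return [
        ltr_element("cons_gypsy1", "Gypsy", 400, 3200, 0.30),
        ltr_element("cons_copia1", "Copia", 250, 2000, 0.25),
        TEConsensus("cons_cacta1", "TIR", "CACTA", _random_seq(rng, 1200), weight=0.15),
        TEConsensus("cons_mudr1", "TIR", "MuDR", _random_seq(rng, 600), weight=0.10),
        TEConsensus("cons_mite1", "MITE", "Tourist", _random_seq(rng, 250), weight=0.08),
        TEConsensus("cons_line1", "LINE", "L1", _random_seq(rng, 1800), weight=0.07),
        TEConsensus("cons_heli1", "Helitron", "Helitron", _random_seq(rng, 900), weight=0.05),
    ]


@dataclass
class SimParams:
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    snp_rate: float = 1.0 / 350
    indel_rate: float = 1.0 / 921
    sv_rate: float = 1.0 / 15432
    te_library: list[TEConsensus] | None = None
    gene_per_bp: float = 1.0 / 50_000
    te_per_bp: float = 1.0 / 20_000
    het_te_fraction: float = 0.4
    tsd_len_by_order: dict[str, int] = field(default_factory=lambda: {"LTR": 5})
    ltr_age_range_het: tuple[float, float] = (1e5, 5e6)
    ltr_age_range_hom: tuple[float, float] = (2e6, 12e6)
    mu: float = 1.3e-8
    n_organs: int = 3
    n_replicates: int = 3
    mean_depth: float = 200.0
    nb_dispersion: float = 10.0  # gamma shape: var = m + m^2 / dispersion
    ase_effect_fraction: float = 0.1
    ase_effect_ratio: float = 0.8
    sv_length_range: tuple[int, int] = (40, 10_000)
    indel_length_max: int = 39
    min_separation: int = 20
    edge_margin: int = 200
    seed: int = 0

    def validate(self) -> None:
        for name in ("snp_rate", "indel_rate", "sv_rate", "het_te_fraction",
                     "ase_effect_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(t < 0 for t in self.tsd_len_by_order.values()):
            raise ValueError("TSD lengths must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.n_organs < 1 or self.n_replicates < 1:
            raise ValueError("organ and replicate counts must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    def library(self) -> list[TEConsensus]:
        return self.te_library if self.te_library is not None else default_te_library()


@dataclass
class ReferenceSet:
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    tes: list[TEAnnotation]
    te_consensus: dict[str, TEConsensus]


@dataclass
class HaplotypePair:
    phase0: dict[str, str]
    phase1: dict[str, str]


@dataclass
class TruthSet:
    planted_variants: list[Variant] = field(default_factory=list)
    te_zygosity: dict[str, str] = field(default_factory=dict)  # ref-copy labels
    te_age: dict[str, float] = field(default_factory=dict)  # years, ref copies
    gene_allelic_ratios: dict[str, dict[str, float]] = field(default_factory=dict)

    def het_te_count(self) -> int:
        n_ref_het = sum(1 for lab in self.te_zygosity.values()
                        if lab == "heterozygous")
        n_new = sum(1 for v in self.planted_variants
                    if v.info.get("zyg") == "heterozygous" and v.is_insertion()
                    and v.info.get("srcte"))
        return n_ref_het + n_new


# -------------------------------------------------------------- reference

_EXON_LENS = (150, 210, 120)  # 480 coding bp, divisible by 3
_INTRON_LENS = (180, 240)
_GENE_SPAN = sum(_EXON_LENS) + sum(_INTRON_LENS)


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def generate_reference(params: SimParams,
                       rng: np.random.Generator | None = None) -> ReferenceSet:
    """Random-composition chromosomes carrying multi-exon gene models (one
    per 1/gene_per_bp of sequence) and pre-existing TE copies (one per
    1/te_per_bp) placed in intergenic space with a flanking target-site
    duplication.  Deterministic for a fixed seed."""
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lib = params.library()
    if not lib:
        raise ValueError("TE library must be non-empty")
    weights = np.array([c.weight for c in lib], dtype=float)
    weights /= weights.sum()
    gene_tile = round(1.0 / params.gene_per_bp)
    te_tile = round(1.0 / params.te_per_bp)
    max_te = max(len(c.sequence) for c in lib) + max(
        params.tsd_len_by_order.values(), default=0)
    margin = params.edge_margin
    if gene_tile < _GENE_SPAN + 2 * margin:
        raise SizingError("gene tile too small for the gene template")
    if te_tile < max_te + 2 * margin:
        raise SizingError("TE tile too small for the largest consensus")

    chroms: dict[str, str] = {}
    genes: list[GeneModel] = []
    tes: list[TEAnnotation] = []
    gi = ti = 0
    for c in range(params.n_chromosomes):
        name = f"chr{c + 1}"
        L = params.genome_length
        seq = _BASES[rng.integers(0, 4, L)]

        gene_spans: list[tuple[int, int]] = []
        for tile_i in range(L // gene_tile):
            off = int(rng.integers(margin, gene_tile - _GENE_SPAN - margin))
            start = tile_i * gene_tile + off
            strand = "+" if rng.random() < 0.5 else "-"
            exons: list[tuple[int, int]] = []
            pos = start
            for ei, el in enumerate(_EXON_LENS):
                exons.append((pos, pos + el))
                pos += el
                if ei < len(_INTRON_LENS):
                    pos += _INTRON_LENS[ei]
            gi += 1
            gene = GeneModel(f"g{gi:05d}", name, strand, exons, list(exons))
            cds = _make_cds(rng, sum(_EXON_LENS) // 3)
            genomic = cds if strand == "+" else revcomp(cds)
            k = 0
            for s, e in exons:
                seq[s:e] = list(genomic[k : k + e - s])
                k += e - s
            genes.append(gene)
            gene_spans.append((gene.start, gene.end))

        for tile_i in range(L // te_tile):
            cons = lib[int(rng.choice(len(lib), p=weights))]
            tsd = params.tsd_len_by_order.get(cons.order, 0)
            slot = len(cons.sequence) + tsd
            placed = False
            for _ in range(1000):
                off = int(rng.integers(margin, te_tile - slot - margin))
                s = tile_i * te_tile + off
                if s < tsd + margin or s + slot > L - margin:
                    continue
                if any(gs - margin < s + slot and s < ge + margin
                       for gs, ge in gene_spans):
                    continue
                if any(t.chrom == name and t.start - margin < s + slot
                       and s < t.end + margin for t in tes[-5:]):
                    continue
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a TE copy in tile {tile_i} of {name}")
            seq[s : s + len(cons.sequence)] = list(cons.sequence)
            if tsd:
                seq[s + len(cons.sequence) : s + slot] = seq[s - tsd : s]
            ti += 1
            is_ltr = cons.order == "LTR"
            tes.append(
                TEAnnotation(
                    f"te{ti:05d}", name, s, s + len(cons.sequence), cons.order,
                    cons.superfamily, intact=True,
                    ltr5=(s, s + cons.ltr_len) if is_ltr else None,
                    ltr3=(s + len(cons.sequence) - cons.ltr_len,
                          s + len(cons.sequence)) if is_ltr else None,
                    consensus_id=cons.id,
                )
            )
        chroms[name] = "".join(seq)
    return ReferenceSet(chroms, genes, tes, {c.id: c for c in lib})


# -------------------------------------------------------------- planting


def _jc_site_prob(mu: float, age_years: float) -> float:
    """Per-site substitution probability on one branch of length mu * age."""
    return 0.75 * (1.0 - math.exp(-4.0 / 3.0 * mu * age_years))


def _mutate(seq: str, p_site: float, rng: np.random.Generator) -> str:
    if p_site <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = np.nonzero(rng.random(len(arr)) < p_site)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _aged_ltr_copy(cons: TEConsensus, age: float, mu: float,
                   rng: np.random.Generator) -> str:
    """A consensus copy whose two LTRs have diverged for ``age`` years."""
    if cons.order != "LTR" or cons.ltr_len == 0:
        return cons.sequence
    p = _jc_site_prob(mu, age)
    s, L = cons.sequence, len(cons.sequence)
    ltr5 = _mutate(s[: cons.ltr_len], p, rng)
    ltr3 = _mutate(s[L - cons.ltr_len :], p, rng)
    return ltr5 + s[cons.ltr_len : L - cons.ltr_len] + ltr3


class _Blocked:
    """Sorted occupancy structure for collision-free event placement."""

    def __init__(self) -> None:
        from intervaltree import IntervalTree

        self.tree = IntervalTree()

    def free(self, start: int, end: int) -> bool:
        return not self.tree.overlaps(start, max(end, start + 1))

    def add(self, start: int, end: int) -> None:
        self.tree.addi(start, max(end, start + 1))


def _place(rng: np.random.Generator, blocked: _Blocked, low: int, high: int,
           length: int, margin: int, what: str,
           extra_ok=None, retries: int = 1000) -> int:
    if high <= low:
        raise PlacementError(f"no room to place {what} (genome too small)")
    for _ in range(retries):
        p = int(rng.integers(low, high))
        if not blocked.free(p - margin, p + length + margin):
            continue
        if extra_ok is not None and not extra_ok(p):
            continue
        return p
    raise PlacementError(f"could not place {what} after {retries} retries")


def plant_variants(reference: ReferenceSet, params: SimParams,
                   rng: np.random.Generator | None = None
                   ) -> tuple[HaplotypePair, TruthSet]:
    """Derive the two phases and the exact truth of their differences.

    LTR aging is applied first (identically in both phases for homozygous
    copies, since phase-1 inherits phase-0's reference copies); all planted
    edits then go into phase-1.  Truth records are left-aligned against the
    final phase-0 sequence.
    """
    params.validate()
    if not params.library():
        raise ValueError("TE library must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    lib = params.library()
    weights = np.array([c.weight for c in lib], dtype=float)
    weights /= weights.sum()
    by_cons = reference.te_consensus
    truth = TruthSet()
    sep = params.min_separation
    margin = params.edge_margin

    # -- 1. zygosity plan and LTR aging of reference copies
    n_ref = len(reference.tes)
    k_each = round(params.het_te_fraction * n_ref / 2.0)
    order_ids = rng.permutation(n_ref)
    del_set = set(order_ids[:k_each].tolist())

    phase0: dict[str, str] = {}
    for chrom, seq in reference.chromosomes.items():
        arr = np.array(list(seq))
        for i, t in enumerate(reference.tes):
            if t.chrom != chrom or t.order != "LTR" or t.ltr5 is None:
                if t.chrom == chrom:
                    label = "heterozygous" if i in del_set else "homozygous"
                    truth.te_zygosity[t.id] = label
                    lo, hi = (params.ltr_age_range_het if i in del_set
                              else params.ltr_age_range_hom)
                    truth.te_age[t.id] = float(rng.uniform(lo, hi))
                continue
            het = i in del_set
            lo, hi = params.ltr_age_range_het if het else params.ltr_age_range_hom
            age = float(rng.uniform(lo, hi))
            truth.te_zygosity[t.id] = "heterozygous" if het else "homozygous"
            truth.te_age[t.id] = age
            p = _jc_site_prob(params.mu, age)
            for iv in (t.ltr5, t.ltr3):
                sub = "".join(arr[iv[0] : iv[1]])
                arr[iv[0] : iv[1]] = list(_mutate(sub, p, rng))
        phase0[chrom] = "".join(arr)

    counters = {"snp": 0, "ind": 0, "sv": 0, "te": 0}

    def next_id(kind: str) -> str:
        counters[kind] += 1
        return f"truth_{kind}{counters[kind]:06d}"

    edits: dict[str, list[tuple[int, int, str, Variant]]] = {
        c: [] for c in phase0
    }

    tes_by_chrom: dict[str, list[TEAnnotation]] = {c: [] for c in phase0}
    for t in reference.tes:
        tes_by_chrom[t.chrom].append(t)

    for chrom, seq in phase0.items():
        L = len(seq)
        blocked = _Blocked()
        blocked.add(0, margin)
        blocked.add(L - margin, L)
        for t in tes_by_chrom[chrom]:
            tsd = params.tsd_len_by_order.get(t.order, 0)
            blocked.add(t.start - sep, t.end + tsd + sep)

        # -- 2. deletions of the chosen reference TE copies (het, P0-specific)
        for i, t in enumerate(reference.tes):
            if t.chrom != chrom or i not in del_set:
                continue
            tsd = params.tsd_len_by_order.get(t.order, 0)
            dlen = len(t) + tsd
            npos, ref_al, alt_al = left_align_indel(seq, t.start, dlen, "")
            var = Variant(chrom, npos, "SV" if dlen >= 40 else "INDEL", "DEL",
                          dlen, ref_al, alt_al, "P0", id=next_id("te"),
                          info={"zyg": "heterozygous", "srcte": t.id})
            edits[chrom].append((t.start, dlen, "", var))

        # -- 3. new heterozygous TE insertions into phase-1 (P1-specific);
        #       same count as the deletions, spread by each chromosome's
        #       share of reference copies
        share = len(tes_by_chrom[chrom]) / max(1, n_ref)
        n_new_c = round(k_each * share)
        for _ in range(n_new_c):
            cons = lib[int(rng.choice(len(lib), p=weights))]
            tsd = params.tsd_len_by_order.get(cons.order, 0)
            age = float(rng.uniform(*params.ltr_age_range_het))
            te_seq = _aged_ltr_copy(cons, age, params.mu, rng)

            def tsd_exact(p: int) -> bool:
                if tsd == 0:
                    return True
                ins = te_seq + seq[p - tsd : p]
                res = detect_tsd(p, ins, seq, max_len=tsd + 10)
                return res.found and res.tsd_length == tsd

            p = _place(rng, blocked, margin + tsd, L - margin, 0, sep,
                       "TE insertion", extra_ok=tsd_exact)
            ins_seq = te_seq + seq[p - tsd : p]
            npos, ref_al, alt_al = left_align_indel(seq, p, 0, ins_seq)
            var = Variant(chrom, npos, "SV", "INS", len(ins_seq), ref_al,
                          alt_al, "P1", id=next_id("te"),
                          info={"zyg": "heterozygous", "srcte": cons.id,
                                "age": age, "ltrlen": cons.ltr_len,
                                "telen": len(te_seq), "tsd": tsd})
            edits[chrom].append((p, 0, ins_seq, var))
            blocked.add(p - sep, p + sep)

        # -- 4. other structural variants (insertions, deletions, inversions,
        #       duplications), to the total SV rate
        n_sv_total = int(rng.poisson(L * params.sv_rate))
        n_te_sv = sum(1 for t in tes_by_chrom[chrom]
                      if truth.te_zygosity.get(t.id) == "heterozygous") + n_new_c
        sv_types = ["INS", "DEL", "INV", "DUP_TANDEM", "DUP_INT"]
        sv_probs = [0.465, 0.465, 0.015, 0.05, 0.005]
        lo, hi = params.sv_length_range
        for _ in range(max(0, n_sv_total - n_te_sv)):
            svtype = sv_types[int(rng.choice(len(sv_types), p=sv_probs))]
            svlen = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
            svlen = min(max(svlen, lo), hi)
            if svtype == "INS":
                p = _place(rng, blocked, margin, L - margin, 0, sep, "SV INS")
                ins = _random_seq(rng, svlen)
                npos, ref_al, alt_al = left_align_indel(seq, p, 0, ins)
                var = Variant(chrom, npos, "SV", "INS", svlen, ref_al, alt_al,
                              "P1", id=next_id("sv"))
                edits[chrom].append((p, 0, ins, var))
                blocked.add(p - sep, p + sep)
            elif svtype == "DEL":
                p = _place(rng, blocked, margin, L - margin - svlen, svlen,
                           sep, "SV DEL")
                npos, ref_al, alt_al = left_align_indel(seq, p, svlen, "")
                var = Variant(chrom, npos, "SV", "DEL", svlen, ref_al, alt_al,
                              "P0", id=next_id("sv"))
                edits[chrom].append((p, svlen, "", var))
                blocked.add(p - sep, p + svlen + sep)
            elif svtype == "INV":

                def inv_ok(p: int) -> bool:
                    seg = seq[p : p + svlen]
                    return seg[0] != revcomp(seg[-1])

                p = _place(rng, blocked, margin, L - margin - svlen, svlen,
                           sep, "SV INV", extra_ok=inv_ok)
                seg = seq[p : p + svlen]
                var = Variant(chrom, p, "SV", "INV", svlen, seg, "", "both",
                              id=next_id("sv"))
                edits[chrom].append((p, svlen, revcomp(seg), var))
                blocked.add(p - sep, p + svlen + sep)
            elif svtype == "DUP_TANDEM":

                def dup_ok(p: int) -> bool:
                    return (p - svlen - 1 >= 0
                            and seq[p - svlen - 1] != seq[p - 1]
                            and blocked.free(p - svlen, p))

                p = _place(rng, blocked, margin + svlen + 1, L - margin, 0,
                           sep, "tandem duplication", extra_ok=dup_ok)
                ins = seq[p - svlen : p]
                npos, ref_al, alt_al = left_align_indel(seq, p, 0, ins)
                var = Variant(chrom, npos, "SV", "DUP_TANDEM", svlen, ref_al,
                              alt_al, "P1", id=next_id("sv"))
                edits[chrom].append((p, 0, ins, var))
                # protect the template copy too: an edit inside it would make
                # the duplication breakpoints ambiguous
                blocked.add(p - svlen - sep, p + sep)
            else:  # DUP_INT: copy of a distant donor interval
                donor = _place(rng, blocked, margin, L - margin - svlen, svlen,
                               0, "duplication donor")
                ins = seq[donor : donor + svlen]

                def far_ok(p: int) -> bool:
                    return abs(p - donor) > 2000

                p = _place(rng, blocked, margin, L - margin, 0, sep,
                           "interspersed duplication", extra_ok=far_ok)
                npos, ref_al, alt_al = left_align_indel(seq, p, 0, ins)
                var = Variant(chrom, npos, "SV", "DUP_INT", svlen, ref_al,
                              alt_al, "P1", id=next_id("sv"),
                              info={"donor": donor})
                edits[chrom].append((p, 0, ins, var))
                blocked.add(p - sep, p + sep)

        # -- 5. short indels (1..39 bp)
        n_indel = int(rng.poisson(L * params.indel_rate))
        for _ in range(n_indel):
            ilen = int(min(rng.geometric(0.35), params.indel_length_max))
            if rng.random() < 0.5:  # insertion
                p = _place(rng, blocked, margin, L - margin, 0, sep, "indel")
                ins = _random_seq(rng, ilen)
                npos, ref_al, alt_al = left_align_indel(seq, p, 0, ins)
                var = Variant(chrom, npos, "INDEL", "INS", ilen, ref_al,
                              alt_al, "P1", id=next_id("ind"))
                edits[chrom].append((p, 0, ins, var))
                blocked.add(p - sep, p + sep)
            else:
                p = _place(rng, blocked, margin, L - margin - ilen, ilen, sep,
                           "indel")
                npos, ref_al, alt_al = left_align_indel(seq, p, ilen, "")
                var = Variant(chrom, npos, "INDEL", "DEL", ilen, ref_al,
                              alt_al, "P0", id=next_id("ind"))
                edits[chrom].append((p, ilen, "", var))
                blocked.add(p - sep, p + ilen + sep)

        # -- 6. SNPs
        n_snp = int(rng.poisson(L * params.snp_rate))
        for _ in range(n_snp):
            p = _place(rng, blocked, margin, L - margin, 1, 2, "SNP")
            ref_b = seq[p]
            alt_b = "ACGT".replace(ref_b, "")[int(rng.integers(0, 3))]
            var = Variant(chrom, p, "SNP", "none", 1, ref_b, alt_b, "both",
                          id=next_id("snp"))
            edits[chrom].append((p, 1, alt_b, var))
            blocked.add(p - 2, p + 3)

    # -- 7. apply edits and finalise truth
    phase1: dict[str, str] = {}
    for chrom, seq in phase0.items():
        ed = sorted(edits[chrom], key=lambda e: (e[0], e[1]))
        parts = []
        cur = 0
        for pos, rlen, alt, var in ed:
            if pos < cur:
                raise PlacementError("overlapping planted events")
            parts.append(seq[cur:pos])
            parts.append(alt)
            cur = pos + rlen
            truth.planted_variants.append(var)
        parts.append(seq[cur:])
        phase1[chrom] = "".join(parts)

    truth.planted_variants.sort(key=lambda v: (v.chrom, v.pos))

    # -- 8. true allelic ratios: PAV genes are fully P0; a fraction of the
    #       rest get a shared non-0.5 ratio across organs
    organs = [f"organ{i + 1}" for i in range(params.n_organs)]
    del_ivs: dict[str, list[tuple[int, int]]] = {c: [] for c in phase0}
    for v in truth.planted_variants:
        if v.is_deletion():
            del_ivs[v.chrom].append((v.pos, v.end))
    for g in reference.genes:
        if any(s <= g.start and g.end <= e for s, e in del_ivs[g.chrom]):
            ratio = 1.0
        elif rng.random() < params.ase_effect_fraction:
            r = params.ase_effect_ratio
            ratio = r if rng.random() < 0.5 else 1.0 - r
        else:
            ratio = 0.5
        truth.gene_allelic_ratios[g.id] = {o: ratio for o in organs}

    return HaplotypePair(phase0, phase1), truth


# -------------------------------------------------------------- counts


def simulate_allele_counts(truth: TruthSet, params: SimParams,
                           rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Negative-binomial totals split binomially by the true P0 fraction,
    per gene x organ x replicate."""
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    if not truth.gene_allelic_ratios:
        raise ValueError("truth has no gene allelic ratios")
    theta = params.nb_dispersion
    p_nb = theta / (theta + params.mean_depth)
    rows = []
    for gene in sorted(truth.gene_allelic_ratios):
        for organ, ratio in truth.gene_allelic_ratios[gene].items():
            for rep in range(1, params.n_replicates + 1):
                n = int(rng.negative_binomial(theta, p_nb))
                x = int(rng.binomial(n, ratio)) if n else 0
                rows.append({"gene": gene, "organ": organ, "replicate": rep,
                             "count_p0": x, "count_p1": n - x})
    return pd.DataFrame(rows)


# -------------------------------------------------------------- fixtures


def write_fixture(directory, reference: ReferenceSet, pair: HaplotypePair,
                  truth: TruthSet, counts: pd.DataFrame | None = None
                  ) -> dict[str, Path]:
    """Write the full fixture set; files round-trip through the package's
    own readers."""
    out = dio.ensure_dir(directory)
    paths = {
        "phase0": out / "phase0.fa",
        "phase1": out / "phase1.fa",
        "genes": out / "genes.gff3",
        "tes": out / "tes.gff3",
        "truth_vcf": out / "truth_variants.vcf",
        "zygosity_bed": out / "te_zygosity_truth.bed",
        "ratios": out / "gene_allelic_ratios.json",
    }
    dio.write_fasta(pair.phase0, paths["phase0"])
    dio.write_fasta(pair.phase1, paths["phase1"])
    dio.write_genes_gff3(reference.genes, paths["genes"])
    dio.write_tes_gff3(reference.tes, paths["tes"])
    dio.write_vcf(truth.planted_variants, pair.phase0, paths["truth_vcf"])
    from .models import ZygosityCall

    calls = [ZygosityCall(te_id, lab) for te_id, lab in truth.te_zygosity.items()]
    dio.write_zygosity_bed(reference.tes, calls, paths["zygosity_bed"])
    with open(paths["ratios"], "w") as fh:
        json.dump(truth.gene_allelic_ratios, fh, indent=1, sort_keys=True)
    if counts is not None:
        paths["counts"] = out / "allele_counts.tsv"
        dio.write_counts_tsv(counts, paths["counts"])
    return paths
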
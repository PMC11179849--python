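"""Transposable-element zygosity, target-site duplications, and LTR dating.

A TE copy present in only one haplotype shows up as a deletion in the other
haplotype's alignment; the reciprocal-overlap rule turns TE x deletion
intersections into het/hom calls.  LTR retrotransposons carry two terminal
repeats that are identical at insertion time, so their divergence, under a
substitution model and a clock rate, dates the insertion.
"""

from __future__ import annotations

import math
from collections import defaultdict

import edlib
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import (
    AgeEstimate,
    AlignmentBlock,
    FlankUnavailableError,
    GeneModel,
    SaturatedDivergenceError,
    TEAnnotation,
    TsdResult,
    Variant,
    ZygosityCall,
)

# -------------------------------------------------------------- zygosity


def merged_reference_intervals(blocks: list[AlignmentBlock]) -> dict[str, list[tuple[int, int]]]:
    """Union of the reference intervals covered by alignment blocks."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for b in blocks:
        by_chrom[b.ref_name].append((b.ref_start, b.ref_end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [tuple(x) for x in out]
    return merged


def classify_te_zygosity(
    tes: list[TEAnnotation],
    deletions: list[Variant],
    alignment_blocks: list[AlignmentBlock],
    *,
    min_frac_of_deletion: float = 0.5,
    min_frac_of_te: float = 0.8,
) -> list[ZygosityCall]:
    """Reciprocal-overlap classification of TEs against the SV deletion set.

    heterozygous: the best-overlapping deletion is spanned by the TE for
    strictly more than ``min_frac_of_deletion`` of the deletion's length AND
    the deletion covers at least ``min_frac_of_te`` of the TE.
    partial: some deletion overlap but below the reciprocal thresholds.
    homozygous: no deletion overlap and the TE interval 100% covered by the
    genome alignment.  unresolved: anything else.
    """
    for t in tes:
        if t.end <= t.start:
            raise ValueError(f"TE {t.id}: negative-length interval")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, d in enumerate(deletions):
        if d.end <= d.pos:
            raise ValueError(f"deletion {d.id or i}: negative-length interval")
        trees[d.chrom].addi(d.pos, d.end, (d.pos, d.id or f"del{i}", d.length))
    covered = merged_reference_intervals(alignment_blocks)

    calls: list[ZygosityCall] = []
    for t in tes:
        te_len = len(t)
        hits = []
        for iv in trees[t.chrom].overlap(t.start, t.end):
            ov = min(t.end, iv.end) - max(t.start, iv.begin)
            if ov > 0:
                hits.append((ov, iv.begin, iv.data))
        if hits:
            # maximal overlap, ties broken by leftmost deletion start
            hits.sort(key=lambda h: (-h[0], h[1]))
            ov, _, (dpos, did, dlen) = hits[0]
            f_del = ov / dlen
            f_te = ov / te_len
            label = (
                "heterozygous"
                if f_del > min_frac_of_deletion and f_te >= min_frac_of_te
                else "partial"
            )
            calls.append(ZygosityCall(t.id, label, ov, f_del, f_te, did))
            continue
        fully = any(
            s <= t.start and t.end <= e for s, e in covered.get(t.chrom, [])
        )
        calls.append(ZygosityCall(t.id, "homozygous" if fully else "unresolved"))
    return calls


# -------------------------------------------------------------- TSD


def detect_tsd(pos: int, inserted_seq: str, chrom_seq: str,
               max_len: int = 20) -> TsdResult:
    """Search the insertion breakpoint for a target-site duplication.

    Reports the largest k <= max_len such that the k-mer immediately 5' of
    the breakpoint equals the terminal k-mer of the inserted sequence (exact
    match).  The insertion is first rotated to its rightmost equivalent
    placement, so any left-aligned (VCF-normalised) representation gives the
    same answer.  found is False with length 0 when no k >= 2 matches.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if not inserted_seq:
        raise ValueError("empty inserted sequence")
    if pos < 2 or pos > len(chrom_seq) - 1:
        raise FlankUnavailableError(
            f"breakpoint {pos} too close to a contig edge for TSD search"
        )
    s = inserted_seq
    # rotate to the rightmost placement (bounded: rotations cycle)
    for _ in range(len(s) + max_len):
        if pos < len(chrom_seq) and s[0] == chrom_seq[pos]:
            s = s[1:] + s[0]
            pos += 1
        else:
            break
    for k in range(min(max_len, pos, len(s)), 1, -1):
        if chrom_seq[pos - k : pos] == s[-k:]:
            return TsdResult("", k, s[-k:], True)
    return TsdResult("", 0, "", False)


def detect_tsd_for_variant(v: Variant, seqs: dict[str, str],
                           max_len: int = 20) -> TsdResult:
    if not v.is_insertion() or not v.alt_allele:
        raise ValueError("TSD detection requires an insertion with its sequence")
    res = detect_tsd(v.pos, v.alt_allele, seqs[v.chrom], max_len=max_len)
    res.sv_id = v.id
    return res


# -------------------------------------------------------------- LTR dating


def _aligned_columns(a: str, b: str) -> tuple[int, int]:
    """(ungapped columns, mismatches) after a global alignment of two LTRs."""
    if not a or not b:
        raise ValueError("empty LTR sequence")
    if len(a) == len(b):
        mism = sum(1 for x, y in zip(a, b) if x != y)
        return len(a), mism
    res = edlib.align(a, b, mode="NW", task="path")
    sites = mism = 0
    for n, op in _iter_cigar(res["cigar"]):
        if op == "=":
            sites += n
        elif op == "X":
            sites += n
            mism += n
    return sites, mism


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturatedDivergenceError(f"mismatch proportion {p:.3f} >= 0.75")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kimura2p(transitions: float, transversions: float, sites: int) -> float:
    P, Q = transitions / sites, transversions / sites
    inner = (1 - 2 * P - Q) * math.sqrt(1 - 2 * Q)
    if inner <= 0:
        raise SaturatedDivergenceError("K2P distance undefined for these counts")
    return -0.5 * math.log(inner)


_PURINES = {"A", "G"}


def ltr_insertion_age(ltr5_seq: str, ltr3_seq: str, mu: float = 1.3e-8,
                      model: str = "jc", te_id: str = "") -> AgeEstimate:
    """Date an LTR-RT insertion from the divergence of its two LTRs.

    d is the substitution distance between the LTRs; since both diverged from
    a common sequence at insertion, age = d / (2 * mu).
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    sites, mism = _aligned_columns(ltr5_seq.upper(), ltr3_seq.upper())
    if sites == 0:
        raise ValueError("empty LTR alignment")
    p = mism / sites
    if model == "jc":
        d = jukes_cantor(p)
    elif model == "k2p":
        ts = tv = 0
        if len(ltr5_seq) == len(ltr3_seq):
            for x, y in zip(ltr5_seq.upper(), ltr3_seq.upper()):
                if x != y:
                    if (x in _PURINES) == (y in _PURINES):
                        ts += 1
                    else:
                        tv += 1
        else:  # fall back through the JC mismatch proportion split 1:2
            ts, tv = mism / 3.0, 2.0 * mism / 3.0
        d = kimura2p(ts, tv, sites)
    else:
        raise ValueError(f"unknown substitution model {model!r}")
    return AgeEstimate(te_id, d, d / (2.0 * mu), mu, mismatch_p=p, sites=sites)


def compare_age_by_zygosity(
    ages_het: list[float], ages_hom: list[float]
) -> tuple[float, float, float | None]:
    """Group means and two-sided Wilcoxon rank-sum p (None when a group n < 3)."""
    if not ages_het or not ages_hom:
        raise ValueError("both groups must be non-empty")
    mean_het = float(np.mean(ages_het))
    mean_hom = float(np.mean(ages_hom))
    if min(len(ages_het), len(ages_hom)) < 3:
        return mean_het, mean_hom, None
    p = float(
        stats.mannwhitneyu(ages_het, ages_hom, alternative="two-sided").pvalue
    )
    return mean_het, mean_hom, p


# -------------------------------------------------------------- geometry


def te_gene_distance(
    tes: list[TEAnnotation],
    genes: list[GeneModel],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Distance of each TE to its nearest gene (0 when overlapping).

    Chromosomes without genes yield NaN distances.  When ``labels`` maps TE id
    to a zygosity label, the result carries it for grouped summaries.
    """
    bounds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in genes:
        bounds[g.chrom].append((g.start, g.end))
    for chrom in bounds:
        bounds[chrom].sort()
    rows = []
    for t in tes:
        gl = bounds.get(t.chrom)
        if not gl:
            dist = math.nan
        else:
            # gap in bp between closest boundaries of half-open intervals
            # ([5000,6000) vs [8000,9000) -> 2000); 0 when overlapping
            dist = min(
                0 if (s < t.end and t.start < e)
                else (s - t.end if s >= t.end else t.start - e)
                for s, e in gl
            )
        rows.append({"te_id": t.id, "chrom": t.chrom, "distance": dist,
                     "label": (labels or {}).get(t.id, "")})
    return pd.DataFrame(rows)


def grouped_median_distance(df: pd.DataFrame) -> pd.Series:
    return df.dropna(subset=["distance"]).groupby("label")["distance"].median()


def window_density(
    features: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    window_bp: int,
) -> dict[str, np.ndarray]:
    """Fraction of each non-overlapping window covered by the (merged) features."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    ivs: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, s, e in features:
        if e > s:
            ivs[chrom].append((max(0, s), min(e, chrom_lengths.get(chrom, e))))
    out: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_win = (length + window_bp - 1) // window_bp
        cov = np.zeros(n_win, dtype=float)
        merged: list[list[int]] = []
        for s, e in sorted(ivs.get(chrom, [])):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            w0, w1 = s // window_bp, (e - 1) // window_bp
            for w in range(w0, w1 + 1):
                ws, we = w * window_bp, min((w + 1) * window_bp, length)
                cov[w] += max(0, min(e, we) - max(s, ws))
        for w in range(n_win):
            wlen = min((w + 1) * window_bp, length) - w * window_bp
            cov[w] /= wlen
        out[chrom] = cov
    return out


def density_to_bedgraph(density: dict[str, np.ndarray], chrom_lengths: dict[str, int],
                        window_bp: int) -> dict[str, list[tuple[int, int, float]]]:
    track = {}
    for chrom, vals in density.items():
        rows = []
        for w, v in enumerate(vals):
            rows.append((w * window_bp, min((w + 1) * window_bp, chrom_lengths[chrom]), float(v)))
        track[chrom] = rows
    return track
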
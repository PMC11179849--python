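"""Shared domain types for phased-diploid variant analysis.

Coordinates are 0-based half-open everywhere inside the package; file writers
translate to the 1-based conventions of VCF/GFF3 and the 0-based convention of
BED at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class PlacementError(RuntimeError):
    """A planted event could not be placed without collision."""


class SizingError(ValueError):
    """Requested genome too small to host the requested annotations."""


class FlankUnavailableError(ValueError):
    """An insertion breakpoint sits too close to a contig edge to test a TSD."""


class SaturatedDivergenceError(ValueError):
    """LTR mismatch proportion at or beyond the Jukes-Cantor domain (p >= 0.75)."""


class DependencyError(RuntimeError):
    """A pipeline stage is missing the output of an upstream stage."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def left_align_indel(seq: str, pos: int, ref_len: int, alt: str) -> tuple[int, str, str]:
    """Shift a pure insertion or deletion to its leftmost equivalent position.

    ``pos``/``ref_len`` describe the replaced reference interval (ref_len == 0
    for an insertion of ``alt`` before ``pos``; alt == "" for a deletion).
    Returns (pos, ref_allele, alt_allele) in the canonical leftmost form.
    """
    if ref_len > 0 and alt == "":
        # deletion of seq[pos:pos+ref_len]
        while pos > 0 and seq[pos - 1] == seq[pos + ref_len - 1]:
            pos -= 1
        return pos, seq[pos : pos + ref_len], ""
    if ref_len == 0 and alt:
        s = alt
        while pos > 0 and s[-1] == seq[pos - 1]:
            s = s[-1] + s[:-1]
            pos -= 1
        return pos, "", s
    return pos, seq[pos : pos + ref_len], alt


@dataclass
class AlignmentBlock:
    """One chained alignment block between phase-0 (ref) and phase-1 (query).

    The CIGAR is a list of (op, length) with op in {"=", "X", "M", "I", "D"};
    "I" consumes query only (sequence present in the query), "D" consumes
    reference only.  For strand "-", query coordinates are forward-strand but
    the CIGAR walks the query from ``query_end`` backwards (reverse
    complement), as in PAF.
    """

    ref_name: str
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str
    cigar: list[tuple[str, int]] = field(default_factory=list)

    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    def query_span(self) -> int:
        return self.query_end - self.query_start

    def validate(self) -> None:
        r = sum(n for op, n in self.cigar if op in "=XMD")
        q = sum(n for op, n in self.cigar if op in "=XMI")
        if r != self.ref_span() or q != self.query_span():
            raise ValueError(
                f"CIGAR spans ({r}, {q}) inconsistent with block "
                f"({self.ref_span()}, {self.query_span()})"
            )
        if any(n <= 0 for _, n in self.cigar):
            raise ValueError("zero/negative-length CIGAR op")


@dataclass
class Variant:
    """A single difference between the two phases, on phase-0 coordinates.

    SNP: ref_allele/alt_allele are single bases.  Insertions have ref_allele
    "" (sequence present in phase-1 before ``pos``); deletions have
    alt_allele "" (phase-0 sequence absent from phase-1).  Inversions carry
    the reference span as length with symbolic alleles.
    """

    chrom: str
    pos: int
    var_class: str  # SNP | INDEL | SV
    svtype: str  # INS | DEL | INV | DUP_TANDEM | DUP_INT | none
    length: int
    ref_allele: str
    alt_allele: str
    phase_of_presence: str  # P0 | P1 | both
    id: str = ""
    info: dict = field(default_factory=dict)

    @property
    def end(self) -> int:
        """End of the affected reference interval (== pos for insertions)."""
        if self.svtype in ("DEL", "INV"):
            return self.pos + self.length
        if self.var_class == "SNP":
            return self.pos + 1
        return self.pos + len(self.ref_allele)

    def is_insertion(self) -> bool:
        return self.svtype in ("INS", "DUP_TANDEM", "DUP_INT")

    def is_deletion(self) -> bool:
        return self.svtype == "DEL"


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    def validate(self) -> None:
        if not self.cds or self.cds_len() <= 0:
            raise ValueError(f"gene {self.id}: empty CDS")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"gene {self.id}: CDS outside exons")


@dataclass
class TEAnnotation:
    id: str
    chrom: str
    start: int
    end: int
    order: str  # LTR | TIR | MITE | Helitron | LINE
    superfamily: str
    intact: bool = False
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    consensus_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"TE {self.id}: end <= start")
        for ltr in (self.ltr5, self.ltr3):
            if ltr is not None and not (self.start <= ltr[0] < ltr[1] <= self.end):
                raise ValueError(f"TE {self.id}: LTR interval outside element")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ZygosityCall:
    te_id: str
    label: str  # heterozygous | homozygous | partial | unresolved
    overlap_bp: int = 0
    frac_of_deletion: float = 0.0
    frac_of_te: float = 0.0
    deletion_id: str | None = None


@dataclass
class TsdResult:
    sv_id: str
    tsd_length: int
    tsd_sequence: str
    found: bool


@dataclass
class AgeEstimate:
    te_id: str
    divergence: float  # substitutions/site under the chosen model
    age_years: float
    mu: float
    mismatch_p: float = 0.0
    sites: int = 0


@dataclass
class EffectCall:
    variant_id: str
    gene_id: str
    region: str  # CDS | intron | upstream | downstream | intergenic
    effect: str
    impact: str  # HIGH | MODERATE | LOW | MODIFIER
    var_class: str = ""


IMPACT_BY_EFFECT = {
    "frameshift_variant": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "gene_deleted": "HIGH",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "intron_variant": "MODIFIER",
    "upstream_variant": "MODIFIER",
    "downstream_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}
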
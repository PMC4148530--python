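"""Diagnostic-SNP survival screening for bisulfite amplicons.

Homeolog-specific methylation calling in an allopolyploid hinges on parental
SNPs that remain readable *after* bisulfite conversion: a C/T polymorphism
whose C sits in a convertible (non-CG) context collapses to T/T on that
strand and is useless, while the complementary strand may still carry a
readable G/A difference. This module finds parental SNPs, classifies their
per-strand post-conversion observability, and reports whether an amplicon
retains enough diagnostic SNPs to be worth sequencing at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .sequtil import (
    BASES,
    CytosineContext,
    classify_context,
    clean_seq,
    complement,
    reverse_complement,
)

__all__ = [
    "LocusReference",
    "DiagnosticSNP",
    "find_snps",
    "post_conversion_observables",
    "classify_snp",
    "locus_amenability",
    "AmenabilityReport",
]

DIAGNOSTIC = "diagnostic"
LOST = "lost"
CONFOUNDED = "confounded"


@dataclass
class LocusReference:
    """Aligned parental haplotypes plus region annotation for one locus.

    Parent A is the *T. dubius*-like haplotype, parent B the
    *T. pratensis*-like one; sequences must be equal length, gap-free and
    pre-aligned (amplicon-scale loci; indels are rejected, not skipped).
    ``regions`` are disjoint half-open ``(start, end, label)`` intervals with
    label "promoter" or "genic".
    """

    locus_id: str
    seq_parent_A: str
    seq_parent_B: str
    regions: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq_parent_A = clean_seq(self.seq_parent_A)
        self.seq_parent_B = clean_seq(self.seq_parent_B)
        if len(self.seq_parent_A) != len(self.seq_parent_B):
            raise ValueError(
                f"{self.locus_id}: parental sequences differ in length "
                f"({len(self.seq_parent_A)} vs {len(self.seq_parent_B)})"
            )
        for seq, name in ((self.seq_parent_A, "A"), (self.seq_parent_B, "B")):
            if "-" in seq:
                raise ValueError(f"{self.locus_id}: gap column in parent {name}")
            if set(seq) - BASES:
                raise ValueError(
                    f"{self.locus_id}: parent {name} contains ambiguity codes"
                )
        last = 0
        for start, end, label in sorted(self.regions):
            if not (0 <= start < end <= len(self.seq_parent_A)):
                raise ValueError(f"{self.locus_id}: region {(start, end)} out of bounds")
            if start < last:
                raise ValueError(f"{self.locus_id}: overlapping regions")
            if label not in ("promoter", "genic"):
                raise ValueError(f"{self.locus_id}: unknown region label {label!r}")
            last = end

    def __len__(self) -> int:
        return len(self.seq_parent_A)

    def parent_seq(self, which: str) -> str:
        if which == "A":
            return self.seq_parent_A
        if which == "B":
            return self.seq_parent_B
        raise KeyError(which)

    def region_of(self, pos: int) -> str:
        for start, end, label in self.regions:
            if start <= pos < end:
                return label
        return "unannotated"

    @property
    def cg_catalog(self):
        """CG-site catalog (computed lazily; see :func:`bsphase.methylcall.build_cg_catalog`)."""
        from .methylcall import build_cg_catalog

        return build_cg_catalog(self)


@dataclass
class DiagnosticSNP:
    """A parental polymorphism with per-strand post-conversion observability.

    ``status_*`` is one of: "diagnostic" (the two alleles' post-conversion
    observable base sets are disjoint on that strand), "lost" (both alleles
    convert to determinate, overlapping — i.e. identical — observations), or
    "confounded" (the observable sets overlap because at least one allele's
    converted identity depends on its methylation state).
    """

    pos: int
    allele_A: str
    allele_B: str
    context_A: dict[str, str | None] = field(default_factory=dict)
    context_B: dict[str, str | None] = field(default_factory=dict)
    status_sense: str | None = None
    status_antisense: str | None = None

    def __post_init__(self) -> None:
        if self.allele_A == self.allele_B:
            raise ValueError(f"not a polymorphism at {self.pos}: {self.allele_A}")

    def status(self, strand: str) -> str | None:
        return self.status_sense if strand == "sense" else self.status_antisense


def find_snps(ref: LocusReference) -> list[DiagnosticSNP]:
    """All positions where the parents differ, ascending, statuses unset."""
    return [
        DiagnosticSNP(pos=i, allele_A=a, allele_B=b)
        for i, (a, b) in enumerate(zip(ref.seq_parent_A, ref.seq_parent_B))
        if a != b
    ]


def post_conversion_observables(
    allele: str, pos: int, strand: str, locus_seq: str
) -> frozenset[str]:
    """Possible post-conversion reads of ``allele`` placed at ``pos``.

    Assumes complete conversion and no non-CG methylation (deviations are
    surfaced by conversion QC, not by widening these sets): a non-C allele
    reads as itself; a C in non-CG context always converts to T; a C in CG
    context reads C or T depending on methylation. The antisense strand is
    evaluated on the reverse-complemented haplotype at the mapped coordinate.
    """
    allele = str(allele).upper()
    if allele not in BASES:
        raise ValueError(f"invalid base {allele!r}")
    seq = clean_seq(locus_seq)
    hap = seq[:pos] + allele + seq[pos + 1 :]
    if strand == "antisense":
        return post_conversion_observables(
            complement(allele), len(hap) - 1 - pos, "sense", reverse_complement(hap)
        )
    if strand != "sense":
        raise ValueError(f"bad strand {strand!r}")
    if allele != "C":
        return frozenset({allele})
    ctx = classify_context(hap, pos, "sense")
    if ctx == CytosineContext.CG:
        return frozenset({"C", "T"})
    if ctx == CytosineContext.EDGE:
        # context (hence convertibility interpretation) undefined; keep both
        return frozenset({"C", "T"})
    return frozenset({"T"})


def _strand_context(allele: str, pos: int, strand: str, locus_seq: str) -> str | None:
    """Context of the allele's cytosine on ``strand``, if it has one there."""
    hap = locus_seq[:pos] + allele + locus_seq[pos + 1 :]
    strand_base = allele if strand == "sense" else complement(allele)
    if strand_base != "C":
        return None
    return classify_context(hap, pos, strand)


def classify_snp(snp: DiagnosticSNP, ref: LocusReference) -> DiagnosticSNP:
    """Set per-strand observability statuses on a SNP.

    Each allele's observables are computed in its *own* parental haplotype
    context — a SNP can create a CG in one parent only, which matters both
    here and for genotype-determined methylation calls downstream.
    """
    statuses: dict[str, str] = {}
    ctx_A: dict[str, str | None] = {}
    ctx_B: dict[str, str | None] = {}
    for strand in ("sense", "antisense"):
        obs_a = post_conversion_observables(snp.allele_A, snp.pos, strand, ref.seq_parent_A)
        obs_b = post_conversion_observables(snp.allele_B, snp.pos, strand, ref.seq_parent_B)
        ctx_A[strand] = _strand_context(snp.allele_A, snp.pos, strand, ref.seq_parent_A)
        ctx_B[strand] = _strand_context(snp.allele_B, snp.pos, strand, ref.seq_parent_B)
        if not obs_a & obs_b:
            statuses[strand] = DIAGNOSTIC
        elif len(obs_a) == 1 and len(obs_b) == 1:
            statuses[strand] = LOST
        else:
            statuses[strand] = CONFOUNDED
    return replace(
        snp,
        context_A=ctx_A,
        context_B=ctx_B,
        status_sense=statuses["sense"],
        status_antisense=statuses["antisense"],
    )


@dataclass
class AmenabilityReport:
    locus_id: str
    amenable: bool
    usable_snps_sense: list[DiagnosticSNP]
    usable_snps_antisense: list[DiagnosticSNP]


def locus_amenability(
    snps: list[DiagnosticSNP],
    amplicon: tuple[int, int],
    locus_id: str = "",
    min_diagnostic: int = 1,
) -> AmenabilityReport:
    """Is an amplicon worth sequencing on either strand?

    Amenable iff at least ``min_diagnostic`` classified-diagnostic SNPs fall
    inside the half-open ``amplicon`` interval on at least one strand (the
    screen that excludes loci like S8, where no parental SNP survives
    conversion on any readable strand).
    """
    start, end = amplicon
    if end <= start:
        raise ValueError(f"empty amplicon {amplicon}")
    inside = [s for s in snps if start <= s.pos < end]
    if any(s.status_sense is None for s in inside):
        raise ValueError("SNPs must be classified before the amenability screen")
    usable_s = [s for s in inside if s.status_sense == DIAGNOSTIC]
    usable_a = [s for s in inside if s.status_antisense == DIAGNOSTIC]
    amenable = len(usable_s) >= min_diagnostic or len(usable_a) >= min_diagnostic
    return AmenabilityReport(locus_id, amenable, usable_s, usable_a)
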
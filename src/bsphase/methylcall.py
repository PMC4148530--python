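"""Per-CG-site, per-strand, homeolog-aware methylation calling.

The caller reads bisulfite-converted Sanger consensus observations of an
allopolyploid against the two aligned parental haplotypes. At a CG site
shared by both homeologs, a pure C peak means both copies are methylated, a
pure T means both are unmethylated, and a composite Y peak is a mixture that
direct sequencing cannot phase (clone sequencing resolves it, see
:mod:`bsphase.clone_quant`). At a CG site that a parental SNP destroyed in
one homeolog, the surviving copy's state is *genotype-determined*: the
non-carrier homeolog's contribution to the peak is fixed by its own allele,
so the composite either does or does not contain a C from the carrier.

Conversion integrity is checked the standard way: every C not followed by G
must read T after conversion; residual non-CG Cs are flagged (incomplete
conversion, or possibly CHH/CHG methylation — the context is recorded so
that reading stays available) and never interpreted as CG methylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .bisulfite_sim import ConvertedObservation
from .sequtil import CytosineContext, context_map, expand_code, reverse_complement
from .snp_diagnostics import LocusReference

__all__ = [
    "CGSite",
    "MethylationCall",
    "ConversionQC",
    "ConcordanceVerdict",
    "build_cg_catalog",
    "conversion_qc",
    "call_cg_site",
    "call_locus",
    "detect_hemimethylation",
    "summarize_locus",
    "integrate_silencing",
]

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
MIXED = "mixed"
NO_DATA = "no_data"


@dataclass(frozen=True)
class CGSite:
    """One CG dinucleotide of the parental alignment.

    ``sense_c_pos`` is the sense-strand cytosine; ``antisense_c_pos`` is the
    sense coordinate of the paired G (the antisense cytosine),
    always ``sense_c_pos + 1``. ``present_in`` records which parent(s) carry
    the intact dinucleotide — a SNP can destroy the site in one parent,
    which is what makes genotype-determined calls possible.
    """

    sense_c_pos: int
    region: str
    present_in: str  # "A" | "B" | "both"

    def __post_init__(self) -> None:
        if self.present_in not in ("A", "B", "both"):
            raise ValueError(f"bad present_in {self.present_in!r}")

    @property
    def antisense_c_pos(self) -> int:
        return self.sense_c_pos + 1


@dataclass
class MethylationCall:
    site: CGSite
    strand: str  # sense | antisense
    level: str  # methylated | unmethylated | mixed | no_data
    homeolog: str  # both | A | B | unassigned
    evidence: str  # genotype_determined | uniform | clone_phased | none
    obs_base: str | None = None
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.level in (METHYLATED, UNMETHYLATED) and self.homeolog == "both":
            if self.obs_base is not None and self.obs_base not in ("C", "T"):
                raise ValueError("a both-homeolog determinate call needs a C or T peak")
        if self.homeolog in ("A", "B") and self.evidence == "uniform":
            raise ValueError("uniform evidence cannot assign a single homeolog")


@dataclass
class ConversionQC:
    """Conversion-integrity report for one converted observation."""

    unconverted_positions: list[tuple[int, str, str, str]]  # (sense pos, strand, context, observed)
    conversion_rate: float
    verdict: str  # complete | incomplete
    n_checked: int = 0


def build_cg_catalog(ref: LocusReference) -> list[CGSite]:
    """Catalog every CG dinucleotide present in either parent.

    Sites are sorted by position and labeled with the region overlapping the
    sense cytosine ("unannotated" when outside every region). Sites whose
    cytosine sits within 2 bases of either sequence end are dropped: their
    context on one of the strands cannot be resolved.
    """
    n = len(ref)
    sites = []
    for pos in range(1, n - 2):
        in_a = ref.seq_parent_A[pos : pos + 2] == "CG"
        in_b = ref.seq_parent_B[pos : pos + 2] == "CG"
        if not (in_a or in_b):
            continue
        present = "both" if (in_a and in_b) else ("A" if in_a else "B")
        sites.append(CGSite(sense_c_pos=pos, region=ref.region_of(pos), present_in=present))
    return sites


def _strand_view(seq: str, strand: str) -> str:
    return seq if strand == "sense" else reverse_complement(seq)


def _frame_pos(sense_pos: int, strand: str, length: int) -> int:
    """Map a sense coordinate into the strand product's reading frame."""
    return sense_pos if strand == "sense" else length - 1 - sense_pos


def obs_strand(obs: ConvertedObservation) -> str:
    return "sense" if obs.strand_product == "sense_derived" else "antisense"


def conversion_qc(
    obs: ConvertedObservation,
    ref: LocusReference,
    catalog: Sequence[CGSite] | None = None,
    parents: Iterable[str] = ("A", "B"),
) -> ConversionQC:
    """Check that every convertible (non-CG) C reads T in an observation.

    ``parents`` names the haplotypes expected in the template pool (both for
    a polyploid consensus, one for an assigned clone). A position enters the
    check when at least one relevant parent carries a CHH/CHG cytosine there
    and *no* relevant parent carries a CG cytosine there (a CG C may
    legitimately read C through methylation, so such columns cannot falsify
    conversion). Observed N drops the position from the denominator.
    """
    strand = obs_strand(obs)
    n = len(ref)
    if len(obs.seq) != n:
        raise ValueError(
            f"observation length {len(obs.seq)} != locus length {n} "
            f"(observations must be pre-aligned)"
        )
    views = {p: _strand_view(ref.parent_seq(p), strand) for p in parents}
    ctx_maps = {p: context_map(v) for p, v in views.items()}
    failures: list[tuple[int, str, str, str]] = []
    checked = 0
    converted = 0
    for i in range(n):
        contexts = []
        cg_here = False
        for cmap in ctx_maps.values():
            ctx = cmap[i]
            if ctx == CytosineContext.CG:
                cg_here = True
            elif ctx in (CytosineContext.CHG, CytosineContext.CHH):
                contexts.append(ctx)
        if cg_here or not contexts:
            continue
        observed = obs.seq[i]
        if observed == "N":
            continue
        checked += 1
        sense_pos = _frame_pos(i, strand, n)
        if "C" in expand_code(observed):
            failures.append((sense_pos, strand, contexts[0], observed))
        else:
            converted += 1
    rate = converted / checked if checked else 1.0
    verdict = "incomplete" if failures else "complete"
    return ConversionQC(failures, rate, verdict, n_checked=checked)


def call_cg_site(
    obs_base: str,
    site: CGSite,
    strand: str,
    other_converted: str | None = None,
) -> MethylationCall:
    """Call one CG site on one strand from a consensus peak.

    ``obs_base`` is the IUPAC code observed at the site's cytosine in the
    strand product's frame. For a site present in a single parent,
    ``other_converted`` is the base the non-carrier parent contributes to
    the composite peak after conversion (computed from its own allele; see
    :func:`call_locus`).
    """
    base_set = expand_code(obs_base)  # validates the symbol
    if site.present_in == "both":
        if obs_base == "C":
            return MethylationCall(site, strand, METHYLATED, "both", "uniform", obs_base)
        if obs_base == "T":
            return MethylationCall(site, strand, UNMETHYLATED, "both", "uniform", obs_base)
        if obs_base == "Y":
            return MethylationCall(site, strand, MIXED, "unassigned", "none", obs_base)
        return MethylationCall(site, strand, NO_DATA, "unassigned", "none", obs_base, conflict=True)
    carrier = site.present_in
    if other_converted is None:
        raise ValueError(
            "a single-parent site needs the non-carrier parent's converted base"
        )
    other = frozenset(expand_code(other_converted))
    exp_unmeth = other | {"T"}
    exp_meth = other | {"C"}
    exp_mixed = other | {"C", "T"}
    if base_set == exp_unmeth:
        return MethylationCall(site, strand, UNMETHYLATED, carrier, "genotype_determined", obs_base)
    if base_set == exp_meth:
        return MethylationCall(site, strand, METHYLATED, carrier, "genotype_determined", obs_base)
    if base_set == exp_mixed:
        return MethylationCall(site, strand, MIXED, carrier, "genotype_determined", obs_base)
    return MethylationCall(site, strand, NO_DATA, "unassigned", "none", obs_base, conflict=True)


def _other_converted_base(site: CGSite, strand: str, ref: LocusReference) -> str:
    """Post-conversion base the non-carrier parent shows at the site's C.

    Because the non-carrier lacks the CG dinucleotide, any C it carries at
    the column is non-CG and converts to T under the QC-enforced assumption
    of complete conversion without non-CG methylation.
    """
    other = "B" if site.present_in == "A" else "A"
    view = _strand_view(ref.parent_seq(other), strand)
    pos = _frame_pos(
        site.sense_c_pos if strand == "sense" else site.antisense_c_pos, strand, len(ref)
    )
    base = view[pos]
    return "T" if base == "C" else base


def call_locus(
    obs_sense: ConvertedObservation | None,
    obs_antisense: ConvertedObservation | None,
    ref: LocusReference,
    catalog: Sequence[CGSite] | None = None,
) -> dict[str, list[MethylationCall]]:
    """Call every cataloged CG site on both strands of one locus."""
    if catalog is None:
        catalog = build_cg_catalog(ref)
    n = len(ref)
    out: dict[str, list[MethylationCall]] = {}
    for strand, obs in (("sense", obs_sense), ("antisense", obs_antisense)):
        calls = []
        for site in catalog:
            if obs is None:
                calls.append(MethylationCall(site, strand, NO_DATA, "unassigned", "none"))
                continue
            if len(obs.seq) != n:
                raise ValueError("observation length differs from locus length")
            c_sense_pos = site.sense_c_pos if strand == "sense" else site.antisense_c_pos
            obs_base = obs.seq[_frame_pos(c_sense_pos, strand, n)]
            other = (
                None
                if site.present_in == "both"
                else _other_converted_base(site, strand, ref)
            )
            calls.append(call_cg_site(obs_base, site, strand, other))
        out[strand] = calls
    return out


def detect_hemimethylation(
    calls_sense: Sequence[MethylationCall], calls_antisense: Sequence[MethylationCall]
) -> list[str]:
    """Per-site strand-symmetry flags.

    "hemi_antisense": methylation (full or mixed) on the antisense strand
    over an unmethylated sense strand; "hemi_sense" the mirror image;
    "symmetric": equal determinate levels on both strands; everything else
    "indeterminate".
    """
    if len(calls_sense) != len(calls_antisense):
        raise ValueError("strand call lists index different catalogs")
    flags = []
    for cs, ca in zip(calls_sense, calls_antisense):
        if cs.site != ca.site:
            raise ValueError("strand call lists index different catalogs")
        s, a = cs.level, ca.level
        if s == UNMETHYLATED and a in (METHYLATED, MIXED):
            flags.append("hemi_antisense")
        elif a == UNMETHYLATED and s in (METHYLATED, MIXED):
            flags.append("hemi_sense")
        elif s == a and s in (METHYLATED, UNMETHYLATED):
            flags.append("symmetric")
        else:
            flags.append("indeterminate")
    return flags


def summarize_locus(
    calls: Iterable[MethylationCall], catalog: Sequence[CGSite]
) -> dict[tuple[str, str], dict[str, float]]:
    """Per (region, strand) site tallies and methylated fractions.

    Mixed calls are counted separately, never as methylated; the fraction is
    ``n_methylated / n_sites`` over all cataloged sites of the stratum.
    """
    strata: dict[tuple[str, str], dict[str, float]] = {}
    for call in calls:
        key = (call.site.region, call.strand)
        st = strata.setdefault(
            key,
            {"n_sites": 0, "n_methylated": 0, "n_unmethylated": 0, "n_mixed": 0, "n_no_data": 0},
        )
        st["n_sites"] += 1
        if call.level == METHYLATED:
            st["n_methylated"] += 1
        elif call.level == UNMETHYLATED:
            st["n_unmethylated"] += 1
        elif call.level == MIXED:
            st["n_mixed"] += 1
        else:
            st["n_no_data"] += 1
    for st in strata.values():
        st["fraction_methylated"] = (
            st["n_methylated"] / st["n_sites"] if st["n_sites"] else 0.0
        )
    return strata


@dataclass
class ConcordanceVerdict:
    """Does methylation of the silenced homeolog accompany its silencing?"""

    silenced_homeolog_methylated: str  # yes | no | not_applicable
    strands: tuple[str, ...]  # subset of ("A", "S"); A = antisense, S = sense
    formatted: str  # Table-style token: Yes-A/S, Yes-A, Yes-S, No, NA


def integrate_silencing(
    calls_by_strand: dict[str, list[MethylationCall]],
    record,
    min_methylated_sites: int = 1,
) -> ConcordanceVerdict:
    """Concordance between an expression-silencing record and methylation.

    ``record`` is a silencing-status row (:class:`bsphase.io.SilencingRecord`
    or anything with ``silenced_homeolog``); subscript "d" names the
    *T. dubius*-like homeolog (parent A), "p" the *T. pratensis*-like one
    (parent B). The verdict is "yes" when the silenced homeolog carries at
    least ``min_methylated_sites`` methylated CG sites (uniform or
    genotype-determined), with the strands involved reported in the
    antisense/sense (A/S) notation.
    """
    silenced = getattr(record, "silenced_homeolog", None) if record is not None else None
    if silenced in (None, "", "none", "na"):
        return ConcordanceVerdict("not_applicable", (), "NA")
    if silenced == "genomic_copy_lost":
        return ConcordanceVerdict("not_applicable", (), "NA")
    if silenced not in ("d", "p"):
        raise ValueError(f"unknown silenced-homeolog token {silenced!r}")
    parent = "A" if silenced == "d" else "B"
    strands = []
    for strand, letter in (("antisense", "A"), ("sense", "S")):
        n_meth = sum(
            1
            for call in calls_by_strand.get(strand, [])
            if call.level == METHYLATED and call.homeolog in (parent, "both")
        )
        if n_meth >= min_methylated_sites:
            strands.append(letter)
    if strands:
        return ConcordanceVerdict("yes", tuple(strands), "Yes-" + "/".join(strands))
    return ConcordanceVerdict("no", (), "No")
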
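"""Clone-based homeolog assignment and methylation quantification.

When direct Sanger sequencing shows both homeologs methylated at shared CG
sites (a composite Y peak), cloning the bisulfite PCR product and sequencing
individual clones phases the mixture: each clone is one template molecule,
assigned to a parental homeolog through the diagnostic SNPs it spans, and
its CG sites are read directly (C = methylated, T = unmethylated). The
per-homeolog ratio of methylated clones quantifies how methylation is
apportioned between the duplicated copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import beta

from .methylcall import CGSite, _frame_pos
from .sequtil import BASES, clean_seq
from .snp_diagnostics import DIAGNOSTIC, DiagnosticSNP, LocusReference, post_conversion_observables

__all__ = [
    "CloneCall",
    "assign_clone",
    "clone_methylation",
    "homeolog_methylation_ratio",
    "clopper_pearson",
    "RatioReport",
]


@dataclass
class CloneCall:
    clone_id: str
    homeolog: str = "ambiguous"  # A | B | ambiguous | chimeric
    snp_matches: dict[int, str] = field(default_factory=dict)  # pos -> supported parent or "?"
    methyl_vector: dict[int, str] = field(default_factory=dict)  # sense_c_pos -> state


def assign_clone(
    clone_seq: str,
    snps: Sequence[DiagnosticSNP],
    ref: LocusReference,
    strand: str,
    min_matches: int = 1,
    clone_id: str = "",
) -> CloneCall:
    """Assign a clone to a parental homeolog via surviving diagnostic SNPs.

    ``clone_seq`` must be an unambiguous base string aligned to locus
    coordinates, in the frame of its strand product. Only SNPs classified
    diagnostic on ``strand`` are informative; the observed base at each is
    matched against the parental alleles' post-conversion observable sets.
    A clone is A or B when at least ``min_matches`` SNPs support that parent
    and none supports the other; one supporter of each parent marks a PCR
    chimera; anything else is ambiguous.
    """
    seq = clean_seq(clone_seq)
    if set(seq) - BASES:
        raise ValueError("clone sequences must be unambiguous")
    if len(seq) != len(ref):
        raise ValueError(f"clone length {len(seq)} != locus length {len(ref)}")
    support = {"A": 0, "B": 0}
    matches: dict[int, str] = {}
    for snp in snps:
        if snp.status(strand) != DIAGNOSTIC:
            continue
        observed = seq[_frame_pos(snp.pos, strand, len(ref))]
        obs_a = post_conversion_observables(snp.allele_A, snp.pos, strand, ref.seq_parent_A)
        obs_b = post_conversion_observables(snp.allele_B, snp.pos, strand, ref.seq_parent_B)
        if observed in obs_a and observed not in obs_b:
            support["A"] += 1
            matches[snp.pos] = "A"
        elif observed in obs_b and observed not in obs_a:
            support["B"] += 1
            matches[snp.pos] = "B"
        else:
            matches[snp.pos] = "?"
    if support["A"] >= 1 and support["B"] >= 1:
        homeolog = "chimeric"
    elif support["A"] >= min_matches and support["B"] == 0:
        homeolog = "A"
    elif support["B"] >= min_matches and support["A"] == 0:
        homeolog = "B"
    else:
        homeolog = "ambiguous"
    return CloneCall(clone_id=clone_id, homeolog=homeolog, snp_matches=matches)


def clone_methylation(
    clone_seq: str,
    catalog: Sequence[CGSite],
    strand: str,
    homeolog: str | None = None,
) -> dict[int, str]:
    """Read per-CG-site methylation states off one clone.

    C at the site's cytosine means methylated, T unmethylated, anything else
    no_data. Sites absent from the assigned parent (SNP-destroyed) are
    no_data for that clone regardless of the base observed.
    """
    seq = clean_seq(clone_seq)
    vector: dict[int, str] = {}
    for site in catalog:
        if homeolog in ("A", "B") and site.present_in not in (homeolog, "both"):
            vector[site.sense_c_pos] = "no_data"
            continue
        c_pos = site.sense_c_pos if strand == "sense" else site.antisense_c_pos
        base = seq[_frame_pos(c_pos, strand, len(seq))]
        if base == "C":
            vector[site.sense_c_pos] = "methylated"
        elif base == "T":
            vector[site.sense_c_pos] = "unmethylated"
        else:
            vector[site.sense_c_pos] = "no_data"
    return vector


def call_clone(
    clone_seq: str,
    snps: Sequence[DiagnosticSNP],
    catalog: Sequence[CGSite],
    ref: LocusReference,
    strand: str,
    min_matches: int = 1,
    clone_id: str = "",
) -> CloneCall:
    """Full per-clone call: homeolog assignment plus methylation vector."""
    call = assign_clone(clone_seq, snps, ref, strand, min_matches, clone_id)
    call.methyl_vector = clone_methylation(
        clone_seq, catalog, strand, call.homeolog if call.homeolog in ("A", "B") else None
    )
    return call


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for k/n."""
    if n == 0:
        return (0.0, 1.0)
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


@dataclass
class RatioReport:
    n_meth_A: int
    n_meth_B: int
    n_assigned_A: int
    n_assigned_B: int
    n_ambiguous: int
    n_chimeric: int
    ratio: float | None  # n_meth_A / n_meth_B; None when undefined
    ratio_undefined: bool
    ci95: tuple[float, float]  # Clopper–Pearson on n_meth_A / (n_meth_A + n_meth_B)


def _clone_is_methylated(call: CloneCall, site_rule: str) -> bool:
    states = [s for s in call.methyl_vector.values() if s != "no_data"]
    if site_rule == "any_site":
        return any(s == "methylated" for s in states)
    if site_rule == "all_sites":
        return bool(states) and all(s == "methylated" for s in states)
    raise ValueError(f"unknown site rule {site_rule!r}")


def homeolog_methylation_ratio(
    calls: Sequence[CloneCall], site_rule: str = "any_site"
) -> RatioReport:
    """Per-homeolog methylated-clone counts, ratio and exact 95% CI.

    Ambiguous and chimeric clones are excluded from the counts but reported.
    The ratio ``n_meth_A / n_meth_B`` is flagged undefined (not raised) when
    no methylated B clone exists.
    """
    if not calls:
        raise ValueError("no clone calls supplied")
    counts = {"A": 0, "B": 0}
    assigned = {"A": 0, "B": 0}
    n_ambiguous = sum(1 for c in calls if c.homeolog == "ambiguous")
    n_chimeric = sum(1 for c in calls if c.homeolog == "chimeric")
    for call in calls:
        if call.homeolog not in ("A", "B"):
            continue
        assigned[call.homeolog] += 1
        if _clone_is_methylated(call, site_rule):
            counts[call.homeolog] += 1
    ka, kb = counts["A"], counts["B"]
    undefined = kb == 0
    ratio = None if undefined else ka / kb
    return RatioReport(
        n_meth_A=ka,
        n_meth_B=kb,
        n_assigned_A=assigned["A"],
        n_assigned_B=assigned["B"],
        n_ambiguous=n_ambiguous,
        n_chimeric=n_chimeric,
        ratio=ratio,
        ratio_undefined=undefined,
        ci95=clopper_pearson(ka, ka + kb),
    )
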
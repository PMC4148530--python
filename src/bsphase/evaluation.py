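"""Validation studies: exhaustive oracles and simulation-based calibration.

These routines quantify how well the rule-based components recover known
ground truth, using only the package's own simulator as the data source:

* an exhaustive enumeration check of SNP-survival classification against a
  brute-force simulation of every allele pair, flanking context, strand and
  legal methylation state;
* algebraic sanity sweeps of the conversion operator on random sequences;
* end-to-end recovery of per-site, per-homeolog methylation truth across a
  mix of locus scenarios, at perfect and imperfect conversion efficiency;
* calibration of the clone-based methylation ratio and its exact binomial
  confidence interval;
* the amplicon amenability screen on adversarially constructed loci.

Every function takes an integer seed and returns a plain dict of numbers.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .bisulfite_sim import MethylationProfile, convert_duplex, convert_sequence
from .clone_quant import call_clone, homeolog_methylation_ratio
from .methylcall import (
    METHYLATED,
    MIXED,
    NO_DATA,
    UNMETHYLATED,
    call_locus,
    conversion_qc,
    detect_hemimethylation,
)
from .sequtil import CytosineContext, context_map, reverse_complement
from .snp_diagnostics import (
    CONFOUNDED,
    DIAGNOSTIC,
    LOST,
    LocusReference,
    classify_snp,
    find_snps,
    locus_amenability,
)
from .synthetic_data import LocusScenario, simulate_individual, simulate_parents

__all__ = [
    "snp_oracle_agreement",
    "conversion_algebra_check",
    "endtoend_recovery",
    "clone_ratio_calibration",
    "amenability_screen_check",
]


# ---------------------------------------------------------------------------
# 1. exhaustive SNP-survival oracle


def _enumerated_observables(hap: str, pos: int, strand: str) -> frozenset[str]:
    """Observable bases at ``pos`` by brute force over legal methylation states.

    Legal states are all subsets of the CG-context cytosines of the strand
    (no CHH/CHG methylation); an EDGE cytosine's context is unknowable at
    the amplicon boundary, so either state is legal for it. Each state is
    driven through convert_sequence at efficiency 1 and the converted base
    at the focal position collected.
    """
    view = hap if strand == "sense" else reverse_complement(hap)
    fpos = pos if strand == "sense" else len(hap) - 1 - pos
    cg_cs = [
        i
        for i, c in enumerate(context_map(view))
        if c in (CytosineContext.CG, CytosineContext.EDGE)
    ]
    seen = set()
    for k in range(len(cg_cs) + 1):
        for subset in combinations(cg_cs, k):
            converted = convert_sequence(view, frozenset(subset), 1.0)
            seen.add(converted[fpos])
    return frozenset(seen)


def snp_oracle_agreement(flank_bases: str = "ACGT") -> dict[str, float]:
    """Compare rule-based SNP classification against brute-force enumeration.

    Every ordered allele pair (12) is embedded in every combination of two
    upstream and two downstream flanking bases (shared between the parents,
    so the alleles' contexts arise naturally), classified on both strands,
    and checked against statuses derived from enumerated observable sets.
    """
    n_cases = 0
    n_agree = 0
    pad = "TAT"
    for a, b in product("ACGT", repeat=2):
        if a == b:
            continue
        for u2, u1, d1, d2 in product(flank_bases, repeat=4):
            left, right = pad + u2 + u1, d1 + d2 + pad
            hap_a = left + a + right
            hap_b = left + b + right
            pos = len(left)
            ref = LocusReference("oracle", hap_a, hap_b)
            snp = classify_snp(find_snps(ref)[0], ref)
            for strand in ("sense", "antisense"):
                obs_a = _enumerated_observables(hap_a, pos, strand)
                obs_b = _enumerated_observables(hap_b, pos, strand)
                if not obs_a & obs_b:
                    expected = DIAGNOSTIC
                elif len(obs_a) == 1 and len(obs_b) == 1:
                    expected = LOST
                else:
                    expected = CONFOUNDED
                n_cases += 1
                n_agree += snp.status(strand) == expected
    return {
        "n_cases": n_cases,
        "n_agree": n_agree,
        "agreement_pct": 100.0 * n_agree / n_cases,
    }


# ---------------------------------------------------------------------------
# 2. conversion algebra


def conversion_algebra_check(
    n_seqs: int = 1000, max_len: int = 500, seed: int = 0
) -> dict[str, int]:
    """Random-sequence sweep of the conversion operator's algebraic laws.

    Checks, per sequence: complete unmethylated conversion leaves no C;
    A/G/T positions are never altered; and the two converted strand
    products of a duplex fail reverse-complementarity whenever the sequence
    contains at least one C and one G.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    residual_c = altered_agt = complementary_duplex = 0
    n_duplex_eligible = 0
    for _ in range(n_seqs):
        n = int(rng.integers(1, max_len + 1))
        seq = "".join(rng.choice(bases, size=n))
        conv = convert_sequence(seq, frozenset(), 1.0)
        if "C" in conv:
            residual_c += 1
        if any(c != o for c, o in zip(conv, seq) if o != "C"):
            altered_agt += 1
        if "C" in seq and "G" in seq:
            n_duplex_eligible += 1
            s_prod, a_prod = convert_duplex(seq, MethylationProfile("x"), 1.0)
            if reverse_complement(a_prod) == s_prod:
                complementary_duplex += 1
    return {
        "n_seqs": n_seqs,
        "n_duplex_eligible": n_duplex_eligible,
        "residual_c_violations": residual_c,
        "altered_agt_violations": altered_agt,
        "complementary_duplex_violations": complementary_duplex,
    }


# ---------------------------------------------------------------------------
# 3/4. end-to-end recovery on simulated loci

_PATTERN_MIX = [
    ("cg_both", "cg_both"),  # both homeologs methylated
    ("cg_both", "none"),  # A only
    ("none", "cg_both"),  # B only
    ("none", "none"),  # neither
    ("cg_antisense", "none"),  # antisense hemimethylation of A
]


def _truth_level(site, strand: str, truth) -> str:
    """Pool-level truth at a site/strand, aggregated over present homeologs."""
    states = []
    for parent, profile in (("A", truth.profile_A), ("B", truth.profile_B)):
        if site.present_in not in (parent, "both"):
            continue
        pos = site.sense_c_pos if strand == "sense" else site.antisense_c_pos
        states.append(profile.prob(strand, pos))
    if all(p == 1.0 for p in states):
        return METHYLATED
    if all(p == 0.0 for p in states):
        return UNMETHYLATED
    return MIXED


def _expected_flag(s_level: str, a_level: str) -> str:
    if s_level == UNMETHYLATED and a_level in (METHYLATED, MIXED):
        return "hemi_antisense"
    if a_level == UNMETHYLATED and s_level in (METHYLATED, MIXED):
        return "hemi_sense"
    if s_level == a_level and s_level in (METHYLATED, UNMETHYLATED):
        return "symmetric"
    return "indeterminate"


def endtoend_recovery(
    n_loci: int = 200,
    efficiency: float = 1.0,
    n_clones: int = 12,
    seed: int = 0,
    length: int = 600,
    divergence: float = 0.02,
) -> dict[str, float]:
    """Recovery of simulated truth by the full calling pipeline.

    Simulates ``n_loci`` loci cycling through a mix of methylation
    scenarios (both-methylated, one homeolog only, neither, antisense
    hemimethylation), calls consensus observations, and scores:

    * consensus calls vs truth over determinate + genotype-determined
      site/strand instances;
    * hemimethylation flags vs profile-derived expectation;
    * conversion QC on clones vs loci that truly had a conversion failure;
    * clone homeolog assignment and per-site clone methylation accuracy.
    """
    rng = np.random.default_rng(seed)
    det_total = det_match = 0
    flag_total = flag_match = 0
    loci_with_failure = loci_flagged = 0
    clone_sites_total = clone_sites_match = 0
    clones_assignable = clones_assigned_right = 0
    for i in range(n_loci):
        pat_a, pat_b = _PATTERN_MIX[i % len(_PATTERN_MIX)]
        scenario = LocusScenario(
            locus_id=f"L{i:03d}",
            length=length,
            promoter_len=length // 2,
            divergence=divergence,
            cg_count_target=int(rng.integers(10, 23)),
            pattern_A=pat_a,
            pattern_B=pat_b,
            efficiency=efficiency,
            n_clones=n_clones,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ref, truth = simulate_parents(scenario)
        bundle, truth = simulate_individual(scenario, truth)
        calls = call_locus(
            bundle.converted_consensus["sense_derived"],
            bundle.converted_consensus["antisense_derived"],
            ref,
            truth.catalog,
        )
        for strand in ("sense", "antisense"):
            for call in calls[strand]:
                t_level = _truth_level(call.site, strand, truth)
                if call.homeolog == "both" and call.level in (METHYLATED, UNMETHYLATED):
                    det_total += 1
                    det_match += call.level == t_level
                elif call.evidence == "genotype_determined":
                    det_total += 1
                    det_match += call.level == t_level
        flags = detect_hemimethylation(calls["sense"], calls["antisense"])
        for site, flag in zip(truth.catalog, flags):
            expected = _expected_flag(
                _truth_level(site, "sense", truth), _truth_level(site, "antisense", truth)
            )
            flag_total += 1
            flag_match += flag == expected
        fail_truth, fail_called = _clone_qc(bundle, truth, ref)
        loci_with_failure += fail_truth
        loci_flagged += fail_called if fail_truth else 0
        a, b, c, d = _clone_accuracy(bundle, truth, ref)
        clones_assignable += a
        clones_assigned_right += b
        clone_sites_total += c
        clone_sites_match += d
    return {
        "n_loci": n_loci,
        "consensus_instances": det_total,
        "consensus_recovery_pct": 100.0 * det_match / det_total,
        "hemi_flag_accuracy_pct": 100.0 * flag_match / flag_total,
        "loci_with_conversion_failure": loci_with_failure,
        "qc_detection_pct": (
            100.0 * loci_flagged / loci_with_failure if loci_with_failure else 100.0
        ),
        "clone_assignment_pct": (
            100.0 * clones_assigned_right / clones_assignable if clones_assignable else 100.0
        ),
        "clone_site_accuracy_pct": (
            100.0 * clone_sites_match / clone_sites_total if clone_sites_total else 100.0
        ),
    }


def _clone_qc(bundle, truth, ref) -> tuple[bool, bool]:
    """(locus truly had >=1 failed conversion event, QC flagged >=1 clone)."""
    had_failure = False
    flagged = False
    views = {
        ("A", "sense"): ref.seq_parent_A,
        ("B", "sense"): ref.seq_parent_B,
        ("A", "antisense"): reverse_complement(ref.seq_parent_A),
        ("B", "antisense"): reverse_complement(ref.seq_parent_B),
    }
    cmaps = {k: context_map(v) for k, v in views.items()}
    n = len(ref)
    for obs, (hom, product_), meth in zip(
        bundle.clones, truth.clone_origins, truth.clone_methylation
    ):
        strand = "sense" if product_ == "sense_derived" else "antisense"
        cmap = cmaps[(hom, strand)]
        meth_frame = {p if strand == "sense" else n - 1 - p for p in meth}
        for i, ctx in enumerate(cmap):
            if (
                ctx in ("CHG", "CHH")
                and i not in meth_frame
                and obs.seq[i] == "C"
            ):
                had_failure = True
                break
        qc = conversion_qc(obs, ref, parents=(hom,))
        if qc.verdict == "incomplete":
            flagged = True
    return had_failure, flagged


def _clone_accuracy(bundle, truth, ref) -> tuple[int, int, int, int]:
    """Clone homeolog-assignment and per-site methylation accuracy counts."""
    assignable = assigned_right = sites_total = sites_match = 0
    for obs, (hom, product_), meth in zip(
        bundle.clones, truth.clone_origins, truth.clone_methylation
    ):
        strand = "sense" if product_ == "sense_derived" else "antisense"
        cc = call_clone(obs.seq, truth.snps, truth.catalog, ref, strand)
        usable = [
            s for s in truth.snps if s.status(strand) == DIAGNOSTIC
        ]
        if usable:
            assignable += 1
            assigned_right += cc.homeolog == hom
        if cc.homeolog != hom:
            continue
        for site in truth.catalog:
            if site.present_in not in (hom, "both"):
                continue
            pos = site.sense_c_pos if strand == "sense" else site.antisense_c_pos
            t_state = "methylated" if pos in meth else "unmethylated"
            called = cc.methyl_vector[site.sense_c_pos]
            if called == NO_DATA:
                continue
            sites_total += 1
            sites_match += called == t_state
    return assignable, assigned_right, sites_total, sites_match


# ---------------------------------------------------------------------------
# 5. clone-ratio calibration


def clone_ratio_calibration(
    n_replicates: int = 1000,
    n_clones: int = 12,
    p_meth_A: float = 2 / 3,
    p_meth_B: float = 1 / 3,
    seed: int = 0,
    length: int = 300,
) -> dict[str, float]:
    """Calibration of the per-homeolog methylated-clone ratio.

    One fixed locus; per replicate, ``n_clones`` cloned molecules are drawn
    (homeolog fair-coin, whole-molecule methylation with the homeolog's
    probability), converted, assigned back via diagnostic SNPs, and scored.
    Reports the pooled ratio across replicates (which converges to
    ``p_meth_A / p_meth_B``) and the empirical coverage of the per-pool
    Clopper–Pearson interval for the methylated-clone proportion.
    """
    scenario = LocusScenario(
        locus_id="calib",
        length=length,
        promoter_len=length // 2,
        divergence=0.04,
        cg_count_target=8,
        seed=seed,
    )
    ref, truth = simulate_parents(scenario)
    usable = [s for s in truth.snps if s.status_sense == DIAGNOSTIC]
    if not usable:
        raise RuntimeError("calibration locus lost all sense-strand diagnostic SNPs")
    all_meth = {
        ("sense", s.sense_c_pos): 1.0 for s in truth.catalog
    }
    rng = np.random.default_rng(seed + 1)
    true_prop = p_meth_A / (p_meth_A + p_meth_B)
    pooled_a = pooled_b = 0
    covered = n_eval = 0
    per_pool_ratios = []
    for _ in range(n_replicates):
        calls = []
        for k in range(n_clones):
            hom = "A" if rng.random() < 0.5 else "B"
            p = p_meth_A if hom == "A" else p_meth_B
            methylated = rng.random() < p
            parent_seq = ref.parent_seq(hom)
            meth_sites = (
                frozenset(
                    s.sense_c_pos
                    for s in truth.catalog
                    if s.present_in in (hom, "both")
                )
                if methylated
                else frozenset()
            )
            seq = convert_sequence(parent_seq, meth_sites, 1.0)
            calls.append(call_clone(seq, truth.snps, truth.catalog, ref, "sense"))
        rep = homeolog_methylation_ratio(calls)
        pooled_a += rep.n_meth_A
        pooled_b += rep.n_meth_B
        if rep.ratio is not None:
            per_pool_ratios.append(rep.ratio)
        n_meth = rep.n_meth_A + rep.n_meth_B
        if n_meth:
            n_eval += 1
            lo, hi = rep.ci95
            covered += lo <= true_prop <= hi
    return {
        "n_replicates": n_replicates,
        "pooled_ratio": pooled_a / pooled_b,
        "mean_per_pool_ratio": float(np.mean(per_pool_ratios)),
        "ci95_coverage_pct": 100.0 * covered / n_eval,
        "pooled_ratio_mc_ci": _ratio_mc_ci(pooled_a, pooled_b, n_replicates),
    }


def _ratio_mc_ci(ka: int, kb: int, n_reps: int) -> tuple[float, float]:
    """Rough Monte-Carlo interval for the pooled ratio (delta method)."""
    ra, rb = ka / n_reps, kb / n_reps
    var = (ka + kb) / n_reps**2  # Poisson-style scale bound on each count mean
    se = (var**0.5) * (1 / rb + ra / rb**2) / 2
    ratio = ka / kb
    return (ratio - 3 * se, ratio + 3 * se)


# ---------------------------------------------------------------------------
# 6. amenability screen


def amenability_screen_check() -> dict[str, int]:
    """Adversarially constructed loci through the amenability screen.

    Loci whose only SNPs are C/T with the C in a convertible (CHH) context
    must have no usable sense-strand SNP; mixed constructions must agree
    with the enumeration oracle strand by strand.
    """
    n_cases = n_correct = 0
    # C/T-in-CHH SNPs only: sense collapses, antisense (G/A) survives
    ref = LocusReference("s8like", "TTTCATTTTCATTT", "TTTTATTTTTATTT")
    snps = [classify_snp(s, ref) for s in find_snps(ref)]
    rep = locus_amenability(snps, (0, len(ref)))
    n_cases += 1
    n_correct += not rep.usable_snps_sense and bool(rep.usable_snps_antisense)
    # no SNPs at all
    ref0 = LocusReference("mono", "TTACGTT", "TTACGTT")
    rep0 = locus_amenability([classify_snp(s, ref0) for s in find_snps(ref0)], (0, 7))
    n_cases += 1
    n_correct += not rep0.amenable
    # mixed constructions: every SNP's per-strand status against enumeration
    mixes = [
        ("TATCACGTATA", "TATTACGTATA"),  # C/T near a CG
        ("TATACGTTATA", "TATATGTTATA"),  # CG destroyed in B
        ("TATAATTTATA", "TATATTTTATA"),  # A/T survivor
        ("TATACATTATA", "TATGCATTATA"),  # A/G survivor
    ]
    for sa, sb in mixes:
        refm = LocusReference("mix", sa, sb)
        for snp in find_snps(refm):
            classified = classify_snp(snp, refm)
            for strand in ("sense", "antisense"):
                obs_a = _enumerated_observables(sa, snp.pos, strand)
                obs_b = _enumerated_observables(sb, snp.pos, strand)
                if not obs_a & obs_b:
                    expected = DIAGNOSTIC
                elif len(obs_a) == 1 and len(obs_b) == 1:
                    expected = LOST
                else:
                    expected = CONFOUNDED
                n_cases += 1
                n_correct += classified.status(strand) == expected
    return {"n_cases": n_cases, "n_correct": n_correct}
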
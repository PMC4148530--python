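"""Synthetic study generator: loci, methylation truth, and observables.

Generates complete in-silico inputs with known ground truth for every
pipeline stage: two diverged parental haplotypes per locus (a promoter and
a genic region), a tetraploid individual carrying both, per-homeolog
per-strand CG methylation (including hemimethylation and partial
methylation), bisulfite conversion with tunable efficiency, Sanger-like
mixed-template consensus reads with IUPAC ambiguity codes, and finite clone
sampling.

Named methylation patterns per homeolog:

* ``"none"``           — no methylation
* ``"cg_both"``        — every CG site methylated on both strands
* ``"cg_sense"``       — every CG site methylated on the sense strand only
* ``"cg_antisense"``   — antisense-only (hemimethylation)

A float in (0, 1) methylates each CG cytosine with that probability on both
strands (within-homeolog partial methylation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bisulfite_sim import (
    ConvertedObservation,
    MethylationProfile,
    consensus_from_weights,
    convert_sequence,
    sample_methylation,
    sanger_consensus,
)
from .methylcall import CGSite, build_cg_catalog
from .sequtil import classify_context, reverse_complement
from .snp_diagnostics import DiagnosticSNP, LocusReference, classify_snp, find_snps

__all__ = [
    "LocusScenario",
    "GroundTruth",
    "ObservableBundle",
    "simulate_parents",
    "simulate_individual",
]

Pattern = str | float


@dataclass
class LocusScenario:
    """Design of one simulated locus / individual.

    Defaults mirror the study design the pipeline targets: an amplicon-scale
    locus split into promoter and genic regions, parental divergence at the
    few-percent level typical of congeneric diploids, roughly a dozen CG
    sites, near-complete conversion chemistry, and 12 sequenced clones.
    """

    locus_id: str = "locus"
    length: int = 600
    promoter_len: int = 300
    divergence: float = 0.02
    cg_count_target: int = 11
    pattern_A: Pattern = "none"
    pattern_B: Pattern = "none"
    efficiency: float = 1.0
    non_cg_methyl_prob: float = 0.0
    n_clones: int = 12
    minor_threshold: float = 0.2
    silencing_override: str | None = None  # force the silencing row (S3-like decoupling)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.2:
            raise ValueError("divergence must be in [0, 0.2]")
        if not 0 < self.promoter_len < self.length:
            raise ValueError("promoter_len must lie inside the locus")
        for p in (self.efficiency, self.non_cg_methyl_prob, self.minor_threshold):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        if self.cg_count_target > self.length // 4:
            raise ValueError(
                f"cg_count_target {self.cg_count_target} unsatisfiable for length {self.length}"
            )

    @property
    def regions(self) -> list[tuple[int, int, str]]:
        return [(0, self.promoter_len, "promoter"), (self.promoter_len, self.length, "genic")]


@dataclass
class GroundTruth:
    """Everything needed to replay and verify the emitted observables."""

    ref: LocusReference
    snps: list[DiagnosticSNP]
    catalog: list[CGSite]
    profile_A: MethylationProfile
    profile_B: MethylationProfile
    clone_origins: list[tuple[str, str]] = field(default_factory=list)  # (homeolog, strand_product)
    clone_methylation: list[frozenset[int]] = field(default_factory=list)  # sense coords
    clone_seeds: list[int] = field(default_factory=list)


@dataclass
class ObservableBundle:
    """One simulated individual's data files, in memory."""

    parent_fasta: dict[str, str]  # record id -> sequence
    polyploid_genomic_consensus: str
    converted_consensus: dict[str, ConvertedObservation]  # strand_product -> obs
    clones: list[ConvertedObservation]
    silencing_row: dict[str, str]
    regions: list[tuple[int, int, str]]


_BASES = np.array(list("ACGT"))


def _break_cg(seq: list[str], rng: np.random.Generator) -> None:
    """Destroy accidental CG dinucleotides by re-drawing the G."""
    for i in range(len(seq) - 1):
        while seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = str(rng.choice(_BASES))


def simulate_parents(scenario: LocusScenario) -> tuple[LocusReference, GroundTruth]:
    """Draw two diverged parental haplotypes with a controlled CG catalog.

    Parent A gets exactly ``cg_count_target`` CG dinucleotides at reserved
    slots split across promoter and genic regions (uniform base composition
    elsewhere, accidental CGs broken). Parent B is derived by per-site
    substitution at rate ``divergence`` outside the reserved slots; when
    divergence > 0 and the locus is long enough, one fully surviving A/T SNP
    and one strand-asymmetric C/T-in-CHH SNP are guaranteed by targeted
    placement. Substitutions never create new CG dinucleotides, so the
    catalog size equals the target (some sites may be destroyed in B,
    yielding genotype-determined sites).
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.length
    seq_a = list(rng.choice(_BASES, size=n))
    _break_cg(seq_a, rng)

    # reserved CG slots, margin 3 from each end, spacing >= 3, split between regions
    margin = 3
    n_prom = round(scenario.cg_count_target * scenario.promoter_len / n)
    n_genic = scenario.cg_count_target - n_prom
    slots: list[int] = []
    for (lo, hi), k in (
        ((margin, scenario.promoter_len - margin), n_prom),
        ((scenario.promoter_len + margin, n - margin), n_genic),
    ):
        placed = 0
        attempts = 0
        while placed < k:
            attempts += 1
            if attempts > 10000:
                raise ValueError("could not place CG slots; scenario too dense")
            p = int(rng.integers(lo, hi - 1))
            if all(abs(p - q) >= 3 for q in slots):
                slots.append(p)
                placed += 1
    for p in sorted(slots):
        seq_a[p] = "C"
        seq_a[p + 1] = "G"
    _protect = set()
    for p in slots:
        _protect.update((p, p + 1))
    # break any accidental CG created at a slot boundary (reserved slots kept)
    for i in range(n - 1):
        if i in _protect and i + 1 in _protect:
            continue
        while seq_a[i] == "C" and seq_a[i + 1] == "G":
            seq_a[i + 1] = str(rng.choice(_BASES))

    seq_b = list(seq_a)
    if scenario.divergence > 0:
        # substitutions may destroy a reserved CG in B (the site stays in the
        # catalog as present_in A — the genotype-determined case) but must
        # never create a new CG, so the catalog size equals the target.
        for i in range(n):
            if not rng.random() < scenario.divergence:
                continue
            choices = [b for b in "ACGT" if b != seq_b[i]]
            rng.shuffle(choices)
            for b in choices:
                if _creates_cg(seq_b, i, b):
                    continue
                seq_b[i] = b
                break
        if n >= 300:
            _ensure_snp_classes(seq_a, seq_b, _protect, rng)

    ref = LocusReference(
        locus_id=scenario.locus_id,
        seq_parent_A="".join(seq_a),
        seq_parent_B="".join(seq_b),
        regions=scenario.regions,
    )
    catalog = build_cg_catalog(ref)
    snps = [classify_snp(s, ref) for s in find_snps(ref)]
    profile_a = _profile_from_pattern(ref.seq_parent_A, catalog, "A", scenario.pattern_A, scenario, rng)
    profile_b = _profile_from_pattern(ref.seq_parent_B, catalog, "B", scenario.pattern_B, scenario, rng)
    return ref, GroundTruth(ref, snps, catalog, profile_a, profile_b)


def _creates_cg(seq: list[str], i: int, b: str) -> bool:
    left = i > 0 and seq[i - 1] == "C" and b == "G"
    right = i + 1 < len(seq) and b == "C" and seq[i + 1] == "G"
    return left or right


def _ensure_snp_classes(seq_a, seq_b, protect, rng: np.random.Generator) -> None:
    """Guarantee one A/T (fully surviving) and one C/T-in-CHH SNP."""
    n = len(seq_a)

    def has(cls: str) -> bool:
        for i in range(n):
            if seq_a[i] == seq_b[i]:
                continue
            pair = {seq_a[i], seq_b[i]}
            if cls == "AT" and pair == {"A", "T"}:
                return True
            if cls == "CT_CHH" and pair == {"C", "T"}:
                c_hap = seq_a if seq_a[i] == "C" else seq_b
                if i + 2 < n and classify_context("".join(c_hap), i, "sense") == "CHH":
                    return True
        return False

    def free_positions():
        order = list(range(5, n - 5))
        rng.shuffle(order)
        return order

    if not has("AT"):
        for i in free_positions():
            if i in protect or seq_a[i] != seq_b[i]:
                continue
            if _creates_cg(seq_a, i, "A") or _creates_cg(seq_b, i, "T"):
                continue
            seq_a[i], seq_b[i] = "A", "T"
            break
    if not has("CT_CHH"):
        for i in free_positions():
            if i in protect or seq_a[i] != seq_b[i]:
                continue
            # need A-haplotype context CHH: next two bases not G, and no CG creation
            if seq_a[i + 1] == "G" or seq_a[i + 2] == "G":
                continue
            if {i + 1, i + 2} & protect:
                continue
            if _creates_cg(seq_a, i, "C") or _creates_cg(seq_b, i, "T"):
                continue
            seq_a[i], seq_b[i] = "C", "T"
            break


def _profile_from_pattern(
    parent_seq: str,
    catalog: Sequence[CGSite],
    parent: str,
    pattern: Pattern,
    scenario: LocusScenario,
    rng: np.random.Generator,
) -> MethylationProfile:
    """Concretize a named pattern into per-(strand, position) probabilities."""
    entries: dict[tuple[str, int], float] = {}
    own_sites = [s for s in catalog if s.present_in in (parent, "both")]
    if isinstance(pattern, float):
        strands_p = {"sense": pattern, "antisense": pattern}
    elif pattern == "none":
        strands_p = {}
    elif pattern == "cg_both":
        strands_p = {"sense": 1.0, "antisense": 1.0}
    elif pattern == "cg_sense":
        strands_p = {"sense": 1.0}
    elif pattern == "cg_antisense":
        strands_p = {"antisense": 1.0}
    else:
        raise ValueError(f"unknown methylation pattern {pattern!r}")
    for site in own_sites:
        for strand, p in strands_p.items():
            pos = site.sense_c_pos if strand == "sense" else site.antisense_c_pos
            entries[(strand, pos)] = p
    if scenario.non_cg_methyl_prob > 0:
        for strand in ("sense", "antisense"):
            view = parent_seq if strand == "sense" else reverse_complement(parent_seq)
            for i, b in enumerate(view):
                if b != "C":
                    continue
                ctx = classify_context(view, i, "sense")
                if ctx in ("CHG", "CHH"):
                    sense_pos = i if strand == "sense" else len(view) - 1 - i
                    key = (strand, sense_pos)
                    if key not in entries:
                        entries[key] = scenario.non_cg_methyl_prob
    return MethylationProfile(locus_id=f"{parent}", entries=entries)


def _expected_base_weights(
    seq: str, strand: str, profile: MethylationProfile, efficiency: float
) -> list[dict[str, float]]:
    """Per-position expected base distribution of one converted strand.

    The strand view is read 5'->3' in its own frame; at each C the weight of
    T is (1 - p_methyl) * efficiency, the rest stays C. Non-C bases are
    point masses. This is the bulk (many-molecule) limit a Sanger trace of
    the template pool reflects.
    """
    n = len(seq)
    view = seq if strand == "sense" else reverse_complement(seq)
    probs = profile.strand_positions(strand)
    out: list[dict[str, float]] = []
    for i, b in enumerate(view):
        if b != "C":
            out.append({b: 1.0})
            continue
        sense_pos = i if strand == "sense" else n - 1 - i
        p_meth = probs.get(sense_pos, 0.0)
        p_t = (1.0 - p_meth) * efficiency
        out.append({"T": p_t, "C": 1.0 - p_t} if p_t > 0 else {"C": 1.0})
    return out


def simulate_individual(
    scenario: LocusScenario, truth: GroundTruth
) -> tuple[ObservableBundle, GroundTruth]:
    """Emit one simulated tetraploid individual's observables.

    The polyploid genomic consensus is the Sanger merge of the two parental
    haplotypes; each converted consensus merges the expected converted base
    distributions of both homeologs at equal template weight (single-copy
    homeologous loci). Clones are individual molecules: homeolog drawn
    uniformly, binary methylation sampled from that homeolog's profile,
    stochastic conversion at the scenario efficiency. The silencing row
    follows the simulation convention that a homeolog whose promoter CG
    sites are all fully methylated is recorded silenced (override available
    to decouple the two, as real loci can be silenced without methylation).
    """
    ref = truth.ref
    n = len(ref)
    rng = np.random.default_rng(scenario.seed + 1)
    genomic_consensus = sanger_consensus(
        [(ref.seq_parent_A, 1.0), (ref.seq_parent_B, 1.0)], scenario.minor_threshold
    )
    converted: dict[str, ConvertedObservation] = {}
    for strand, product in (("sense", "sense_derived"), ("antisense", "antisense_derived")):
        dists_a = _expected_base_weights(ref.seq_parent_A, strand, truth.profile_A, scenario.efficiency)
        dists_b = _expected_base_weights(ref.seq_parent_B, strand, truth.profile_B, scenario.efficiency)
        merged = [
            {b: 0.5 * da.get(b, 0.0) + 0.5 * db.get(b, 0.0) for b in set(da) | set(db)}
            for da, db in zip(dists_a, dists_b)
        ]
        converted[product] = ConvertedObservation(
            seq=consensus_from_weights(merged, scenario.minor_threshold),
            strand_product=product,
            source="consensus",
            locus_id=ref.locus_id,
            homeolog_truth="mixture",
        )

    clones: list[ConvertedObservation] = []
    origins: list[tuple[str, str]] = []
    meth_states: list[frozenset[int]] = []
    clone_seeds: list[int] = []
    for strand, product in (("sense", "sense_derived"), ("antisense", "antisense_derived")):
        for k in range(scenario.n_clones):
            homeolog = "A" if rng.random() < 0.5 else "B"
            parent_seq = ref.parent_seq(homeolog)
            profile = truth.profile_A if homeolog == "A" else truth.profile_B
            clone_seed = int(rng.integers(0, 2**31 - 1))
            meth_sense_coords = sample_methylation(profile, strand, clone_seed)
            view = parent_seq if strand == "sense" else reverse_complement(parent_seq)
            meth_frame = frozenset(
                p if strand == "sense" else n - 1 - p for p in meth_sense_coords
            )
            seq = convert_sequence(view, meth_frame, scenario.efficiency, clone_seed + 1)
            clones.append(
                ConvertedObservation(
                    seq=seq,
                    strand_product=product,
                    source="clone",
                    locus_id=ref.locus_id,
                    homeolog_truth=homeolog,
                )
            )
            origins.append((homeolog, product))
            meth_states.append(meth_sense_coords)
            clone_seeds.append(clone_seed)

    silencing_row = _silencing_row(scenario, truth)
    bundle = ObservableBundle(
        parent_fasta={
            f"{ref.locus_id}_A": ref.seq_parent_A,
            f"{ref.locus_id}_B": ref.seq_parent_B,
        },
        polyploid_genomic_consensus=genomic_consensus,
        converted_consensus=converted,
        clones=clones,
        silencing_row=silencing_row,
        regions=ref.regions,
    )
    truth_full = replace(
        truth, clone_origins=origins, clone_methylation=meth_states, clone_seeds=clone_seeds
    )
    return bundle, truth_full


def _silencing_row(scenario: LocusScenario, truth: GroundTruth) -> dict[str, str]:
    """Table-style silencing row under the simulation's convention."""
    if scenario.silencing_override is not None:
        silenced = scenario.silencing_override
    else:
        silenced = "none"
        for parent, profile, tag in (("A", truth.profile_A, "d"), ("B", truth.profile_B, "p")):
            prom_sites = [
                s
                for s in truth.catalog
                if s.region == "promoter" and s.present_in in (parent, "both")
            ]
            if prom_sites and all(
                profile.prob("sense", s.sense_c_pos) == 1.0
                and profile.prob("antisense", s.antisense_c_pos) == 1.0
                for s in prom_sites
            ):
                silenced = tag
                break
    return {
        "Population": "synthetic",
        "Species": "T. miscellus",
        "Lineage": f"sim-{scenario.seed}",
        "Locus silenced": (
            "" if silenced in ("none", None) else f"{scenario.locus_id}_{silenced}"
        ),
        "Methylated?": "",
    }
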
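"""In-silico bisulfite conversion of duplex DNA.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is protected. After conversion the two
strands of a duplex are no longer complementary, so each strand becomes a
distinct amplifiable template ("sense_derived" and "antisense_derived"
strand products). Direct Sanger sequencing of a mixed template pool (the two
homeologs of an allopolyploid, or methylated and unmethylated molecules of
one homeolog) yields composite peaks, modeled here as IUPAC ambiguity codes.

Methylation state is carried per strand and per cytosine as a probability,
so hemimethylation and within-homeolog partial methylation are
representable. Clone draws use binary per-molecule states; consensus
emission uses expected template weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequtil import BASES, clean_seq, expand_code, merge_bases, reverse_complement

__all__ = [
    "MethylationProfile",
    "ConvertedObservation",
    "convert_sequence",
    "convert_duplex",
    "sanger_consensus",
    "consensus_from_weights",
    "sample_methylation",
]

STRANDS = ("sense", "antisense")


def _position_uniforms(n: int, seed: int) -> np.ndarray:
    """One U(0,1) draw per position from a counter-based stream.

    Philox is counter-based, so draw i is a pure function of (seed, i):
    outputs are reproducible under any reordering of position queries.
    """
    return np.random.Generator(np.random.Philox(key=seed)).random(n)


@dataclass
class MethylationProfile:
    """Per-strand, per-cytosine methylation probabilities for one locus.

    Keys of ``entries`` are ``(strand, sense_pos)`` where ``sense_pos`` is
    the sense-coordinate of the cytosine: for the sense strand that position
    holds C; for the antisense strand it holds G (the antisense C pairs with
    it). Absent positions default to probability 0 (unmethylated).
    """

    locus_id: str
    entries: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (strand, pos), p in self.entries.items():
            if strand not in STRANDS:
                raise ValueError(f"bad strand {strand!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} at {(strand, pos)} outside [0,1]")

    def validate_against(self, sense_seq: str) -> None:
        """Check every keyed position really is a C on its strand."""
        s = clean_seq(sense_seq)
        for strand, pos in self.entries:
            want = "C" if strand == "sense" else "G"
            if not 0 <= pos < len(s) or s[pos] != want:
                raise ValueError(
                    f"profile position {pos} on {strand} strand is not a cytosine "
                    f"(sense base {s[pos] if 0 <= pos < len(s) else 'out of range'})"
                )

    def prob(self, strand: str, sense_pos: int) -> float:
        return self.entries.get((strand, sense_pos), 0.0)

    def strand_positions(self, strand: str) -> dict[int, float]:
        """Sense-coordinate -> probability map for one strand."""
        return {pos: p for (st, pos), p in self.entries.items() if st == strand}


@dataclass
class ConvertedObservation:
    """A bisulfite-converted sequence tied to a locus and strand product."""

    seq: str
    strand_product: str  # sense_derived | antisense_derived
    source: str  # consensus | clone
    locus_id: str
    homeolog_truth: str = "unknown"  # A | B | mixture | unknown

    def __post_init__(self) -> None:
        self.seq = clean_seq(self.seq)
        if self.strand_product not in ("sense_derived", "antisense_derived"):
            raise ValueError(f"bad strand product {self.strand_product!r}")
        if self.source not in ("consensus", "clone"):
            raise ValueError(f"bad source {self.source!r}")
        if self.source == "clone" and set(self.seq) - BASES:
            raise ValueError("clone observations must be unambiguous base strings")


def convert_sequence(
    seq: str,
    methylated: set[int] | frozenset[int] = frozenset(),
    efficiency: float = 1.0,
    seed: int = 0,
) -> str:
    """Bisulfite-convert one strand.

    Each C not in ``methylated`` becomes T independently with probability
    ``efficiency``; methylated Cs always stay C; other bases are untouched.
    Deterministic when efficiency is 0 or 1.
    """
    s = clean_seq(seq)
    if set(s) - BASES:
        raise ValueError("convert_sequence requires an unambiguous base string")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency {efficiency} outside [0,1]")
    for pos in methylated:
        if not 0 <= pos < len(s) or s[pos] != "C":
            raise ValueError(f"methylated position {pos} is not a C")
    if efficiency == 1.0:
        u = None
    elif efficiency == 0.0:
        return s
    else:
        u = _position_uniforms(len(s), seed)
    out = list(s)
    for i, b in enumerate(out):
        if b == "C" and i not in methylated:
            if u is None or u[i] < efficiency:
                out[i] = "T"
    return "".join(out)


def sample_methylation(
    profile: MethylationProfile, strand: str, seed: int
) -> frozenset[int]:
    """Draw a binary methylation state for one strand of one molecule.

    Returns methylated positions in *sense* coordinates. Draws are
    counter-based on the sense position, so a given (seed, position) pair
    always resolves the same way.
    """
    probs = profile.strand_positions(strand)
    if not probs:
        return frozenset()
    n = max(probs) + 1
    u = _position_uniforms(n, seed)
    return frozenset(pos for pos, p in probs.items() if u[pos] < p)


def convert_duplex(
    sense_seq: str,
    profile: MethylationProfile,
    efficiency: float = 1.0,
    seed: int = 0,
) -> tuple[str, str]:
    """Convert both strands of a duplex under a methylation profile.

    Returns ``(sense_derived, antisense_derived)``; the antisense product is
    reported 5'->3' in its own frame (the reverse complement frame of the
    input). Methylation states are drawn per strand from the profile
    probabilities (deterministic for 0/1 probabilities).
    """
    s = clean_seq(sense_seq)
    profile.validate_against(s)
    n = len(s)
    meth_sense = sample_methylation(profile, "sense", seed)
    meth_anti_sense_coords = sample_methylation(profile, "antisense", seed + 1)
    anti = reverse_complement(s)
    meth_anti = frozenset(n - 1 - p for p in meth_anti_sense_coords)
    sense_derived = convert_sequence(s, meth_sense, efficiency, seed + 2)
    antisense_derived = convert_sequence(anti, meth_anti, efficiency, seed + 3)
    return sense_derived, antisense_derived


def consensus_from_weights(
    per_position_weights: list[dict[str, float]], minor_threshold: float = 0.2
) -> str:
    """Merge per-position base weight distributions into an IUPAC consensus.

    At each position, bases whose relative weight reaches ``minor_threshold``
    enter the emitted ambiguity code; if none do (degenerate thresholds), the
    single heaviest base is emitted.
    """
    out = []
    for dist in per_position_weights:
        total = sum(dist.values())
        if total <= 0:
            raise ValueError("position with no positive base weight")
        kept = {b for b, w in dist.items() if w / total >= minor_threshold and w > 0}
        if not kept:
            kept = {max(dist, key=dist.get)}
        out.append(merge_bases(kept))
    return "".join(out)


def sanger_consensus(
    products: list[tuple[str, float]], minor_threshold: float = 0.2
) -> str:
    """Composite Sanger read of a mixed template pool.

    ``products`` are (sequence, weight) pairs of equal length; at each
    position the emitted IUPAC code merges the bases whose summed relative
    weight reaches ``minor_threshold``. With a single product the input is
    returned unchanged.
    """
    if not products:
        raise ValueError("no products to merge")
    seqs = [clean_seq(seq) for seq, _ in products]
    weights = [w for _, w in products]
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("products must be equal length (pre-aligned)")
    if len(products) == 1:
        return seqs[0]
    dists: list[dict[str, float]] = []
    for i in range(n):
        d: dict[str, float] = {}
        for s, w in zip(seqs, weights):
            # an ambiguity code in an input product spreads its weight evenly
            bases = expand_code(s[i])
            for b in bases:
                d[b] = d.get(b, 0.0) + w / len(bases)
        dists.append(d)
    return consensus_from_weights(dists, minor_threshold)
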
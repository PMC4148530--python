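"""Strand-specific nested primer design on bisulfite-converted templates.

After conversion the two strands are no longer complementary, so each
strand product needs its own primer set; nested PCR (a second, internal
primer pair re-amplifying the first amplicon) restores specificity on the
reduced-complexity converted template. Primers are designed against the
fully converted, unmethylated template and must

* be 26-29 bp long,
* avoid every CG-site cytosine (those template positions are C-or-T
  depending on methylation, so a primer over them would bias amplification),
* avoid positions where the two parental converted templates differ
  (one primer set must amplify both homeologs), and
* anchor bisulfite specificity: the 3'-terminal bases must cover at least
  one position that was a convertible (non-CG) C in the genomic sequence
  and therefore reads T only in converted template.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from .bisulfite_sim import convert_sequence
from .methylcall import build_cg_catalog
from .sequtil import BASES, clean_seq, reverse_complement
from .snp_diagnostics import LocusReference

__all__ = [
    "PrimerSpec",
    "PrimerSet",
    "DesignParams",
    "DesignResult",
    "design_primer_set",
    "estimate_tm",
]

MIN_LEN, MAX_LEN = 26, 29


def estimate_tm(seq: str) -> float:
    """Rough melting temperature, °C.

    Wallace rule 2(A+T) + 4(G+C) for short oligos (<= 14 nt), otherwise the
    GC-fraction formula 64.9 + 41*(GC - 16.4)/N. Deterministic and monotone
    nondecreasing in GC count at fixed length, which is all downstream code
    relies on.
    """
    s = clean_seq(seq)
    if not s:
        raise ValueError("empty sequence")
    if set(s) - BASES:
        raise ValueError("Tm estimation requires an unambiguous base string")
    gc = s.count("G") + s.count("C")
    at = len(s) - gc
    if len(s) <= 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(s)


@dataclass(frozen=True)
class PrimerSpec:
    """One primer; ``start`` is the footprint start on the converted
    template of ``template_strand_product``, in that product's own frame."""

    seq: str
    template_strand_product: str
    start: int
    length: int
    role: str  # outer_F | outer_R | nested_F | nested_R
    tm_estimate: float

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class PrimerSet:
    outer_F: PrimerSpec
    outer_R: PrimerSpec
    nested_F: PrimerSpec
    nested_R: PrimerSpec
    outer_amplicon: int
    nested_amplicon: int
    anchor_hits: int  # converted-C count in the four 3'-terminal windows


@dataclass
class DesignParams:
    amplicon_target: int = 300
    amplicon_tol: int = 60
    nested_inset_min: int = 15
    anchor_window: int = 3  # 3'-terminal bases that must cover a converted C
    max_sets: int | None = 50  # ranked sets to return per strand (None = all)


@dataclass
class DesignResult:
    strand_product: str
    sets: list[PrimerSet] = field(default_factory=list)
    no_candidates: dict[str, int] | None = None  # structured report when empty


@dataclass(frozen=True)
class _Window:
    start: int
    length: int
    anchor_hits: int

    @property
    def end(self) -> int:
        return self.start + self.length


def _template_and_masks(ref: LocusReference, strand_product: str):
    """Converted design template plus forbidden/anchor position sets."""
    n = len(ref)
    strand = "sense" if strand_product == "sense_derived" else "antisense"

    def view(seq: str) -> str:
        return seq if strand == "sense" else reverse_complement(seq)

    genomic_a = view(ref.seq_parent_A)
    genomic_b = view(ref.seq_parent_B)
    tmpl_a = convert_sequence(genomic_a)
    tmpl_b = convert_sequence(genomic_b)
    catalog = build_cg_catalog(ref)
    forbidden = set()
    for site in catalog:
        sense_pos = site.sense_c_pos if strand == "sense" else site.antisense_c_pos
        forbidden.add(sense_pos if strand == "sense" else n - 1 - sense_pos)
    forbidden |= {i for i in range(n) if tmpl_a[i] != tmpl_b[i]}
    cg_cols = {
        (site.sense_c_pos if strand == "sense" else n - 1 - site.antisense_c_pos)
        for site in catalog
    }
    anchors = {
        i
        for i in range(n)
        if genomic_a[i] == "C" and tmpl_a[i] == "T" and i not in cg_cols
    }
    return tmpl_a, forbidden, anchors


def _valid_windows(
    n: int,
    lo: int,
    hi: int,
    forbidden: set[int],
    anchors: set[int],
    three_prime: str,
    anchor_window: int,
) -> list[_Window]:
    """All clean primer footprints with starts in [lo, hi)."""
    out = []
    for start in range(max(lo, 0), max(hi, 0)):
        for length in range(MIN_LEN, MAX_LEN + 1):
            end = start + length
            if end > n:
                continue
            if any(p in forbidden for p in range(start, end)):
                continue
            if three_prime == "right":
                win = range(end - anchor_window, end)
            else:
                win = range(start, start + anchor_window)
            hits = sum(1 for p in win if p in anchors)
            if hits == 0:
                continue
            out.append(_Window(start, length, hits))
    return out


def design_primer_set(
    ref: LocusReference,
    target: tuple[int, int],
    params: DesignParams | None = None,
    strand_products: tuple[str, ...] = ("sense_derived", "antisense_derived"),
) -> dict[str, DesignResult]:
    """Design ranked nested primer sets for each strand product.

    ``target`` is a half-open interval in sense coordinates that every
    amplicon must cover. Each returned set is an outer pair plus a nested
    pair lying at least ``nested_inset_min`` inside the outer amplicon, both
    amplicons within ``amplicon_target ± amplicon_tol``. Sets are ranked by
    closeness of the outer amplicon to the target size, then by more
    converted-C anchors in the 3' windows, then leftmost. An unsatisfiable
    template yields an empty result with a structured no-candidates report.
    """
    params = params or DesignParams()
    t0, t1 = target
    n = len(ref)
    if not (0 <= t0 < t1 <= n):
        raise ValueError(f"target {target} outside locus bounds")
    results: dict[str, DesignResult] = {}
    for sp in strand_products:
        tmpl, forbidden, anchors = _template_and_masks(ref, sp)
        ft0, ft1 = (t0, t1) if sp == "sense_derived" else (n - t1, n - t0)
        fwd = _valid_windows(n, 0, ft0 + 1, forbidden, anchors, "right", params.anchor_window)
        fwd = [w for w in fwd if w.start <= ft0]
        rev_all = _valid_windows(n, ft1 - MAX_LEN, n, forbidden, anchors, "left", params.anchor_window)
        rev = [w for w in rev_all if w.end >= ft1]
        lo_amp = params.amplicon_target - params.amplicon_tol
        hi_amp = params.amplicon_target + params.amplicon_tol
        pairs = [
            (f, r)
            for f in fwd
            for r in rev
            if lo_amp <= r.end - f.start <= hi_amp and f.end <= r.start
        ]
        # candidate nested pairs, best-first; for each outer pair the first
        # one fitting inside wins, so the scan is usually very short
        nested_sorted = sorted(
            pairs,
            key=lambda p: (
                abs((p[1].end - p[0].start) - params.amplicon_target),
                -(p[0].anchor_hits + p[1].anchor_hits),
                p[0].start,
                p[1].start,
            ),
        )
        outer_ranked = sorted(
            pairs,
            key=lambda p: (
                abs((p[1].end - p[0].start) - params.amplicon_target),
                -(p[0].anchor_hits + p[1].anchor_hits),
                p[0].start,
                p[1].start,
            ),
        )
        # suffix-min of amplicon end over pairs with forward start >= s:
        # O(log) check whether any nested pair fits a given inner box
        starts_sorted = sorted({f.start for f, _ in pairs})
        min_end_from: dict[int, int] = {}
        running = 10**9
        by_start: dict[int, int] = {}
        for f, r in pairs:
            by_start[f.start] = min(by_start.get(f.start, 10**9), r.end)
        for s0 in reversed(starts_sorted):
            running = min(running, by_start[s0])
            min_end_from[s0] = running

        def nested_exists(lo_in: int, hi_in: int) -> bool:
            i = bisect_left(starts_sorted, lo_in)
            return i < len(starts_sorted) and min_end_from[starts_sorted[i]] <= hi_in

        sets: list[PrimerSet] = []
        for f, r in outer_ranked:
            if params.max_sets is not None and len(sets) >= params.max_sets:
                break
            lo_in = f.start + params.nested_inset_min
            hi_in = r.end - params.nested_inset_min
            if not nested_exists(lo_in, hi_in):
                continue
            for nf, nr in nested_sorted:
                if nf.start >= lo_in and nr.end <= hi_in:
                    sets.append(_make_set(tmpl, sp, f, r, nf, nr))
                    break
        if sets:
            results[sp] = DesignResult(sp, sets)
        else:
            results[sp] = DesignResult(
                sp,
                [],
                no_candidates={
                    "n_forward_windows": len(fwd),
                    "n_reverse_windows": len(rev),
                    "n_forbidden_positions": len(forbidden),
                    "n_anchor_positions": len(anchors),
                },
            )
    return results


def _make_set(tmpl: str, sp: str, f, r, nf, nr) -> PrimerSet:
    def fwd_spec(w, role):
        s = tmpl[w.start : w.end]
        return PrimerSpec(s, sp, w.start, w.length, role, estimate_tm(s))

    def rev_spec(w, role):
        s = reverse_complement(tmpl[w.start : w.end])
        return PrimerSpec(s, sp, w.start, w.length, role, estimate_tm(s))

    return PrimerSet(
        outer_F=fwd_spec(f, "outer_F"),
        outer_R=rev_spec(r, "outer_R"),
        nested_F=fwd_spec(nf, "nested_F"),
        nested_R=rev_spec(nr, "nested_R"),
        outer_amplicon=r.end - f.start,
        nested_amplicon=nr.end - nf.start,
        anchor_hits=f.anchor_hits + r.anchor_hits + nf.anchor_hits + nr.anchor_hits,
    )
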
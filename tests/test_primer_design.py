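"""Nested bisulfite primer design and the exhaustive window oracle."""

import numpy as np
import pytest

from bsphase.bisulfite_sim import convert_sequence
from bsphase.methylcall import build_cg_catalog
from bsphase.primer_design import (
    MAX_LEN,
    MIN_LEN,
    DesignParams,
    design_primer_set,
    estimate_tm,
)
from bsphase.sequtil import reverse_complement
from bsphase.snp_diagnostics import LocusReference
from bsphase.synthetic_data import LocusScenario, simulate_parents


class TestEstimateTm:
    def test_wallace_rule_on_short_oligo(self):
        assert estimate_tm("ACGT") == 12.0

    def test_monotone_in_gc_at_fixed_length(self):
        assert estimate_tm("A" * 26) < estimate_tm("G" * 26)
        tms = [estimate_tm("G" * k + "A" * (26 - k)) for k in range(27)]
        assert tms == sorted(tms)

    def test_deterministic(self):
        assert estimate_tm("ACGTACGTACGTACGTACGTACGTAC") == estimate_tm(
            "ACGTACGTACGTACGTACGTACGTAC"
        )

    def test_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError):
            estimate_tm("ACGY")


def _toy_reference(seed=11, length=520):
    """Identical parents; CG sites confined to the target interior."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(np.array(list("ACGT")), size=length))
    for i in range(length - 1):
        while seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = str(rng.choice(np.array(list("ACT"))))
    for p in (240, 262, 281):
        seq[p], seq[p + 1] = "C", "G"
    s = "".join(seq)
    return LocusReference("toy", s, s), (220, 320)


def _brute_force_windows(ref, strand_product, params):
    """Independent re-enumeration of all clean primer footprints."""
    n = len(ref)
    strand = "sense" if strand_product == "sense_derived" else "antisense"
    genomic = ref.seq_parent_A if strand == "sense" else reverse_complement(ref.seq_parent_A)
    genomic_b = ref.seq_parent_B if strand == "sense" else reverse_complement(ref.seq_parent_B)
    tmpl = convert_sequence(genomic)
    tmpl_b = convert_sequence(genomic_b)
    cg_positions = set()
    for site in build_cg_catalog(ref):
        p = site.sense_c_pos if strand == "sense" else site.antisense_c_pos
        cg_positions.add(p if strand == "sense" else n - 1 - p)
    forbidden = cg_positions | {i for i in range(n) if tmpl[i] != tmpl_b[i]}
    anchors = {
        i
        for i in range(n)
        if genomic[i] == "C" and tmpl[i] == "T" and i not in cg_positions
    }
    fwd, rev = [], []
    for start in range(n):
        for length in range(MIN_LEN, MAX_LEN + 1):
            end = start + length
            if end > n or any(p in forbidden for p in range(start, end)):
                continue
            f_anch = sum(1 for p in range(end - params.anchor_window, end) if p in anchors)
            r_anch = sum(1 for p in range(start, start + params.anchor_window) if p in anchors)
            if f_anch:
                fwd.append((start, length, f_anch))
            if r_anch:
                rev.append((start, length, r_anch))
    return tmpl, fwd, rev


class TestDesignPrimerSet:
    def test_toy_template_matches_brute_force(self):
        """Top-ranked sets equal an independent exhaustive enumeration of all
        window combinations, including the nested-pair choice."""
        ref, target = _toy_reference()
        k = 200
        params = DesignParams(max_sets=k)
        results = design_primer_set(ref, target, params)
        for sp in ("sense_derived", "antisense_derived"):
            res = results[sp]
            assert res.sets, f"no sets on {sp}"
            tmpl, fwd, rev = _brute_force_windows(ref, sp, params)
            n = len(ref)
            ft0, ft1 = target if sp == "sense_derived" else (n - target[1], n - target[0])
            lo = params.amplicon_target - params.amplicon_tol
            hi = params.amplicon_target + params.amplicon_tol
            bf_pairs = [
                (fs, fl, fa, rs, rl, ra)
                for fs, fl, fa in fwd
                if fs <= ft0
                for rs, rl, ra in rev
                if rs + rl >= ft1 and lo <= rs + rl - fs <= hi and fs + fl <= rs
            ]
            nfs = np.array([p[0] for p in bf_pairs])
            nre = np.array([p[3] + p[4] for p in bf_pairs])
            rank = np.array(
                [
                    (abs(p[3] + p[4] - p[0] - params.amplicon_target), -(p[2] + p[5]), p[0], p[3])
                    for p in bf_pairs
                ],
                dtype=[("dev", int), ("anch", int), ("fs", int), ("rs", int)],
            )
            order = np.argsort(rank, order=("dev", "anch", "fs", "rs"), kind="stable")
            inset = params.nested_inset_min
            expected = []
            for idx in order:
                fs, fl, fa, rs, rl, ra = bf_pairs[idx]
                fits = (nfs >= fs + inset) & (nre <= rs + rl - inset)
                if not fits.any():
                    continue
                best_nested = bf_pairs[min(np.flatnonzero(fits), key=lambda j: tuple(rank[j]))]
                expected.append(((fs, fl, rs, rl), (best_nested[0], best_nested[1],
                                                   best_nested[3], best_nested[4])))
                if len(expected) == k:
                    break
            got = [
                (
                    (s.outer_F.start, s.outer_F.length, s.outer_R.start, s.outer_R.length),
                    (s.nested_F.start, s.nested_F.length, s.nested_R.start, s.nested_R.length),
                )
                for s in res.sets
            ]
            assert got == expected

    def test_primer_sequences_come_from_converted_template(self):
        ref, target = _toy_reference()
        res = design_primer_set(ref, target)["sense_derived"]
        tmpl = convert_sequence(ref.seq_parent_A)
        best = res.sets[0]
        assert best.outer_F.seq == tmpl[best.outer_F.start : best.outer_F.end]
        assert best.outer_R.seq == reverse_complement(tmpl[best.outer_R.start : best.outer_R.end])
        assert "C" not in best.outer_F.seq  # fully converted, CG-free footprint

    def test_invariants_on_simulated_loci(self):
        for seed in range(4):
            sc = LocusScenario(length=700, promoter_len=300, cg_count_target=8,
                               divergence=0.01, seed=seed)
            ref, _ = simulate_parents(sc)
            params = DesignParams()
            results = design_primer_set(ref, (280, 400), params)
            for sp, res in results.items():
                for s in res.sets:
                    for primer in (s.outer_F, s.outer_R, s.nested_F, s.nested_R):
                        assert MIN_LEN <= primer.length <= MAX_LEN
                    assert abs(s.outer_amplicon - 300) <= params.amplicon_tol
                    assert abs(s.nested_amplicon - 300) <= params.amplicon_tol
                    assert s.nested_F.start >= s.outer_F.start + params.nested_inset_min
                    assert s.nested_R.end <= s.outer_R.end - params.nested_inset_min

    def test_unsatisfiable_template_reports_no_candidates(self):
        # CG sites everywhere: every window overlaps one
        s = "CG" * 200
        ref = LocusReference("dense", s, s)
        res = design_primer_set(ref, (150, 250))
        for sp in res.values():
            assert sp.sets == []
            assert sp.no_candidates is not None
            assert sp.no_candidates["n_forward_windows"] == 0

    def test_strand_symmetry(self):
        """Antisense design equals sense design on the reverse complement."""
        ref, target = _toy_reference()
        n = len(ref)
        ref_rc = LocusReference(
            "rc", reverse_complement(ref.seq_parent_A), reverse_complement(ref.seq_parent_B)
        )
        anti = design_primer_set(ref, target, strand_products=("antisense_derived",))
        sense_rc = design_primer_set(
            ref_rc, (n - target[1], n - target[0]), strand_products=("sense_derived",)
        )
        got = [
            (s.outer_F.seq, s.outer_R.seq, s.nested_F.seq, s.nested_R.seq)
            for s in anti["antisense_derived"].sets
        ]
        expected = [
            (s.outer_F.seq, s.outer_R.seq, s.nested_F.seq, s.nested_R.seq)
            for s in sense_rc["sense_derived"].sets
        ]
        assert got == expected
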
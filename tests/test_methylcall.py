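"""CG cataloging, conversion QC, site calling, hemimethylation, summaries."""

import pytest

from bsphase.bisulfite_sim import (
    ConvertedObservation,
    MethylationProfile,
    convert_duplex,
    sanger_consensus,
)
from bsphase.methylcall import (
    METHYLATED,
    MIXED,
    NO_DATA,
    UNMETHYLATED,
    CGSite,
    MethylationCall,
    build_cg_catalog,
    call_cg_site,
    call_locus,
    conversion_qc,
    detect_hemimethylation,
    integrate_silencing,
    summarize_locus,
)
from bsphase.snp_diagnostics import LocusReference


class TestBuildCgCatalog:
    def test_shared_site(self):
        cat = build_cg_catalog(LocusReference("x", "TACGTT", "TACGTT"))
        assert [(s.sense_c_pos, s.present_in) for s in cat] == [(2, "both")]
        assert cat[0].antisense_c_pos == 3

    def test_snp_destroyed_site_kept_as_single_parent(self):
        cat = build_cg_catalog(LocusReference("x", "TACGTT", "TATGTT"))
        assert [(s.sense_c_pos, s.present_in) for s in cat] == [(2, "A")]

    def test_no_sites(self):
        assert build_cg_catalog(LocusReference("x", "AAAAAA", "AAAAAA")) == []

    def test_region_labels_and_unannotated_sentinel(self):
        ref = LocusReference(
            "x", "TACGTTTCGTTT", "TACGTTTCGTTT", regions=[(0, 6, "promoter")]
        )
        cat = build_cg_catalog(ref)
        assert [(s.sense_c_pos, s.region) for s in cat] == [(2, "promoter"), (7, "unannotated")]

    def test_edge_sites_excluded(self):
        # CG at the very end: antisense context unresolvable
        assert build_cg_catalog(LocusReference("x", "TTTTCG", "TTTTCG")) == []


class TestConversionQC:
    def _ref(self):
        #        0123456789
        return LocusReference("q", "TTCATTCGTT", "TTCATTCGTT")

    def test_fully_converted_is_complete(self):
        obs = ConvertedObservation("TTTATTTGTT", "sense_derived", "consensus", "q")
        qc = conversion_qc(obs, self._ref())
        assert qc.verdict == "complete"
        assert qc.conversion_rate == 1.0
        assert qc.unconverted_positions == []

    def test_residual_chh_c_flagged(self):
        obs = ConvertedObservation("TTCATTTGTT", "sense_derived", "consensus", "q")
        qc = conversion_qc(obs, self._ref())
        assert qc.verdict == "incomplete"
        assert qc.unconverted_positions == [(2, "sense", "CHH", "C")]

    def test_cg_site_cytosine_not_checked(self):
        # C at 6 is the CG cytosine: reading C there is methylation, not failure
        obs = ConvertedObservation("TTTATTCGTT", "sense_derived", "consensus", "q")
        assert conversion_qc(obs, self._ref()).verdict == "complete"

    def test_rate_arithmetic(self):
        seq = "TTCA" * 10 + "TT"  # 10 CHH cytosines, none at the edge
        ref = LocusReference("q", seq, seq)
        observed = list(seq.replace("C", "T"))
        observed[2] = "C"  # one failure
        obs = ConvertedObservation("".join(observed), "sense_derived", "consensus", "q")
        qc = conversion_qc(obs, ref)
        assert qc.n_checked == 10
        assert qc.conversion_rate == pytest.approx(0.9)

    def test_length_mismatch_rejected(self):
        obs = ConvertedObservation("TTT", "sense_derived", "consensus", "q")
        with pytest.raises(ValueError):
            conversion_qc(obs, self._ref())


class TestCallCgSite:
    def _site(self, present="both"):
        return CGSite(sense_c_pos=4, region="promoter", present_in=present)

    @pytest.mark.parametrize(
        "obs,level,homeolog,evidence",
        [
            ("C", METHYLATED, "both", "uniform"),
            ("T", UNMETHYLATED, "both", "uniform"),
            ("Y", MIXED, "unassigned", "none"),
        ],
    )
    def test_shared_site_calls(self, obs, level, homeolog, evidence):
        call = call_cg_site(obs, self._site(), "sense")
        assert (call.level, call.homeolog, call.evidence) == (level, homeolog, evidence)

    def test_shared_site_conflict(self):
        call = call_cg_site("W", self._site(), "sense")
        assert call.level == NO_DATA and call.conflict

    def test_genotype_determined_methylated(self):
        call = call_cg_site("Y", self._site("A"), "sense", other_converted="T")
        assert (call.level, call.homeolog, call.evidence) == (
            METHYLATED,
            "A",
            "genotype_determined",
        )

    def test_genotype_determined_unmethylated(self):
        call = call_cg_site("T", self._site("A"), "sense", other_converted="T")
        assert (call.level, call.homeolog) == (UNMETHYLATED, "A")

    def test_genotype_determined_with_nonconvertible_other_allele(self):
        # other parent contributes A: unmethylated -> W, methylated -> M
        call = call_cg_site("W", self._site("B"), "sense", other_converted="A")
        assert (call.level, call.homeolog) == (UNMETHYLATED, "B")
        call = call_cg_site("M", self._site("B"), "sense", other_converted="A")
        assert (call.level, call.homeolog) == (METHYLATED, "B")
        # all three bases present: carrier partially methylated
        call = call_cg_site("H", self._site("B"), "sense", other_converted="A")
        assert call.level == MIXED and call.homeolog == "B"

    def test_genotype_determined_conflict(self):
        call = call_cg_site("G", self._site("A"), "sense", other_converted="T")
        assert call.level == NO_DATA and call.conflict

    def test_single_parent_site_requires_other_base(self):
        with pytest.raises(ValueError):
            call_cg_site("Y", self._site("A"), "sense")

    def test_oracle_simulation_of_genotype_determined_logic(self):
        """Genotype-determined calls equal brute-force simulation through
        convert_duplex + sanger_consensus for every non-C other allele and
        every binary state of the carrier, on both strands."""
        for other_allele in "AGT":
            #       0123456789
            hap_a = "TTTACGTTTT"
            hap_b = hap_a[:4] + other_allele + hap_a[5:]
            ref = LocusReference("o", hap_a, hap_b)
            cat = build_cg_catalog(ref)
            assert len(cat) == 1 and cat[0].present_in == "A"
            site = cat[0]
            for meth_a in (False, True):
                profile = MethylationProfile(
                    "o",
                    {("sense", 4): 1.0, ("antisense", 5): 1.0} if meth_a else {},
                )
                prod_a = convert_duplex(hap_a, profile, 1.0)
                prod_b = convert_duplex(hap_b, MethylationProfile("o"), 1.0)
                for strand, idx in (("sense", 0), ("antisense", 1)):
                    consensus = sanger_consensus(
                        [(prod_a[idx], 1.0), (prod_b[idx], 1.0)], 0.2
                    )
                    n = len(hap_a)
                    c_pos = site.sense_c_pos if strand == "sense" else site.antisense_c_pos
                    frame = c_pos if strand == "sense" else n - 1 - c_pos
                    obs_base = consensus[frame]
                    # the non-carrier's converted base, from its own allele
                    view_b = prod_b[idx]
                    other_conv = view_b[frame]
                    call = call_cg_site(obs_base, site, strand, other_conv)
                    assert call.evidence == "genotype_determined", (other_allele, strand)
                    assert call.homeolog == "A"
                    assert call.level == (METHYLATED if meth_a else UNMETHYLATED)


class TestCallLocus:
    def test_mixture_and_genotype_determined(self, two_region_ref):
        ref = two_region_ref
        # A methylated everywhere, B unmethylated
        prof_a = MethylationProfile(
            "t", {("sense", 4): 1.0, ("antisense", 5): 1.0,
                  ("sense", 10): 1.0, ("antisense", 11): 1.0}
        )
        prod_a = convert_duplex(ref.seq_parent_A, prof_a, 1.0)
        prod_b = convert_duplex(ref.seq_parent_B, MethylationProfile("t"), 1.0)
        obs = {}
        for strand, idx, product in (("sense", 0, "sense_derived"), ("antisense", 1, "antisense_derived")):
            obs[product] = ConvertedObservation(
                sanger_consensus([(prod_a[idx], 1.0), (prod_b[idx], 1.0)], 0.2),
                product,
                "consensus",
                "t",
            )
        calls = call_locus(obs["sense_derived"], obs["antisense_derived"], ref)
        by_pos = {(c.site.sense_c_pos, c.strand): c for c in calls["sense"] + calls["antisense"]}
        # shared CG at 4: A methylated + B unmethylated -> mixed, unphased
        assert by_pos[(4, "sense")].level == MIXED
        assert by_pos[(4, "sense")].homeolog == "unassigned"
        # SNP-destroyed CG at 10: genotype-determined methylated A
        assert by_pos[(10, "sense")].level == METHYLATED
        assert by_pos[(10, "sense")].homeolog == "A"
        assert by_pos[(10, "antisense")].level == METHYLATED

    def test_missing_observation_gives_no_data(self, two_region_ref):
        calls = call_locus(None, None, two_region_ref)
        assert all(c.level == NO_DATA for c in calls["sense"] + calls["antisense"])


class TestDetectHemimethylation:
    def _call(self, level, strand, pos=2):
        site = CGSite(pos, "genic", "both")
        homeolog = "both" if level in (METHYLATED, UNMETHYLATED) else "unassigned"
        evidence = "uniform" if homeolog == "both" else "none"
        obs = {"methylated": "C", "unmethylated": "T", "mixed": "Y"}.get(level)
        return MethylationCall(site, strand, level, homeolog, evidence, obs)

    @pytest.mark.parametrize(
        "s_level,a_level,flag",
        [
            (UNMETHYLATED, METHYLATED, "hemi_antisense"),
            (UNMETHYLATED, MIXED, "hemi_antisense"),
            (METHYLATED, UNMETHYLATED, "hemi_sense"),
            (METHYLATED, METHYLATED, "symmetric"),
            (UNMETHYLATED, UNMETHYLATED, "symmetric"),
            (NO_DATA, METHYLATED, "indeterminate"),
            (MIXED, MIXED, "indeterminate"),
        ],
    )
    def test_flag_table(self, s_level, a_level, flag):
        got = detect_hemimethylation(
            [self._call(s_level, "sense")], [self._call(a_level, "antisense")]
        )
        assert got == [flag]

    def test_catalog_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_hemimethylation(
                [self._call(METHYLATED, "sense", pos=2)],
                [self._call(METHYLATED, "antisense", pos=5)],
            )


class TestSummarizeLocus:
    def test_genic_fraction(self):
        calls = []
        for i in range(11):
            site = CGSite(10 + 3 * i, "genic", "both")
            level = METHYLATED if i < 5 else UNMETHYLATED
            calls.append(
                MethylationCall(site, "antisense", level, "both", "uniform",
                                "C" if i < 5 else "T")
            )
        summary = summarize_locus(calls, None)
        st = summary[("genic", "antisense")]
        assert st["n_sites"] == 11 and st["n_methylated"] == 5
        assert st["fraction_methylated"] == pytest.approx(5 / 11)

    def test_mixed_not_counted_as_methylated(self):
        site = CGSite(3, "promoter", "both")
        calls = [MethylationCall(site, "sense", MIXED, "unassigned", "none", "Y")]
        st = summarize_locus(calls, None)[("promoter", "sense")]
        assert st["n_methylated"] == 0 and st["n_mixed"] == 1
        assert st["fraction_methylated"] == 0.0


class _Record:
    def __init__(self, silenced):
        self.silenced_homeolog = silenced


class TestIntegrateSilencing:
    def _calls(self, strand, level, homeolog="A"):
        site = CGSite(3, "promoter", "A" if homeolog == "A" else "both")
        ev = "genotype_determined" if homeolog in ("A", "B") else "uniform"
        return [MethylationCall(site, strand, level, homeolog, ev, "Y")]

    def test_methylated_on_both_strands(self):
        verdict = integrate_silencing(
            {"sense": self._calls("sense", METHYLATED),
             "antisense": self._calls("antisense", METHYLATED)},
            _Record("d"),
        )
        assert verdict.silenced_homeolog_methylated == "yes"
        assert verdict.formatted == "Yes-A/S"

    def test_antisense_only(self):
        verdict = integrate_silencing(
            {"sense": self._calls("sense", UNMETHYLATED),
             "antisense": self._calls("antisense", METHYLATED)},
            _Record("d"),
        )
        assert verdict.formatted == "Yes-A"

    def test_silenced_but_unmethylated(self):
        verdict = integrate_silencing(
            {"sense": self._calls("sense", UNMETHYLATED),
             "antisense": self._calls("antisense", UNMETHYLATED)},
            _Record("d"),
        )
        assert verdict.silenced_homeolog_methylated == "no"
        assert verdict.formatted == "No"

    def test_no_record_not_applicable(self):
        assert integrate_silencing({}, None).formatted == "NA"
        assert integrate_silencing({}, _Record("genomic_copy_lost")).formatted == "NA"

    def test_methylation_of_other_homeolog_does_not_count(self):
        verdict = integrate_silencing(
            {"sense": self._calls("sense", METHYLATED, homeolog="A")},
            _Record("p"),  # B silenced, but only A methylated
        )
        assert verdict.silenced_homeolog_methylated == "no"
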
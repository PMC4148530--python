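# bsphase

Homeolog-specific DNA methylation analysis from bisulfite Sanger amplicons
in allopolyploids.

## The problem

An allopolyploid carries two diverged parental subgenomes, so every locus
exists as two homeologous copies. When one copy falls silent, a natural
suspect is promoter or gene-body CG methylation of that copy alone —
but a direct Sanger read of a bisulfite PCR product is a *mixture* of both
homeologs, and bisulfite conversion (unmethylated C → U → T) erases most of
the sequence differences that would let you tell them apart.

`bsphase` implements the comparative bisulfite sequencing workflow for this
setting, built around *Tragopogon miscellus* (formed from *T. dubius* ×
*T. pratensis*) but applicable to any two-parent polyploid:

1. **SNP survival screening** (`snp_diagnostics`) — classify every parental
   SNP, per strand, as *diagnostic* (post-conversion observable sets of the
   two alleles are disjoint), *lost* (both alleles read identically after
   conversion, e.g. a C/T SNP with the C in CHH context reading T/T), or
   *confounded* (overlap depends on methylation state, e.g. the C sits in a
   CG context and reads C or T). A locus with no surviving diagnostic SNP
   in the amplicon cannot be phased and is screened out.
2. **In-silico bisulfite conversion** (`bisulfite_sim`) — per-strand,
   per-cytosine methylation states (hemimethylation representable),
   tunable conversion efficiency, and Sanger-style mixed-template consensus
   emission with IUPAC ambiguity codes (Y = C/T, W = A/T, R = A/G …).
3. **Primer design** (`primer_design`) — strand-specific nested primer
   pairs (26–29 bp, ~300 bp amplicons) on the fully converted template,
   avoiding CG-site cytosines and anchoring the 3' end on a converted C.
4. **Methylation calling** (`methylcall`) — conversion-integrity QC (every
   C not followed by G must read T), per-CG-site per-strand calls, homeolog
   attribution at *genotype-determined* sites (a CG destroyed by a SNP in
   one parent pins the composite peak's C to the other parent),
   hemimethylation flags, region summaries, and concordance with
   expression-silencing records.
5. **Clone quantification** (`clone_quant`) — assign cloned converted
   molecules to homeologs via diagnostic SNPs and estimate the
   per-homeolog methylated-clone ratio with an exact (Clopper–Pearson)
   95% CI.
6. **Synthetic data** (`synthetic_data`) — a generator producing two
   diverged parental haplotypes, methylation profiles, consensus and clone
   observables, and complete ground truth, so the whole pipeline is
   testable without any external data.

## Worked example

Simulate an individual whose *T. dubius*-like homeolog (parent A) is fully
CG-methylated while the *T. pratensis*-like homeolog (parent B) is not,
then call it:

```python
from bsphase.synthetic_data import LocusScenario, simulate_parents, simulate_individual
from bsphase.methylcall import call_locus, conversion_qc
from bsphase.clone_quant import call_clone, homeolog_methylation_ratio

scenario = LocusScenario(locus_id="T1", pattern_A="cg_both", pattern_B="none", seed=5)
ref, truth = simulate_parents(scenario)
bundle, truth = simulate_individual(scenario, truth)

calls = call_locus(bundle.converted_consensus["sense_derived"],
                   bundle.converted_consensus["antisense_derived"],
                   ref, truth.catalog)
print(sorted({(c.level, c.homeolog) for c in calls["sense"]}))
# [('mixed', 'unassigned')]

qc = conversion_qc(bundle.converted_consensus["sense_derived"], ref)
print(qc.verdict, qc.conversion_rate, qc.n_checked)
# complete 1.0 169
```

Every shared CG site reads Y (a C/T composite peak): both homeologs
contribute, one methylated, one not — direct sequencing cannot phase the
mixture. The QC line confirms all 169 convertible (non-CG) cytosines read
T, so the Y peaks are methylation, not failed conversion. Cloning resolves
the mixture:

```python
clone_calls = []
for obs, (hom, product) in zip(bundle.clones, truth.clone_origins):
    strand = "sense" if product == "sense_derived" else "antisense"
    clone_calls.append(call_clone(obs.seq, truth.snps, truth.catalog, ref, strand))
rep = homeolog_methylation_ratio(clone_calls)
print(rep.n_meth_A, rep.n_meth_B, rep.n_assigned_A, rep.n_assigned_B)
# 10 0 10 14
```

All 10 clones assigned to homeolog A are methylated and none of the 14
B clones are — the simulated one-sided methylation, recovered.

The same stages are available as a CLI (`bsphase simulate`,
`diagnose-snps`, `design-primers`, `qc-conversion`, `call`, `clones`,
`report`), all seeded through `--seed`.

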
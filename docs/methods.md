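# Methods

## Model of the assay

A locus is represented by two pre-aligned, gap-free parental haplotypes of
equal length (parent A, *T. dubius*-like; parent B, *T. pratensis*-like)
with half-open promoter/genic region annotations. All coordinates are
0-based, half-open; "sense" is the orientation of the stored reference
string. The tetraploid template pool is the two haplotypes at equal weight
(single-copy homeologous loci).

Bisulfite chemistry is modeled as an independent per-cytosine event: an
unmethylated C converts to T with probability *e* (conversion efficiency),
a 5-methyl-C never converts, and A/G/T are untouched. Methylation state is
carried per strand and per cytosine as a probability in [0, 1], keyed by
the cytosine's sense coordinate (for the antisense strand that position
holds the paired G). This representation covers symmetric CG methylation,
hemimethylation, and within-homeolog partial methylation. After conversion
the two strands are no longer complementary and are treated as distinct
strand products, each read 5'→3' in its own frame.

Direct Sanger sequencing of a mixed pool is modeled in the bulk limit: at
each position the expected base distribution of every template is summed
at its template weight, and every base reaching the minor-peak threshold
(default 0.2, a typical secondary-peak detectability for Sanger traces)
enters the emitted IUPAC code. Clones are single molecules: homeolog drawn
at equal odds, binary methylation sampled from the homeolog's profile, and
stochastic conversion applied per molecule. The bulk-limit consensus is
deliberately noise-free — at realistic efficiencies (e.g. 0.98) a 2%
unconverted fraction sits far below the minor-peak threshold, so
conversion failures surface in clones, exactly where the QC step looks for
them; only a systematic per-site failure (not modeled; the simulator
exposes a single global efficiency knob plus an optional non-CG
methylation probability) would produce a visible consensus-level failure
peak.

## Cytosine contexts and the CG catalog

A cytosine's context is read 3' on its own strand: CG if the next base is
G; CHG if (H, G) follows; CHH if (H, H); H = A, C or T. A cytosine whose
context cannot be resolved before the strand ends is labeled EDGE; since
CG needs only one downstream base, a C directly followed by G is CG even
at the penultimate position. The CG catalog lists every CG dinucleotide
present in *either* parent, labeled with its region and with
`present_in ∈ {A, B, both}`; sites whose cytosine sits within two bases of
either sequence end are excluded because the partner strand's context is
unresolvable there. A CG destroyed by a SNP in one parent has no CG
cytosine on either strand of that parent, so presence is a per-parent (not
per-strand) property.

## SNP survival classification

Post-conversion observables of an allele placed in its own haplotype
context: a non-C allele reads as itself; a C in CHG/CHH context reads T
(complete conversion, no non-CG methylation — deviations are a QC matter,
the observable sets are not widened for them); a C in CG context reads
{C, T} depending on methylation. A C in EDGE context also keeps {C, T}
(convertibility undefined). Per strand, a SNP is *diagnostic* when the two
alleles' sets are disjoint, *lost* when both sets are determinate
singletons that coincide, and *confounded* when the overlap involves a
methylation-dependent set — confounded sites are kept distinct from lost
ones because a caller can exploit them jointly with the methylation state
(the genotype-determined logic below). An amplicon is amenable when at
least one diagnostic SNP (threshold configurable, default 1) survives on
at least one strand. A notable consequence of the rule table: a C/T SNP
whose C is convertible collapses on that strand but its G/A counterpart on
the other strand always survives, which is why strand-specific screening
matters.

The classification rule is validated by exhaustive enumeration: every
ordered allele pair embedded in every two-base flanking context is driven
through the conversion operator under all legal methylation states (all
subsets of CG-context cytosines), and the statuses derived from the
enumerated observable sets must match the rule table exactly.

## Calling logic

At a site present in both parents, the consensus peak at the CG cytosine
is read directly: C → methylated (both homeologs), T → unmethylated
(both), Y → mixed, which direct sequencing cannot attribute and which is
left for clone phasing. At a site present in one parent P, the other
parent's converted contribution b′ is fixed by its own allele (its C, if
any, is non-CG there and reads T), so the composite peak solves for P's
state: observation = merge(b′, T) → P unmethylated, merge(b′, C) → P
methylated, merge(b′, C, T) → P partially methylated; anything else is
flagged as a conflict. When b′ = T the methylated and partial expectation
coincide (both Y); the binary reading wins, which is the conservative
choice for pure-state templates.

A consensus Y at a *non-CG* C is never a methylation call: it is recorded
by the conversion-integrity QC as a failed conversion, with the context
retained so a CHH/CHG-methylation interpretation stays possible. The QC
denominator is every column where at least one relevant parent carries a
CHG/CHH cytosine and no relevant parent carries a CG cytosine (a CG C may
legitimately read C, so such columns cannot falsify conversion); N
observations drop out of the denominator.

Hemimethylation flags compare the two strands per site:
strand-asymmetric (unmethylated vs methylated-or-mixed) →
`hemi_sense`/`hemi_antisense`; equal determinate levels → `symmetric`;
anything else → `indeterminate`. Region summaries report methylated
fractions with mixed calls counted separately, never as methylated.
Concordance with an expression-silencing record is "yes" when the silenced
homeolog (subscript d → parent A, p → parent B) carries at least one
methylated CG site (threshold configurable), reported per strand in the
A/S notation of the survey table.

## Clone quantification

Clones are assigned through strand-appropriate diagnostic SNPs: at least
`min_matches` (default 1) supporting SNPs and none conflicting → A or B;
one supporter of each parent → chimeric (PCR recombinant); otherwise
ambiguous. Chimeric and ambiguous clones are excluded from ratios but
counted. A clone is "methylated" under the default `any_site` rule (at
least one CG site reads C), matching how methylated clone copies are
counted in practice; a `all_sites` rule is available. The report gives
n_meth_A/n_meth_B and an exact Clopper–Pearson 95% interval on the
proportion n_meth_A/(n_meth_A + n_meth_B), which is exact at clone-pool
sizes (n = 12).

The ratio of two small binomial counts is biased upward as a per-pool
statistic (E[X/Y] > E[X]/E[Y]; at the 2:1 regime with 12-clone pools the
mean per-pool ratio is ≈ 2.3–2.4). Calibration therefore aggregates pooled
counts across replicates — the pooled ratio is consistent for the true
template-proportion ratio — while the per-pool ratio remains available as
the descriptive per-individual statistic.

## Primer design

Primers are designed against the fully converted unmethylated template of
each strand product. Footprints must avoid every CG-site cytosine (those
columns are C-or-T depending on methylation; encoding them as Y would bias
amplification toward one state) and every column where the two parents'
converted templates differ (one primer set must amplify both homeologs).
"Near the 3' end" is operationalized as: the 3'-terminal window (default
3 bases) must cover at least one originally non-CG C, which reads T only
in converted template — the standard bisulfite-specificity anchor; the
window size is configurable because the underlying design practice is
loose on this point. Lengths are 26–29 bp; outer and nested amplicons must
cover the target interval and fall within 300 ± 60 bp; the nested pair
sits at least 15 bp inside the outer amplicon. Candidate sets are ranked
by |outer amplicon − 300|, then more converted-C anchors in the 3'
windows, then leftmost start; for each outer pair the best nested pair
under the same ordering is attached. By default the top 50 sets per strand
are returned (configurable, `None` = all). An unsatisfiable template
yields an empty result with a structured no-candidates report rather than
an exception. The Tm estimate is the Wallace rule up to 14 nt and the
GC-fraction formula 64.9 + 41·(GC − 16.4)/N above that; only determinism
and GC-monotonicity are relied upon.

## Synthetic data

Base composition is uniform over {A, C, G, T} outside reserved CG slots;
accidental CG dinucleotides are broken so the catalog size equals the
requested target exactly, split between promoter and genic regions in
proportion to their lengths. Parent B derives from parent A by per-site
substitution at the divergence rate (default 0.02, a few-percent level
typical of congeneric diploids); substitutions may destroy a reserved CG
in B — producing the genotype-determined site class — but never create a
new CG. When divergence > 0 and the locus is ≥ 300 bp, targeted placement
guarantees at least one fully surviving A/T SNP and one strand-asymmetric
C/T-in-CHH SNP, so every SNP-survival class is exercised. Methylation
patterns are given symbolically per homeolog (`none`, `cg_both`,
`cg_sense`, `cg_antisense`, or a probability for partial methylation) and
concretized into per-position profiles once the sequence exists — the
concrete profiles live in the ground-truth object.

Scenario defaults: locus 600 bp split evenly into promoter and genic
halves, 11 CG sites (the promoter+genic count of a representative locus in
the motivating system), divergence 0.02, conversion efficiency 1.0,
12 clones per strand product, minor-peak threshold 0.2. The silencing row
follows a stated simulation convention — a homeolog whose promoter CG
sites are all fully methylated on both strands is recorded silenced — with
an override flag to decouple silencing from methylation (loci silenced by
other mechanisms show exactly that pattern). Randomness is counter-based
(Philox) per position, so draws are reproducible under reordering, and a
single integer seed determines a whole scenario.

What the generator does *not* emulate: PCR amplification bias, sequencing
error, chromatogram peak-height variation, indels between parents, more
than two haplotypes, and systematic per-site conversion failure. Passing
recovery tests therefore demonstrates correctness of the calling logic
under the stated assay model, not robustness to trace-level artifacts of
real Sanger data.

## Validation studies and problem sizes

The evaluation module runs: the exhaustive SNP oracle (6144 cases);
a 1000-sequence conversion-algebra sweep (lengths ≤ 500); end-to-end
recovery over 200 loci of 600 bp cycling five methylation scenarios
(both-methylated, A-only, B-only, none, antisense-hemimethylated A) at
10–22 CG sites each, at efficiency 1.0 and again at 0.98 with 12 clones;
clone-ratio calibration over 1000 replicates of 12-clone pools at
methylated-template proportions 2/3 (A) vs 1/3 (B) on a fixed 300 bp
locus; and an amenability screen over constructed adversarial loci. These
sizes give stable percentages (binomial standard errors well under the
asserted margins) while keeping the full suite fast on a single core.

## Known limitations

* Direct-consensus calls cannot phase a Y peak at a site present in both
  parents; only clones resolve it. Sites confounded in *both* the SNP and
  methylation dimension simultaneously are reported as conflicts rather
  than guessed.
* The conversion-QC denominator excludes columns where any relevant parent
  has a CG cytosine, so a locus consisting almost entirely of CG cytosines
  would have little QC power — not a realistic regime.
* Ratio confidence intervals condition on assigned, non-chimeric clones;
  assignment errors (absent at the simulated SNP densities) would
  propagate into the interval.
* The silencing-concordance verdict uses a one-site threshold by default;
  locus-level verdicts in real surveys may apply stricter conventions.
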
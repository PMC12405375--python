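# Methods

This note documents the models, rules, and numerical choices behind the
package, and what its synthetic-data tests do and do not demonstrate about
real breeding data.

## Genome model

Coordinates are genetic (centimorgan) throughout; there are no base-pair
positions. SNP alleles use array-style A/B encoding (0/1, −1 missing)
rather than REF/ALT nucleotides, matching genotyping-array semantics; SSR
alleles are integer fragment sizes. Chromosomes are linkage groups
`LG01`..`LG17`. Missing is a first-class allele state. A null allele is
*not* missing: it is a marker allele that fails to read, so a true
heterozygote appears homozygous for the visible allele — the pedigree-QC
module exists to find and repair exactly those calls.

The genetic map is the single coordinate authority: loaders never reorder
loci, and write→load round-trips are byte-stable for all three file kinds
(map TSV, phased VCF or wide haplotype table, pedigree CSV).

## Synthetic data

The generator emulates the study system at desk scale:

* **Map** — 17 linkage groups of 80 cM with 100 SNPs each (1,700 SNPs,
  1,360 cM diploid 2,720 cM) by default. This is a deliberate scale-down
  of the ~10,000-SNP curated array map so the full test suite runs in
  minutes; `snps_per_chrom` scales it up. The real map's total length is
  not published, so 80 cM per group is a stand-in, not a reconstruction.
* **Allele frequencies** — exotic and domestic per-SNP allele frequencies
  are drawn independently, Uniform(0,1) each. No frequency model is
  imposed; the only property the tracing rules need is that exotic
  haplotypes share no extended runs with domestic material, which
  independent profiles deliver (two unrelated haplotypes from *different*
  pools match at ~50% of SNPs, so a 16-SNP run has probability ≈ 2⁻¹⁶ per
  start). Linkage disequilibrium within the domestic pool is not modeled;
  consequently identity-by-state background between domestic individuals
  (~2/3 per-SNP match) is slightly *below* real-world levels of haplotype
  sharing among related elite cultivars.
* **Donor construction** — the donor is assembled as the offspring of a
  fully exotic pseudo-parent and a pseudo-parent carrying its identified
  domestic ancestry (mirroring a donor that is elite × unknown-exotic, or
  one with a single domestic grandparent). Homolog 0 carries min(2f, 1)
  exotic genome and homolog 1 the remainder, with per-chromosome
  breakpoints snapped to inter-SNP midpoints and a running carry, so the
  diploid exotic fraction hits the requested f (0.75 for the MR5-like
  preset, 0.50 for the 'Evereste'-like preset) to within one inter-SNP
  interval. The R-gene window is forced inside an exotic segment on the
  carrier homolog.
* **Marker panel** — in synthetic mode the foreground panel consists of
  SNPs inside the R-gene window whose coupling allele is carried only by
  the donor's carrier homolog (the domestic pool frequency is set to 0).
  This mirrors donor-diagnostic SSR alleles; real SSR chemistry is not
  simulated. Markers stand for the gene: marker–gene recombination is out
  of scope, so "truth carriage" means carriage at the marker positions.
* **Noise** — null-allele injection picks heterozygous sites with a given
  per-SNP probability, chooses the null homolog uniformly, and writes the
  visible allele homozygous. The study reports no quantitative null-allele
  rate; the default of 0.02 is a sensitivity-test placeholder, not an
  empirical value. Truth haplotypes and ancestry labels stay intact on the
  originals.

Every simulated individual carries truth ancestry segments
(exotic/domestic) per homolog, tagged with the founder haplotype they
descend from. Segments tile each homolog exactly; splicing at meiosis
preserves the tiling.

## Meiosis and breeding programs

Crossovers follow the Haldane model: per chromosome the count is
Poisson(L/100) for L cM, breakpoints are Uniform(0, L), with no
interference, no obligate chiasma, and no sex-specific maps. None of these
refinements is specified by the study, and the memoryless model is
analytically checkable (halving law, allele conservation).

`run_pbc_series` parameterizes generations by **meiosis count from the
donor**, never by labels like pBC'4, because label conventions (whether
counting starts at the donor or at an F1 selection) are ambiguous across
programs; the expectation calculator likewise takes the meiosis count
explicitly. Published "expected" percentages of 3.1 for a 50%-donor and
2.3 for a 75%-donor lineage correspond to 4 and 5 meioses respectively,
which is what the calculator reproduces; a label-based chain counted from
the donor itself would give different values, and the package does not
decide which convention a given label implies.

Recurrent parents are fresh unrelated domestic founders each generation
(pseudo-backcrossing uses many distinct cultivars precisely to avoid
inbreeding). Flowering attrition is a per-vernalization-cycle conditional
Bernoulli with at most four cycles (seedlings not flowering by the fourth
are discarded); the cumulative flowering fraction is 1 − Π(1 − pₖ).
Background selection, when enabled, ranks carriers by truth exotic
fraction — using truth rather than traced estimates keeps the tracer's
evaluation independent of the selection it is evaluated on; traced-based
ranking can be run manually from the reports.

## Haplotype tracing

`find_shared_segments` returns maximal runs of matching informative SNPs:
an informative mismatch breaks a run, missing-on-either-side SNPs neither
break nor count, and runs are trimmed to informative shared SNPs at both
ends. The implementation is checked against a naive quadratic scanner on
random instances.

Filtering interprets "more than 15 SNPs" as **≥ 16 informative shared
SNPs** (the boundary is tested explicitly; missing-spanned sites do not
count toward the total). The non-admixed-parent rule drops a surviving
segment the parent also carries unless, walking outward SNP by SNP from
either end, the descendant's match to the donor runs strictly farther than
its match to the parent (by a configurable minimum, default one
informative SNP) on at least one side; such segments are retained with an
`exception-retained` disposition and the report flags that the exception
fired. The extended region's length is not quantified in the source
methodology; strict-extension-beyond-parent is this package's
operationalization.

Segment length is measured from first to last shared SNP (closed, cM);
chromosome-end segments stop at the terminal mapped SNP. Overlapping
retained intervals on one descendant homolog are merged before cM
accounting, so nothing is double-counted. The unadapted percent is total
retained cM over twice the map length.

**Subtraction boundaries.** Defining unadapted donor haplotypes by
subtracting ancestor-shared segments has an intrinsic boundary
uncertainty: an ancestor match extends past the true ancestry junction by
a Geometric(1/2) number of chance-matching SNPs. Tracer recovery is
therefore scored two ways in the tests: against a truth-derived donor
partition (isolating the tracer: segment recall and precision ≥ 0.95,
boundary error ≤ one inter-SNP interval on the default map) and end-to-end
through subtraction (cM recall ≥ 0.9). With null-allele noise at rate
0.02, cM-weighted recall degrades by at most five points; recall is
cM-weighted there because a dropout that splits a run in two leaves the
truth interval mostly covered, making whole-segment recall ill-posed.

What passing these tests shows — and does not: the synthetic exotic pool
is maximally distinguishable from the domestic pool, phasing is perfect,
and pedigrees are exactly known. Real data add phasing errors, curation
artifacts, and shared-by-state haplotypes among related elite parents, so
real-world precision/recall will be lower; the advanced-generation cohort
means published for the real program (≈1.5% and ≈3.9%) depend on its
particular crosses and are used only as plausibility corridors, not as
reproduction targets.

## Pedigree QC

Parent–offspring candidacy uses the opposing-homozygote (Mendelian-error)
rate over jointly typed sites, threshold 0.005 by default (the source
methodology cites an external protocol without printing a number; 0.5% is
conservative given unrelated pairs on the synthetic pool score ≈ 6–7%).
Null-allele adjustment has two modes: conservative (conflicting sites set
missing in both duo members — the default, since the original recoding
choice is unstated) and recode (a conflict replicated in ≥ 2 independent
offspring recodes the parent heterozygous-with-null). Adjustment never
increases a true duo's error rate.

Genome-wide sharing reports, per homolog of one individual, the cM covered
by qualifying (≥ 16-SNP) shared segments against either homolog of the
other; the diploid percent is the mean over homologs. It is a screening
statistic, biased slightly downward by the segment-length filter (IBD
fragments shorter than 16 SNPs are invisible) and upward by
identity-by-state background; the grandparent test subtracts the
background measured on unrelated pairs and uses a denser map so the filter
costs little.

## Summaries

Funnel statistics pool counts per location; per-generation averages divide
by the number of generations with a nonzero cross count at that location
(the only convention consistent with the reference table's printed
averages, e.g. 96/5 = 19.2). The carrier percentage is reported both
pooled and as the mean of per-generation percentages — the reference
table's totals row uses the latter. Zero denominators yield NaN, never 0.
Seed planning is the deterministic inverse chain
seeds = ⌈target / (survival × carrier × flowering)⌉.

ANOVA uses scipy's one-way F test and statsmodels' Tukey HSD; the compact
letter display is built by insert-and-absorb over the all-pairs decisions
and is property-tested against them (groups share a letter iff not
significantly different) on 1,000 random instances. When all values are
identical the display degenerates gracefully to a single shared letter
with p = 1.

## Problem sizes and determinism

Default test problem sizes — 1,700-SNP map, cohorts of 20–40, 10 program
replicates, 10,000 offspring for the segregation check — were chosen as
the smallest scales at which the Monte-Carlo tolerances (3 SE bands) are
meaningful. All randomness flows from explicit seeds; every CLI run
directory records its config and seed, and identical seeds reproduce
phased and truth outputs bit-identically.
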
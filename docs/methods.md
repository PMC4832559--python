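# Methods

## Screening model

The screen encodes one biological hypothesis: a variant that abolishes the
function of a gene required for male fertility can segregate in a population
of fertile males only in the heterozygous state (recessive case) or not at
all (dominant case). The filter cascade therefore retains a biallelic SNV
when it (1) falls inside the transcript span of a candidate gene, (2) has no
hit in the known-variant lists, (3) shows at least one heterozygote and no
homozygous-mutant call in the detection panel, and (4) is classified high
impact. Missing genotype calls carry no evidence in either direction
(per-site complete case), and a site where every called sample is
heterozygous is retained — the rule bars only the mutant homozygote. The
filters are set-intersections, so their order cannot change the result; the
property suite asserts this.

## Consequence classification

The classifier evaluates one annotated transcript per gene, with 1-based
closed genomic intervals throughout. The spliced CDS is the concatenation of
the exon∩CDS fragments in genomic order, reverse-complemented for
minus-strand transcripts. Categories:

- **splice donor / acceptor** — the site lies in the first or last 2
  intronic bases of an intron in transcript orientation (the canonical
  GT/AG footprint). The window width is a parameter (`splice_window`,
  default 2) because annotation tools differ at the margins.
- **start lost** — any mutation of codon 1 whose product is not ATG,
  including third-base changes that would look synonymous elsewhere.
- **stop gained / stop lost** — the mutated codon enters or leaves
  {TAA, TAG, TGA} while the reference codon does not.
- everything else (missense, synonymous, UTR, deep intron, intergenic) is
  **other** and never high impact.

Protein notation uses one-letter codes with the codon number from the CDS
offset (`p.W155*`, `p.M1T`). Correctness is tested against an independent
oracle that rebuilds and fully translates the reference and mutant spliced
CDS for every possible SNV in random 2–4-exon mini-genes on both strands,
and against an explicit strand-mirroring symmetry check. Frameshift and
exon-loss consequences apply to indels, which are out of scope: the screen
is restricted to SNVs.

## Per-site statistics

For genotype counts (n_AA, n_AB, n_BB): the mutant (alt) allele frequency is
q = (2·n_BB + n_AB)/2n, MAF = min(p, q), HET = n_AB/n. The Hardy–Weinberg
test is the uncorrected 1-df chi-square against expected counts p²n, 2pqn,
q²n — no Yates correction and no exact test, which is what reproduces the
published statistics from the counts (22.094, 120.250, 18.572). Monomorphic
sites report chi2 = 0 with the P-value undefined (rendered as a dash).
E(hom) = q²·n_ref takes the reference n as a parameter because two
conventions coexist in reports: the per-site genotyped n and the full cohort
(337); outputs label which was used. MAF group III is the closed interval
[0.01, 0.1] so that variants at 0.0110–0.0125 fall in group III, matching
the published grouping. Cohort summaries are unweighted means over sites and
include zero-MAF sites in the MAF mean (denominator 17).

## Association

Genotype is modeled as an unordered factor, not a dosage, following the
genotype-means presentation of the source analyses; r² is model SS over
total SS from the overall F test. The mixed model
y = Xβ + u + e with cov(u) = σ²_g K, cov(e) = σ²_e I is fitted by REML: K is
eigendecomposed once, the REML profile log-likelihood is maximized over
log δ (δ = σ²_e/σ²_g) by bounded scalar search on [1e-5, 1e5], and the
genotype factor is tested by an F statistic comparing weighted residual sums
of squares under the fitted covariance. With K = I the weights are constant
and the MLM F test reduces exactly to the GLM. Non-PSD kinship inputs are
bent by shifting eigenvalues up to zero, with a warning. The IBS kinship is
the mean shared-allele fraction 1 − d/2 over SNPs non-missing in both
samples (d = allele-count difference of dosages); this is the chosen
convention since IBS scalings differ slightly between tools. Chip QC drops
SNPs with MAF ≤ 0.05, call rate ≤ 0.90 or HWE P < 1e-5, then animals with
call rate ≤ 0.90. Bonferroni correction is min(1, m·p) with m the number of
SNPs actually tested, passed explicitly in reports.

## Classification rules

Class I requires a tested association with Bonferroni-corrected P < 0.05
(the conventional experiment-wide level; the source analysis reports its
significant corrected P without stating α). Class II requires the mutant
homozygote to be missing, the mutant allele observed (MAF > 0), and the
allele non-private (seen in more than one breed). Everything else — private
variants, monomorphic validation sites, and variants with all three
genotypes but no significant association — is class III. The three rules
partition any input; variants never tested for association can be II or III
but not I.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design at its published sample sizes: an
11-horse detection panel, a 337-stallion cohort over 19 breeds dominated by
226 Hanoverians of which 216 carry breeding values, phenotypes standardized
to mean 100 and SD 20 with mean reliability 0.7. Planted variants are placed
by searching a gene for a position where a single substitution yields the
requested category (verified by the classifier itself), then given an exact
panel genotype pattern; negative controls (database-known sites, sites with
a homozygous carrier, low-impact sites) exercise each filter. Cohort
genotypes are drawn per breed from inbreeding-adjusted frequencies
(p² + Fpq, 2pq(1−F), q² + Fpq); F = 0 gives Hardy–Weinberg. Chip genotypes
induce paternal half-sib families: each offspring receives one allele from a
family sire and one from the breed pool. Phenotypes are
y = 100 + Σβ·dosage + u + e with cov(u) = h²σ²K (K the realized IBS of the
chip) and var(e) = (1−h²)σ², then standardized to exactly mean 100, SD 20.
All randomness flows from a single seed through per-stage generators;
outputs are byte-identical across runs.

The default chip has 2,000 SNPs rather than the ~46,000 of a real
medium-density array: IBS estimates from 2,000 independent SNPs are already
precise to ~0.01, which is ample for the kinship covariance, and it keeps
the full workflow fast. The generator makes no attempt at linkage
disequilibrium, recombination maps, genotyping-error models or realistic
site-frequency spectra, so passing tests demonstrate the correctness and
calibration of the statistical machinery under the assumed model — not
robustness to the messiness of real sequencing data, nor the discovery
counts of any real cohort (those depend on real genomes that are not
shipped).

## Numerical and design choices

- Multi-allelic VCF records are dropped, not split; genotype phase is
  discarded on input. Coordinates are 1-based closed everywhere.
- Known-site matching is allele-aware by default when the source lists carry
  alleles; position-only rows match any allele. A position-only mode is
  available since database exports vary.
- The bundled validation table is published summary data (genotype counts,
  breed counts, one association P) used as pipeline input; nothing in the
  package derives these numbers from raw data.
- Simulation-based tests use scaled problem sizes chosen for precision per
  unit time: 1,000 null sites for mixed-model calibration, 2,000–3,000
  replicates for type-I-error checks, 6–10 replicates for variance-component
  and r² recovery where the mean over replicates is the quantity under test.
- Degenerate inputs: monomorphic association sites are flagged untestable
  rather than given a P-value; kinship pairs with no shared non-missing SNP
  are NaN and rejected if they reach the mixed model; empty chips or cohorts
  raise immediately.

## Known limitations

Single transcript per gene (no canonical-transcript election, no
multi-transcript ranking); SNVs only; no exact HWE test (the chi-square is
anti-conservative at very low expected counts — visible in the published
values themselves); the mixed model fits one variance ratio per site rather
than a genome-wide null (EMMA rather than EMMAX convention, fine at
candidate-gene scale); de-regression of breeding values is taken as given
and not implemented.
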
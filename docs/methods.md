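# Methods

`kaspanel` implements the computational side of building a KASP-based SNP
fingerprinting system for a crop germplasm collection: screening candidate
SNPs out of resequencing-derived variant calls, designing the allele-specific
PCR assays, characterizing marker diversity, inferring collection structure,
selecting a minimal discriminating marker set and a diversity-maximizing core
collection, and emitting per-accession fingerprint barcodes. This note
records the models, parameter choices, numerical decisions, and the limits of
what the synthetic-data tests demonstrate.

## Synthetic panels

Because real genotype tables of this kind are typically distribution-
restricted, every stage is exercised on simulated panels drawn from the
admixture model:

- each of K ancestral populations has per-locus alternate-allele frequencies
  P_kj ~ Beta(a, b); the default Beta(0.2, 0.2) concentrates mass near 0 and
  1, i.e. strongly diverged populations;
- each sample's ancestry vector Q_i ~ Dirichlet(α, …, α); the default
  α = 0.05 yields near-pure accessions, which matches how germplasm
  collections with distinct subgroups behave under model-based clustering;
- the two allele copies at a call are independent Bernoulli(Σ_k Q_ik P_kj)
  draws (Hardy–Weinberg within ancestry), ref/alt bases are drawn uniformly
  from the 12 ordered base pairs, and calls are masked missing i.i.d.
  (default study-scale panel: N = 280 samples, L = 32 markers, 2% missing).

One master seed feeds a `SeedSequence` tree so each sub-stage is
independently reproducible. Optional truncation bounds on the Beta draw
produce mid-frequency panels (e.g. frequencies in [0.3, 0.7]).

What the simulator does **not** model: linkage disequilibrium (loci are
independent), assay-specific systematic failure (a plate that fails for one
primer pair fails for all samples — we model only i.i.d. missingness),
genotyping error, and null alleles. Tests passing on these panels therefore
demonstrate correctness of the algorithms under the admixture model, not
robustness to correlated real-world artifacts.

The toy VCF generator places sites with guaranteed spacing except for a
chosen fraction planted within 100 bp of a neighbor, and draws GATK-style
annotations (QD, MQ, MQRankSum, ReadPosRankSum, QUAL, depth) from
distributions comfortably inside the filter thresholds, with configurable
per-annotation fractions planted just past a threshold. Planted violations
are recorded so filter tests can require exact recovery.

## SNP screening funnel

Stages run in a fixed order, each consuming the previous stage's survivors:
annotation hard filter (fail iff a *present* annotation is below its bound;
QD < 2.0, MQ < 40.0, MQRankSum < −12.5, ReadPosRankSum < −8.0, all strict);
site filter with vcftools semantics (biallelic, minor-allele count ≥ 3,
minor-allele frequency ≥ 0.05, mean per-sample depth ≥ 4, QUAL ≥ 30,
non-missing fraction ≥ 0.5 with the boundary inclusive, as `--max-missing`
documents); flank isolation (a site survives only if no other variant of any
type lies within `flank_bp` on its chromosome — distance exactly equal to
the flank violates; clustered sites remove each other; the neighbor set is
the full raw variant list, not just surviving SNPs); a mid-frequency window
keeping alternate-allele frequencies in [0.30, 0.70] inclusive (stated as
"MAF 30–70%" in marker-development practice, but a minor frequency cannot
exceed 0.5, so the operative quantity is the alternate frequency); and even
chromosomal distribution.

`flank_bp` defaults to 100 with 200 available via configuration — both
conventions circulate and the choice materially changes survivor counts, so
it is a visible parameter rather than a constant.

Even distribution apportions the target count across chromosomes by largest
remainder proportional to candidate counts, with a minimum of one where
candidates exist (when the target allows), then picks positions within a
chromosome by greedy farthest-point selection: the first pick is the lowest
position (all choices tie on an empty selection and ties break toward lower
position), then each added site maximizes its minimum distance to those
already chosen. The procedure is fully deterministic.

## KASP assay design

Each assay is two allele-specific forward primers ending exactly at the SNP
(3′ base = allele), carrying the universal FAM tail `GAAGGTGACCAAGTTCATGCT`
or HEX tail `GAAGGTCGGAGTCAACGGATT`, plus one common reverse primer.
Candidate allele-specific lengths 18–30 nt are scanned on the forward strand;
common-primer windows are enumerated on the reverse strand downstream.
Candidates are ordered by smallest product, then longest primers, and the
first triple meeting all constraints is returned, making design deterministic
for a template. Constraints: product ≤ 120 bp, GC fraction < 0.60 and
melting temperature in [55, 62] °C for all three gene-specific sequences
(tails are excluded — they are universal and identical across assays). When
no triple qualifies, the failure report names the constraint that excluded
the most candidates.

Melting temperatures come from nearest-neighbor thermodynamics
(biopython's `Tm_NN`) at declared conditions — 50 mM Na⁺, 1.8 mM Mg²⁺,
0.2 mM dNTPs, 250 nM each strand, Owczarzy 2008 divalent correction —
centralized in `kaspanel.kasp.TM_CONDITIONS` so the choice is auditable.
No public Tm convention exists for this assay family; these are ordinary
qPCR-mix conditions.

Marker QC drops samples whose own missing rate exceeds 0.50, then judges
markers over the retained samples: missing rate > 0.20 and/or a single
genotype class among non-missing calls. The 0.20/0.50 defaults quantify
"high missing rate", which assay-validation reports rarely pin down; both
are configuration-exposed.

## Diversity statistics

Computed from genotype counts without assuming Hardy–Weinberg (PowerMarker's
convention), per marker: allele frequencies (two observations per diploid
call, missing excluded), MAF, gene diversity GD = 1 − Σp², observed
heterozygosity (fraction of non-missing calls heterozygous), and
PIC = 1 − Σp² − ΣΣ 2p²q² (Botstein), which for a biallelic locus caps at
0.375. Because published marker tables sometimes plot the major or the
alternate frequency under a "MAF" label, the panel summary emits `maf`,
`major_freq` and `alt_freq` as separate columns rather than guessing.

## Distances and trees

Distances between single accessions use per-individual "allele frequencies"
(1 / 0.5 / 0 by genotype class) — the only frequencies computable from one
diploid genotype, and the convention PowerMarker applies for individual-level
Nei (1983) DA. Loci missing in either member of a pair are skipped and the
divisor is the shared-locus count (pairwise deletion; no imputation).
Alongside DA, the modified Rogers and Cavalli-Sforza–Edwards distances are
Euclidean forms on frequencies and root-frequencies respectively; both reach
exactly 1 between opposite fixed homozygotes.

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion; ties join the lowest index pair, so output is deterministic.
Additive matrices are recovered exactly (tested to 1e−9 against the
generating tree and against scikit-bio's implementation). Negative
branch-length estimates are clamped to zero and the clamped total logged;
Newick output renders lengths with 6 significant digits and quotes labels
containing metacharacters.

## Population structure

The model-based clustering stage fits the admixture likelihood

    LL(Q, P) = Σ_ij g_ij ln f_ij + (2 − g_ij) ln(1 − f_ij),  f = Q P

over a range of K by EM block updates, missing calls excluded. P is clipped
to [1e−6, 1 − 1e−6]; the log-likelihood is asserted non-decreasing at every
iteration; convergence is |ΔLL| < 1e−4.

Initialization matters more than is commonly appreciated at this panel size:
from uninformative random starts, single EM runs routinely converge with one
true cluster split and another lost, which biases the whole model-selection
curve. Each replicate therefore draws several (default 12) candidate starts
with P anchored on the genotypes of K samples spread k-means++-style across
the panel, advances each a short burn (40 iterations), and continues only
the best to convergence — a standard short-run EM strategy. Replicate fits
(default 10 per K) remain independent and seeded.

Model selection uses the Evanno ΔK statistic on the replicate
log-likelihoods: ΔK = |mean_L(K+1) − 2 mean_L(K) + mean_L(K−1)| / sd_L(K)
over interior K, argmax wins, ties prefer smaller K. Two numerical guards:
K values whose replicate sd is exactly zero are flagged and excluded, and
the denominator is floored at 1.0 log-likelihood unit. The floor matters
because deterministic optimizer replicates that agree on an optimum differ
only by termination noise (sd ~1e−3), and dividing genuine curvature by that
noise manufactures spurious peaks; genuine replicate disagreement is tens of
log-likelihood units, far above the floor. `sd_floor=0` restores the raw
statistic.

On study-scale panels (280 × 32, 8 populations, α = 0.05, Beta(0.2, 0.2)),
ΔK selects K = 8 in 9 of 10 independent panels (the exception is a draw
whose likelihood curve genuinely bends harder at K = 3). Per-sample ancestry
recovery at these conditions is information-limited: the ML fit assigns
>90% of samples to their true cluster, with a median row-wise max error of
~0.09 — 32 biallelic loci cannot pin a pure sample's ancestry vector exactly
to a vertex.

PCA operates on the dosage matrix with per-column mean imputation of missing
entries, centering, and Patterson scaling by √(p(1−p)); zero-variance
columns are dropped with a warning, and component signs are fixed so each
component's largest-magnitude loading is positive.

## Minimal discriminating markers

A marker resolves a sample pair iff both calls are non-missing and the
genotype classes differ — a missing well is never treated as evidence of
difference. Selection is greedy maximum-coverage set cover: repeatedly add
the marker resolving the most currently-unresolved pairs, ties broken by
higher PIC then by (chrom, pos), stopping when no marker adds a pair. An
exhaustive enumerator (guarded to ≤ 20 markers) defines exact optima on
small instances; the greedy solution always attains the oracle's maximum
achievable pair coverage in randomized tests, with size within the classic
(1 + ln #pairs) bound. Residual unresolved groups are the connected
components of the "no chosen marker discriminates" relation; duplicate
*reporting* instead uses strict call-vector equality (missing is a distinct
symbol), mirroring how identical rows are read off a plate report.

## Core collection

The core of round(fraction·N) accessions (round half away from zero, so 20%
of 280 is 56) maximizes one of three objectives — mean entry-to-nearest-entry
modified Rogers distance (default), mean pairwise MR, or mean pairwise CE —
by greedy seeding from the most distant pair followed by steepest-ascent
swap local search with seeded random restarts. Swap evaluation is
incremental and vectorized, so study-scale selection takes seconds. With
coverage enforcement, any allele present in the collection but absent from
the core triggers a repair swap that inserts a carrier while avoiding
regressions of other alleles; on panels where every allele has a carrier,
the selected core attains 100% allele coverage.

Evaluation reports mean MR and CE among core entries, Shannon index (both
the per-locus mean, which caps at ln 2 ≈ 0.693 for biallelic loci, and the
across-loci sum — published tables are ambiguous about the convention, so
both are emitted), expected heterozygosity, effective allele number
(1/Σp² per locus), mean PIC, and allele coverage CV as a percentage.

## Fingerprints

A fingerprint is the ordered string of genotype symbols over a marker panel,
markers sorted by (chrom, pos), heterozygotes alphabetized, no-calls `NN` —
injective on genotype vectors. The matrix rendering follows the conventional
orientation (rows = markers, columns = samples) with homozygotes colored by
base pair (AA yellow, CC green, GG blue, TT purple), heterozygotes gray,
no-calls white; the plot collapses heterozygote identity but the sidecar TSV
retains the full symbols.

## Problem sizes

Tests and the acceptance script run at the study-scale defaults chosen for
the synthetic panels: 280 samples × 32 markers for structure, core-marker
and core-collection stages (the structure scan fits K = 2..10 with 10
replicates each); screening fixtures use a few hundred simulated sites over
12 chromosomes. These sizes keep every property checkable in minutes on one
CPU while matching the data scale the workflow targets.

## Known limitations

- Distances between single accessions use genotype-class frequencies; they
  are not population-level frequency distances, and no missing-data
  imputation is offered.
- The EM replaces MCMC: no admixture-prior inference (α is a simulation
  input, never estimated), no credible intervals, and replicate spread
  reflects optimizer restarts rather than posterior sampling.
- Greedy set cover is not guaranteed minimal in size (only within the
  logarithmic bound); the exact enumerator is exponential and guarded.
- Assay design scores candidates only by product size, primer length, GC and
  Tm; secondary structure, primer-dimer and specificity screening are out of
  scope.
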
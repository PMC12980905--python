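# Methods

This note documents the models, defaults and numerical choices behind
`crcrelapse`, and what the synthetic cohort does and does not emulate.

## Study design emulated by the synthetic cohort

Each synthetic patient carries eight samples: one archival FFPE primary
(P_A), three metastasis samples (L_A, L_B, L_C), three relapse samples
(LR_A, LR_B, LR_C) and a matched normal. Defaults (all exposed as
parameters):

| parameter | default | rationale |
|---|---|---|
| mean depth | 450x | exome coverage of the motivating design |
| liver purity | U(0.4, 0.8) | typical fresh-frozen CRLM tumor content |
| primary purity | U(0.2, 0.5) | FFPE archival material runs lower |
| mutations per clone | Poisson(110), min 8 | yields ~300 present mutations per liver sample, matching the reported per-sample burden (mean 317 ± 124) |
| FFPE artifacts | 20 per primary | C>T-context false positives, primary-only |
| clones per patient | 5 | truncal clone + scenario scaffold + one extra |
| segments | 20 over 5 chromosomes, 10 Mb each | desk-scale shared segmentation |
| cohort | 9 patients, 3 per scenario | mirrors the motivating cohort size |

### Seeding scenarios

Relapse is seeded by a single clone, so the relapsing clone — and every
ancestor of it — is clonal (phi = 1) in all relapse samples. This is not a
free parameter: if the relapsing clone were subclonal in the relapse, the
relapse would have a more recent common ancestor, contradicting
single-clone seeding. Three scenarios differ in where that clone lived
before the relapse:

* **shared** — the relapsing clone is present in exactly one metastasis
  sample at majority fraction (phi ~ U(0.55, 0.85); a clone that seeds a
  later relapse from within a resected metastasis is modeled as locally
  dominant, which also makes its copy-number events visible in the rounded
  bulk profile of that sample);
* **private_sequential** — the relapsing clone appears only in the relapse,
  but an ancestor spans all six liver samples while being absent from the
  primary (sequential dissemination through the first metastasis);
* **private_branchoff** — metastasis and relapse lineages are sibling
  branches under a primary-resident clone (independent seeding).

Additional clones draw their prevalences from the parent's unallocated
headroom, so the infinite-sites sum condition holds exactly by
construction. Extra clones outside the relapsing lineage never span all
three relapse samples, keeping the relapsing-clone definition unambiguous
in truth.

### Read counts, copy number, spectra, expression

Read depth is Poisson around the mean with a floor of one read; alt counts
are binomial at the purity/copy-number-adjusted expected VAF. Copy-number
truth is a per-branch event list in the same event model the phylogeny
module scores (segmental ±1 runs within one chromosome, zero absorption,
optional single WGD); each branch carries 0–3 random events, the relapsing
branch at least two plus an optional whole-chromosome major-allele gain
and/or a WGD. The observed per-sample profile is the cell-fraction-weighted
mean of clone profiles rounded to integers — the clonal rounding a caller
reports for a bulk sample. Mutation multiplicity exceeds 1 only when the
gain lies on the mutation's own branch (a gain on an ancestor branch
predates the mutation, which then arises on a single copy); in that case it
is drawn uniformly from 1..major.

Mutational spectra are clone-specific draws from a bundled synthetic
four-signature catalog (`clock_a`: deamination-like C>T at NpCpG;
`clock_b`: broad background; `fivefu`: fluorouracil/ROS-like T>G at NpTpT;
`flat`). The relapsing branch draws from `fivefu`, all other clones from
the clock-like columns. The catalog is synthetic by construction — shaped
like the corresponding COSMIC classes but not derived from them; real
COSMIC-format files are readable through the same interface.

Expression matrices are log-scale: per-gene baseline N(7, 1.5), within-group
noise SD 1 (so planted effects are in SD units), group shifts on designated
gene sets, and per-sample CMS-template signal (disjoint 25-gene marker sets
per class, weights U(0.5, 1.5), strength 2.5).

### What the generator does not emulate

Sequencing error and mapping artifacts beyond the FFPE C>T class; germline
variation; subclonal copy number within a sample (profiles are clonal
roundings); inter-mutation correlation along the genome; RNA count
overdispersion (expression is simulated directly on the log scale);
realistic human coordinates. Passing tests therefore demonstrate that the
analysis chain recovers truth under its own generative assumptions at
study-like depth/purity — not performance on real tumors.

## Pipeline stages and thresholds

All thresholds live in `PipelineConfig`: presence VAF 0.05 with ≥1 alt
read; deconvolution input needs >5 alt reads in ≥1 liver sample, depth ≥100
in all samples, non-primary-only, allele-specific copy number everywhere;
cluster retention >5 mutations and prevalence ≥0.2 somewhere; cluster
presence ≥0.1; tree slack epsilon 0.25; cluster-merge distance 0.1
(max-norm); ≤15 clusters; 100 restarts; ≤10 signatures; BH FDR 0.05.
Whether the depth rule includes the matched normal is a config switch
(default: tumor samples only, the conservative reading).

**CCF and clustering.** The point-estimate multiplicity op rounds
vaf/rho·(rho·CN + 2(1−rho)) and clamps to [1, major]. Inside the mixture
model, multiplicity is instead a latent per-mutation genotype (1..major,
capped per sample), profiled by maximum likelihood within the EM — fixed
rounding misassigns mutations whose clone is subclonal in every sample
(round(m·phi) collapses to 1, doubling the CCF). The M-step uses a
responsibility-weighted ratio estimator per (cluster, sample), clamped to
[0, 1]; K is selected by BIC with K·S + (K−1) parameters; ties in
assignment break to the lowest cluster index. Initialization is
k-means++-style seeding on the CCF matrix; the restart default is 100,
while the bundled drivers and acceptance runs use 5–10 restarts with ≤8
clusters — at these problem sizes the seeded EM converges reliably, and the
smaller setting keeps the full 30-patient sweeps within desk-scale
runtimes. Overdispersion (beta-binomial) is not modeled; at 450x simulated
depth the binomial likelihood is correctly specified.

The CCF clamp flag (raw estimate > 1.05) is informative for subclonal
mutations only: at 450x, a truly clonal mutation's raw CCF has noise SD
~0.06, so a sizeable fraction of clonal entries exceed 1.05 by chance. This
boundary effect is inherent to the flag definition, not a misspecification
signal.

**Clone trees.** Ancestry DAG: edge i→j iff phi_i ≥ phi_j − epsilon in
every sample. Tree score: total sum-condition overflow
Σ max(0, Σ_children − parent − epsilon); the branch-and-bound search is
exact (the partial score is monotone in added children) and tie-breaks to
the lexicographically first parent assignment. Epsilon plays the role the
error margin plays in lineage tools; here it is defined as the prevalence
slack in both the ancestry and sum conditions.

**Relapsing clone.** Candidates are clusters present in all relapse samples
and absent from ≥1 metastasis sample (an alternative reading requiring
presence in all non-metastasis tumor samples is available via
`candidate_rule="methods"`). The most ancestral candidate wins; ties go to
larger mean prevalence, then lower index. Primary samples participate in
tree building but not in the pattern logic.

**Sample trees.** Exhaustive enumeration of unrooted topologies (stepwise
addition), vectorized Fitch on binary presence characters, normal as
outgroup root. The normal contributes rooting but no score, so a mutation
present in every tumor sample costs zero changes. Feasible to 8 tumor
samples; an independent set-based brute force validates ≤5 leaves.

**Copy-number phylogeny.** The event model is defined by the BFS oracle:
events are ±1 over contiguous same-chromosome runs of one allele, valid
only when every segment in the run has ≥1 copy (so zero is absorbing in
both directions), plus an optional single WGD (cost 1, before all other
events). The closed form — per allele and chromosome, adjacent differences
of the gain and loss components, with infeasibility when a zero-copy source
segment has positive target — is proven equal to the oracle on the
exhaustive sweep of vectors up to 4 segments and values up to 3, including
doubled sources (the WGD route). Because non-WGD events touch one allele,
the joint distance decomposes per allele, so the single-allele sweep covers
the joint model exactly. Distances are symmetrized by the minimum of the
two directed costs; doubly infeasible pairs get a sentinel of 10x the
largest finite distance. Trees are neighbor joining (scikit-bio) over
lexicographically ordered samples, rooted at the diploid normal; an
all-zero matrix yields a star tree. Ancestral states are estimated per
segment and allele by minimum total |change| over the rooted tree (Sankoff
with candidate states from the leaves; the root is anchored by the normal
leaf, not pinned), a stated simplification relative to joint
reconstruction; the branch event list is the minimal decomposition of the
parent→MRCA difference, with the WGD reported as one event when it strictly
reduces the count, and is replay-validated.

**Signatures.** Spectrum counting uses the stricter presence rule (VAF ≥
0.05 and more than one alt read); purine-centered substitutions map to the
reverse-complement channel; indels are excluded. Refitting is exact NNLS
with KKT verification, then a pruning loop that zeroes signatures below 5%
of total exposure and refits until stable. Presence = exposure fraction ≥
5%. Refitting to a fixed catalog stands in for de novo extraction: the
scientific claim under test — the treatment signature co-occurring with the
relapsing clone — is about attribution, not discovery.

**Expression.** Raw counts are normalized to log2-CPM; since ssGSEA, CERNO
and NTP are rank-based (ssGSEA and NTP exactly, CERNO through the ranking
statistic), results are invariant to any strictly monotone normalization,
which is what makes this substitution for variance stabilization safe. CPM
is a per-sample operation, so the per-patient and whole-cohort modes yield
identical values and differ only in grouping metadata and validation.
ssGSEA uses average ranks (descending) and weight rank^alpha, alpha = 0.25.
CERNO uses the published statistic F = −2 Σ ln(r_i/N) against chi-square
with 2|S| df; for sets that are a noticeable fraction of the gene universe
the statistic is mildly conservative (set ranks are drawn without
replacement), so calibration is checked in the |S| ≪ N regime (10 genes of
2,000) where the chi-square null holds. The per-gene statistic feeding
CERNO defaults to the signal-to-noise ratio (relapse minus metastasis,
descending); ranking by magnitude is available for two-sided screens.
Nearest-template prediction computes 1 − cosine between centered expression
and centered class weights over the union of all marker genes, with
permutation p-values from random same-size gene sets, BH across classes,
and unclassified when the best class misses the FDR level; genes are
centered across samples first (skipped for single-sample input).

## Problem sizes used by the bundled runs

The analysis drivers simulate 9 patients; the acceptance script runs 30
patients (10 per scenario) for pattern/prevalence recovery, the exhaustive
oracle sweep to 4 segments x values 3 (139,808 pairs), 36 tree-oracle
instances, 100 shared-scenario cohorts for signature co-occurrence, 30
noisy refits, 2,000 CERNO null simulations, 200 power simulations and 6
artifact-injection cohorts. These sizes were chosen so a full from-scratch
reproduction stays around a minute on one CPU while every estimate's Monte
Carlo error remains well inside the margins being asserted.

## Known limitations

* The binomial-mixture clustering is a desk-scale stand-in for
  beta-binomial tools; fidelity is assessed by truth recovery, not by
  concordance with any specific tool's posteriors.
* Segments are treated independently in ancestral-state estimation; linked
  events spanning segment boundaries are recovered as their per-segment
  projections.
* The sample-tree stage has no sequencing-error model; presence characters
  are taken at face value.
* CMS templates and immune gene sets bundled here are synthetic stand-ins
  shaped like the published resources; real marker tables (TSV/GMT) load
  through the same readers.
* Branch-level signature attribution (assigning spectra to tree branches
  rather than samples) is available only through cluster-assigned mutation
  subsets; the default attribution is per sample.
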
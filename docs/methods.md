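# Methods

## Scope and data model

`mesoclone` analyses multi-region tumour sequencing cohorts: per patient,
4-5 spatially distinct tumour regions and a matched normal, each region with
somatic SNV/indel calls (two-caller evidence), allele-specific copy-number
segments (major/minor, 0-based half-open coordinates), and a purity
estimate. Positions are 1-based at VCF boundaries and converted internally.
All randomised components accept explicit seeds and are bit-reproducible;
the pipeline derives per-stage seeds from one global seed by stable hashing
so stages stay decoupled.

## Variant filtering

SNVs pass when (a) called by both callers with somatic p <= 0.1 and VAF >=
2% in each, or (b) called by the VarScan2-like caller alone with VAF
strictly > 5%; the normal must have VAF < 1% and fewer than 5 alt reads;
blacklisted sites and variants above 1% frequency in any population database
fail. Indels require VAF >= 5%, somatic p <= 0.05, tumour depth > 50, tumour
alt reads > 10 and normal alt reads < 2. Boundary semantics ("no <2%" read
as inclusive, "greater than 5%" strict) are fixed and tested. Sites passing
in at least one region are force-called in the others when mapping quality
> 20 and VAF > 2%; force-calling is monotone (it only adds presence). A
purity sanity check compares the kernel-density mode of the VAF distribution
to purity/2 and excludes samples whose mode falls below 0.1.

## CCF estimation and clustering

Mutation copy number follows `n_mut = VAF (1/p)[p CN_t + CN_n (1-p)]` with
CN_n = 2 (autosomes only). Multiplicity is the maximum-likelihood integer in
1..major under a binomial read model with CCF fixed at 1; ties go to the
smaller state. CCF = n_mut/m, clipped to [0,1]; overshoot beyond 1.1 is
flagged inconsistent. The 95% CI propagates a Jeffreys beta posterior on the
VAF through the same relation (no CI method is standard here; this is the
package's choice).

Clustering uses a Dirichlet-process mixture of per-region binomials on
pseudo-counts `alt* = round(depth * CCF / 2)`, `ref* = depth - alt*` — the
reference transform corresponding to VAF = 0.5 x CCF at major/minor = 2/0
and purity 0.5 — with observed depths (the transform's depth convention is
not fixed by precedent; observed depth preserves per-site information).
Collapsed Gibbs sampling with Beta(1,1) base measure and concentration
alpha = 1.0 (configurable); the point estimate is the most-visited partition
after burn-in, ties broken by joint posterior. Rows are processed in a
canonical sort order so results are invariant to input order at a fixed
seed. Library defaults are 10,000 iterations / 1,000 burn-in; the pipeline
and benchmarks run 2,000/200 or less — at 250x depth the chain mixes within
a few hundred sweeps, and the planted-cluster benchmarks confirm ARI >= 0.9
at these settings. A cluster is clonal when its mean CCF is >= 0.9 in every
region (threshold configurable; no printed cutoff exists upstream).

## Clone trees

Trees are rooted at a germline (GL) node whose single child is the truncal
cluster. Enumeration walks all parent vectors over k clusters (exhaustive up
to k_max = 9) and keeps trees satisfying the sum rule in every region within
tolerance 0.05. On noisy data where no cluster clears the clonal threshold
everywhere, the pipeline roots at the cluster maximising its minimum
per-region CCF and doubles the tolerance (capped at 0.4) until a feasible
tree exists, falling back to a truncal star in the degenerate case. Observed
cluster means are projected onto each tree's sum-rule polytope by
least squares (SLSQP, per region); BIC = n ln(RSS/n) + q ln(n) with
n = clusters x regions and q = edges, constant terms dropped. An RSS floor
of 1e-8 absorbs solver round-off so exact fits tie exactly; ties resolve to
fewer edges, then the lexicographically smaller parent vector in the
cluster-table order. Topology is branched iff a non-truncal node has >= 2
children: a star branching only at the truncal MRCA is linear (trees without
subclonal branching), and a strict mode treating only chains as linear is
available for sensitivity.

SCNA event classes per region: loss (total < 2), CN-LOH (major 2, minor 0),
homozygous deletion (total 0), gain (total > ploidy), amplification (total
>= 2x ploidy); arm loss at >= 50% of arm length lost (configurable; only the
whole-chromosome figure is fixed by precedent), whole-chromosome loss at >=
60%; mirrored subclonal allelic imbalance (MSAI) when the same interval has
minor = 0 in two or more regions with opposite parental alleles lost
(requires phase labels, available from the simulator or mirrored-BAF input).
An event is clonal iff present in every region. Double hits are a
deleterious mutation plus overlapping minor = 0 loss, two distinct
deleterious mutations, or homozygous deletion; timing is clonal only when
every component is.

## Trajectories

Driver events (mutations and copy-number events over NF2, BAP1, FBXW7,
SETD2, LATS2, PTEN, CDKN2A and their loci; "LAST2" in the source vocabulary
is read as the LATS2 typo) map to tree nodes; SCNAs are assigned to the
cluster whose region presence/absence pattern is closest. Orderings: (GL, x)
for truncal drivers, (x, y) when x's node strictly precedes y's; co-resident
drivers stay unordered. The transfer re-fit restricts each patient to
candidate trees within 2 BIC units of its optimum, then alternates between
counting transitions cohort-wide and letting each patient (ascending id)
re-select the candidate with maximal support from the rest of the cohort
(BIC tie-break), to a fixed point or 10 iterations. Transitions in more than
three patients (count >= 4) are repeated. The evolutionary distance is the
Jaccard distance between ordering sets (the named quantity has no published
formula; Jaccard is the package's documented, swappable choice), clustered
by average-linkage hierarchical clustering cut at k (k is a required
parameter; default 5), labels ordered by mean event count so cluster 1 is
simplest. Jackknife stability drops 10% of patients per replicate (100
replicates by default; benchmarks use 50) and reports median within-cluster
co-clustering frequency. A depth-4 CART on binary driver profiles transfers
cluster labels to external cohorts.

## Selection and signatures

dN/dS is a counting estimator: observed non-synonymous/synonymous counts
normalised by expected site masses from the coding sequence, each site's
three alternatives weighted 1/3 under the uniform default (so L_non + L_syn
equals the CDS length) or by a pluggable trinucleotide rate model. This
replaces the full covariate/negative-binomial machinery of the reference
tools — the target quantity is the normalised ratio. Significance is a
conditional binomial test of n_non against L_non/(L_non + L_syn), BH
correction across genes; n_syn = 0 yields an infinite, flagged ratio with a
finite exact CI. Signature fitting classifies substitutions into the 96
pyrimidine-strand trinucleotide channels and solves non-negative least
squares against a signature matrix (columns are probability vectors),
renormalising exposures to sum <= 1; samples under 50 mutations are
excluded. A 5-signature toy basis ships for tests and demos; real analyses
supply a reference matrix. Clonal/subclonal comparisons pool mutations per
patient.

## Immune evasion

Neoantigen candidates (8-11-mers with externally predicted affinities) are
kept at mutant affinity < 500 nM with normal coverage >= 5x, normal VAF <=
2%, tumour coverage >= 10x and tumour VAF >= 10%; wild-type/mutant fold
change > 2 flags priority. Burden counts one neoantigen per source mutation,
split by clonality. HLA LOH per gene: log2 depth ratios (+0.5 haldane
offset) at >= 5 mismatch positions between the two alleles, two-sided paired
Wilcoxon signed-rank against zero; LOH iff p <= 0.01 and median |log ratio|
>= 0.3. The upstream "PVal_unique" rule is internally inconsistent as
printed, so this paired test plus effect-size floor is an explicit
interpretation; the floor suppresses trivially significant sub-0.3 shifts at
very high depth. Patient-level LOH is any positive region/gene.

## Survival and association statistics

All tests are two-sided. Mann-Whitney U uses exact enumeration at pooled
n <= 12 without ties, else the tie-corrected normal approximation. Fisher's
exact test reports the sample odds ratio ad/bc (infinite when bc = 0) with
the conditional exact CI. Survival uses Kaplan-Meier curves and the
Mantel-Cox log-rank test; the hazard ratio defaults to a Cox
proportional-hazards fit — the score-based Mantel-Haenszel estimator
exp((O-E)/V) is available by flag and serves as the automatic fallback when
the Cox fit does not converge (tiny or fully separated groups), but its
sampling distribution is visibly wider and upward-shifted at hazard ratios
near 2 (measured in the recovery benchmark), so it is not the default.
Shapiro-Wilk gates mean (Welch) versus median
(rank-based) comparisons. NLR and PLR are the plain count ratios.

## The simulator

`simulate_cohort` emulates the study design: 22 patients, 4-5 regions, mean
depth 250x (Poisson per site), purity uniform on 0.3-0.9 (one estimate per
patient), 86-204 mutations per patient with roughly half truncal. Clone
trees are uniform over rooted labelled trees (rejection sampling of parent
vectors); per-region CCFs come from recursive Dirichlet stick-breaking down
the tree, which guarantees the sum rule by construction, with each subclone
absent per region with probability 0.3 (the spatial mixing model of real
multi-region sampling is unknown; this presence/absence model is a
documented free choice) and at least one absence forced when k >= 3. Reads
invert the copy-number relation: alt ~ Binomial(depth, p*m*CCF/(p*CN_t +
2(1-p))); the normal sample uses a 0.1% error rate (configurable; no error
model is prescribed upstream). Five driver archetypes (C1 simplest .. C5
most complex) fix which drivers are truncal versus late on a simplified
autosomal genome (real-scale coordinates for BAP1/3p21, FBXW7/chr4,
CDKN2A/9p21.3, NF2/22q, PTEN/10q23, LATS2); survival is exponential with
archetype-specific hazards (C5 at ~4x the baseline) censored at 5 years; HLA
coverage gives LOH patients an allele-imbalance proportional to purity.

What the simulator does not emulate: read-level artefacts (mapping error,
strand bias, FFPE damage), germline variation, subclonal copy number,
kataegis or realistic trinucleotide context (contexts are uniform),
inter-region purity variation, and clinical covariates beyond blood counts.
Passing recovery benchmarks therefore demonstrates correctness of the
estimators under the stated read model, not robustness to artefacts real
callers face.

## Benchmark problem sizes

The calibration benchmarks (also run by `scripts/acceptance.py`) use: the
full 22-patient cohort for CCF recovery (DP Gibbs at 300 sweeps / 50
burn-in; the estimate consumed is the cluster-mean CCF, whose error is far
below the single-site binomial noise floor); three planted 3-cluster
cohorts of 60 mutations at 2,000/200 sweeps for clustering ARI; 100 random
instances (k = 3..6) for the enumeration-vs-brute-force check; 50 planted
identifiable 3-cluster trees at 250x for tree recovery; 10,000 neutral
mutations plus a 20-gene panel with three 2x-enriched genes at 500
mutations/gene for dN/dS; a 25-patient 5-archetype cohort with 50 jackknife
replicates for trajectory stability; 100 power and 1,000 null simulations
for HLA-LOH; and 100 replicates of 200-per-arm exponential survival for
hazard-ratio recovery. These sizes were chosen so each benchmark's Monte
Carlo error is small relative to the threshold it is checked against.

## Known limitations

* The DP cluster point estimate is the modal partition; for weakly separated
  clusters the mode can understate uncertainty — inspect the co-clustering
  tallies for sensitivity.
* Tree enumeration is exhaustive and limited to 9 clusters; larger instances
  need a heuristic search that is out of scope.
* Mutations in subclonal copy-number segments use the region's local segment
  copy number; mutation-SCNA phasing is not resolved.
* The external-input (non-simulated) pipeline path is exercised through the
  per-stage CLI verbs and library functions rather than `run-all`.
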
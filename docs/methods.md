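# Methods

`pahpheno` predicts the metabolic phenotype of phenylketonuria — classical
PKU (cPKU), mild PKU (mPKU) or mild hyperphenylalaninemia (MHP) — from a
patient's pair of PAH alleles, written as HGVS cDNA labels. This note
documents the model, the numerical conventions, the synthetic data the
package is validated on, and the choices made where the design was open.

## Phenotype definition

Phenotype is defined from pretreatment blood phenylalanine (µmol/L):
cPKU above 1200, mPKU between 600 and 1200, MHP from 120 up to 600. The
literature prints the two milder intervals with shared endpoints; we
resolve the boundaries so every value gets exactly one label: mPKU is the
closed interval [600, 1200], cPKU is strictly above 1200, MHP is
[120, 600). Values below 120 µmol/L are not hyperphenylalaninemia and are
rejected rather than silently binned; table readers in lenient mode skip
such rows with a logged reason.

## Structural features (7 per mutation, 14 per genotype)

Each allele is summarised by seven real numbers: scaled cDNA position,
reference and alternate nucleotide codes, reference and alternate
amino-acid codes, the signed exon/intron index, and a variant-kind code.
The concrete codes are a declared convention (`EncodingScheme`,
serialisable to YAML): nucleotides A,C,G,T → 1–4 with 0 for "none";
amino acids 1–20 alphabetically by one-letter code, stop → 21, sentinel
"no consequence" → 0, frameshift/indel → −1; kinds substitution=1,
deletion=2, insertion=3, duplication=4, delins=5, other=6; position
divided by 1500 (≈ the PAH coding length) so it lives on a scale
comparable with the categorical codes. Only injectivity of the codes
matters — tree ensembles, the default learner, are invariant to any
monotone recoding; the values are configurable and recorded with every
run so results reproduce bit-for-bit. Multi-base events use the first
affected base for the nucleotide codes, keeping dimensionality fixed.

Amino-acid consequences are derived by codon translation when a coding
sequence is supplied (Biopython's translation table); exonic
substitutions yield the reference/mutated residue, indels yield
frameshift sentinels, and an absent coding sequence degrades to sentinel
codes with a warning rather than failing. The bundled exon map is the
canonical 13-exon PAH coding-coordinate structure (CDS 1359 nt); users
can override it with a TSV because published cohorts occasionally use
other transcripts. Intron numbering follows the standard convention: a
negative offset anchored on the first base of exon k lies in intron k−1,
a positive offset after exon k lies in intron k.

## Graph features (8 per mutation, 16 per genotype)

All mutations observed in a cohort form a weighted undirected network:
an edge joins two mutations when at least one patient carries them as a
genotype, weighted by the patient count and annotated with per-phenotype
counts. Homozygous genotypes are kept as self-loops for the weight and
hub bookkeeping but never contribute to paths or centralities (a
mutation is not its own neighbour).

Per mutation the features are the unweighted shortest-path distances to
the three phenotype hub nodes plus five node attributes: degree
(distinct neighbours), normalised node betweenness, PageRank (damping
0.85, weighted), closeness and eccentricity. Betweenness is computed per
node although the quantity is sometimes described per edge; what is
wanted is how often a mutation sits on shortest paths, which is node
betweenness — an incident-edge-sum variant is provided for comparison
(`incident_edge_betweenness`). Closeness and eccentricity are computed
within a node's connected component (closeness is (k−1)/Σd over the k
reachable nodes). Distances are hop counts; edge weights are used only
by PageRank and hub scoring, since there is no principled length
interpretation of a co-occurrence count. A hub unreachable from a node
gets a finite sentinel — one hop beyond the largest finite eccentricity
in the network — so feature vectors never contain undefined values while
remaining ordinally "farther than anything connected". The PageRank
solver is run to a summed-error tolerance of 1e−12, comfortably tighter
than the 1e−9 per-node agreement the tests guarantee against a
power-iteration oracle.

Hubs — one classification-centre mutation per phenotype — are the nodes
maximising the *phenotype-weighted degree*: the number of patients of
that class whose genotype involves the mutation (self-loops counted
once). Ties break by total degree, then canonical mutation order. The
original hub selection in the literature was done interactively in a
network viewer without a stated metric; phenotype-weighted degree is our
declared surrogate, and an override lets a run pin any hub trio.

## Classification and evaluation

The three-class problem is decomposed one-vs-rest. Features are the
14-dim structure vector, the 16-dim graph vector, or their 30-dim
concatenation (structure first). The default learner is a random forest
with 500 trees, unlimited depth and a fixed seed; AdaBoost, gradient
boosting, Bernoulli naive Bayes and k-nearest-neighbours are available
for comparison. Hyperparameters beyond these are scikit-learn defaults,
exposed through the algorithm registry and recorded in the model
bundle's fingerprint.

Evaluation uses stratified tenfold cross-validation. Out-of-fold scores
are pooled into a single ROC (threshold sweep over unique scores, AUC by
trapezoid); per-fold AUCs are also retained so a fold-averaged reading
is available. The reported operating point maximises Youden's J. A
stratified 80/20 split provides an independent hold-out evaluation. The
package's AUC equals the Mann–Whitney pairwise statistic (ties counted
half), which the tests verify to 1e−12 against an exhaustive pairwise
oracle.

Multiclass prediction normalises the three positive-class probabilities
to sum to one and takes the argmax, breaking exact ties toward the more
severe class — when evidence is balanced, the clinically conservative
call is the severe one. Published reports of this kind of model do not
state their combination rule; this one is declared and tested.

## Synthetic cohorts

The generator reproduces the three statistical signatures of real PAH
cohorts that the method relies on:

* **Hub-dominated allele frequencies.** Allele ranks follow a Zipf law
  (exponent 1.2 by default), so a handful of mutations dominate and the
  co-occurrence network has one giant component — matching cohorts where
  nearly all mutations are connected.
* **Bimodal allele severity.** A latent severity s ∈ [0,1] per mutation
  is drawn from a two-component Beta mixture (Beta(8,2) "severe" with
  weight 0.7, Beta(2,8) "mild"), reflecting the split between near-null
  alleles and alleles with residual enzyme activity. The three most
  frequent alleles are designated hubs with pinned severity ranges —
  severe (0.70–0.95), intermediate (0.40–0.52), mild (0.05–0.20) — which
  both stabilises cohort composition across seeds and mirrors the
  observed phenomenology: the severe hub anchors cPKU, the intermediate
  hub yields mPKU when paired with severe alleles and MHP when paired
  with mild ones, and the mild hub forces MHP with any partner.
* **Milder-allele dominance.** Genotype severity is min(s_a, s_b): the
  allele retaining more activity sets the phenotype. Mean Phe is the
  monotone map 120 + 2880·s^1.5 µmol/L (spanning 120–3000), multiplied
  by mean-preserving lognormal noise (σ = 0.25 by default, the scale of
  biological plus assay variability in a positive right-skewed
  biomarker) and truncated at 120.

Defaults are 1291 patients and 235 mutations, giving a class split of
roughly 43/21/36 percent across seeds, close to the ~49/23/28 split of
large screening cohorts. Signal-recovery checks use 1200 patients, 200
mutations and σ = 0.1 — sizes chosen so a tenfold random-forest CV is a
desk-scale computation — where combined-feature CV AUC is ≈ 0.97–0.99
per class and collapses to ≈ 0.5 under label permutation.

What the generator deliberately does *not* model: Hardy–Weinberg or any
population-genetic structure, linkage between alleles, the real PAH
allele spectrum (synthetic labels are random substitutions), mutation
class diversity in frequencies (indels are rare in the synthetic pool),
or genotype–Phe relationships more complex than a monotone map of the
milder allele's severity. Passing tests on synthetic cohorts therefore
show that the pipeline recovers the signal *its own generative model*
encodes, not that the clinical AUCs of any published cohort are
reproduced; those depend on clinical data this package does not ship.

A fixed worked cohort of 41 hand-designed patients over 17 real PAH
mutation labels accompanies the generator. It is constructed so that
hub identification returns the trio familiar from East-Asian cohorts
(c.728G>A for cPKU, c.721C>T for mPKU, c.158G>A for MHP), the network is
a single component, and every genotype containing c.158G>A is MHP.

## Degenerate inputs and edge cases

* Unsupported HGVS classes (inversions, alleles-in-cis, extensions)
  raise an explicit "unsupported" error; nothing is silently misparsed.
* A mutation absent from the training network raises in strict mode; in
  lenient mode it is encoded with disconnection sentinels and zero
  centralities, and predictions proceed with a log message.
* Cross-validation refuses k larger than the smallest class and suggests
  a smaller k; ROC computation refuses single-class label vectors.
* An infeasible simulation configuration (e.g. a Phe map too flat to
  populate all classes) raises after a bounded number of attempts.

## Known limitations

* The seven structural code assignments are a documented convention, not
  a reconstruction of any particular published encoding.
* Hub selection by phenotype-weighted degree is a surrogate for an
  unstated interactive procedure; the override exists for exact
  replication of a published hub trio.
* Graph features are cohort-relative: retraining on a different cohort
  changes every centrality, so bundles must never mix encoders and
  models from different runs (the `ModelBundle` keeps them together and
  fingerprints the configuration).
* The mPKU class sits between the other two on a single severity axis,
  and one-vs-rest ROC for the middle class is intrinsically harder; on
  weak-signal cohorts its AUC degrades first.
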
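# Methods

## Co-occurrence model

The evidence unit is the abstract. A gene's profile is its binary
document-incidence vector over the corpus; two genes co-occur when one
abstract mentions both. The pair score is the cosine similarity of the
binary vectors, c(g,h) = n_gh / √(n_g·n_h), which is 0 exactly when the
genes are never co-mentioned and 1 exactly when their abstract sets
coincide. Scoring is done on binary incidence, not mention counts,
because only the binary form supports that interpretation of the
endpoints; mention-count cosine is available as an off-by-default option
(`cosine_matrix(..., use_counts=True)`). Pairs are stored unordered with
the canonical orientation gene_a < gene_b. Ranking is by score
descending, then joint-document count descending, then lexicographic pair
order; pairs tied with the rank-n cutoff are all returned and flagged
rather than truncated arbitrarily, so top-n lists are deterministic.
Network edges require score strictly greater than the threshold (default
0.1); an inclusive mode exists for sensitivity analysis.

## Gene recognition

Recognition is dictionary lookup over maximal alphanumeric tokens:
case-sensitive exact match for approved HGNC symbols, alias resolution to
the approved symbol, and an exclusion list applied at reporting time.
Case sensitivity is a deliberate policy — HGNC symbols are already
case-normalized, and case-insensitive matching floods results with
English homonyms (IMPACT, SET, CAT). Splitting on every non-alphanumeric
character makes hyphenated usages ("EGFR-dependent") match. The shipped
default exclusion list contains measurement acronyms common in
respiratory toxicology (CBF, TEER, LDH, PCR); it is a user-replaceable
input because false-acronym curation is corpus-specific. Both title and
abstract are scanned. Co-occurrence granularity is the abstract, not the
sentence.

## Corpus filtering

Journal impact-factor annotation matches on lowercased, trimmed,
whitespace-collapsed journal names with no fuzzy matching, so every match
is auditable. The retention filter keeps records with IF ≥ 3.0
(inclusive); records with no annotated IF are dropped and counted — the
filter's purpose is to restrict evidence to ranked journals, and an
unranked journal cannot satisfy it. Which IF edition to use is the
caller's choice via the supplied table.

## Curation replay

Human curation is consumed as a decision ledger: keep/discard verdicts on
abstracts (by pmid) or pairs, each discard carrying a coded reason
(low_if, false_acronym, irrelevant, non_hgnc, other). Replay order:
impact-factor filter (optional), abstract discards, pair discards, then
removal of pairs whose entire evidence vanished. Kept pairs retain their
original scores (computed on the pre-curation corpus) with evidence
restricted to surviving abstracts; rescoring after curation would change
the meaning of the published threshold. R-genes are the genes of
surviving pairs minus the seed genes. A-genes must carry at least one
reference. On assembly, categories overlap with precedence S > R > A and
duplicates within a list collapse with a warning, so category counts are
disjoint and total = |S ∪ R ∪ A| always holds. Merging two genesets
(e.g. two heavily overlapping key events) is an explicit user action, not
an automatic overlap rule — no defensible threshold exists for it.

## Validation

Expression matrices are consumed already normalized; normalization of raw
counts, batch correction and differential-expression fits are out of
scope. Genes are Z-scored across samples with the sample standard
deviation (n−1); zero-variance genes are dropped with a warning.
Clustering is agglomerative on pairwise Euclidean distances with Ward
linkage in the squared-distance convention (SciPy's `ward`, equivalent to
R's `ward.D2`); the two historical Ward variants differ, so the choice is
pinned by a test against exhaustive stepwise minimization of the
within-cluster variance increase on small point sets. Label agreement is
quantified by the adjusted Rand index (chance-corrected, expectation 0
under random labels) plus per-cluster purity. PCA is computed by SVD of
the centered samples×genes matrix; complete data are required (no missing
values, imputation out of scope). The default pipeline Z-scores before
PCA, mirroring the clustering preprocessing; centered-only PCA is
obtained by skipping `zscore_rows`. Component–covariate association uses
one-way ANOVA for categorical covariates and Spearman rank correlation
for continuous ones; single-level categorical covariates are skipped with
a warning. P-values are reported raw alongside Benjamini–Hochberg
adjusted values; the adjustment is additive information and no decision
in the package depends on it.

## Synthetic data

The corpus simulator is a topic block model: each document draws one
topic block uniformly; genes of that block are mentioned with probability
p_in, genes of other blocks with p_out, and genes outside any block with
the background rate q. Gene symbols are embedded as standalone
uppercase tokens in lowercase filler text, so dictionary recognition
recovers the planted incidence exactly and tests measure co-occurrence
statistics rather than tokenizer behaviour; an adversarial mode adds
lowercase homographs and an excluded acronym to exercise the NER policy
specifically. The expected cosine has a closed form under the model
(mentions conditionally independent given the topic), which for two
background genes reduces to q; a Monte-Carlo estimator with standard
error backs the closed form in tests. What the simulator does not
emulate: real PubMed language statistics, gene-symbol ambiguity beyond
the planted decoys, citation structure, or any correlation between
journal impact factor and content — conclusions from passing tests are
about the pipeline's arithmetic and policies, not about NER recall on
real text.

The expression simulator draws per-gene baselines ~ N(6, 1) on a
log-like scale with i.i.d. Gaussian noise (sd 1.0 by default), 10 treated
and 10 control samples in a 200-gene universe. The treated group's
geneset genes (25 by default) are shifted by δ (default 5·noise_sd, a
strong, clearly recoverable effect; δ = 0 gives the null). The optional
technical confounder is a standard-normal per-sample covariate adding
loading × value to a disjoint gene subset. Its defaults (50 genes,
loading 1.5) were chosen for identifiability of the planted factor
structure at this sample size: the confounder's total planted variance
(≈35 z-scored units) must sit clearly above the top sampling-noise
eigenvalues (Marchenko–Pastur edge ≈13 for 20 samples × ~125 noise
genes) and clearly apart from the treatment factor's variance (≈21), or
the PCA axes mix under rotation and "the confounder's component" stops
being a well-defined ground truth. Real RNA-seq confounders (mapping-rate
covariates and the like) are not Gaussian and not independent of the
biology; the simulation demonstrates that the association machinery finds
a separable planted factor, nothing more.

## Numerical choices and degenerate inputs

Cosine denominators are computed as √(n_g·n_h) in one square root, making
scores bit-identical to the document-set definition. The incidence
matrix sorts genes and pmids lexicographically, so results are invariant
to record order. Empty corpora, all-zero gene rows, genesets absent from
an expression matrix, all-constant matrices and single-level covariates
all fail fast or are dropped with logged counts, as documented on each
function. Problem sizes used by the test suite and the acceptance script
(1,000 fuzz corpora of ≤50 documents × ≤20 genes; Ward oracles on point
sets of ≤5; 100 simulation seeds per recovery scenario) were chosen as
the smallest sizes at which each property is meaningfully exercised, and
run in seconds.

## Known limitations

Abstract-level mining misses full-text evidence by construction.
Interaction direction and sign are not modelled. The curation ledger
reproduces human decisions but cannot originate them. Live literature
fetching is intentionally outside the core: all pipeline code consumes
offline corpora for reproducibility, and an online fetcher would be
optional glue producing the same record shape.
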
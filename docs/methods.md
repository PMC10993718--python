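# Methods

This note documents the models, parameter choices and numerical conventions
behind orthomap, and what the synthetic worlds used in testing do and do not
demonstrate about real data.

## Ortholog assignment cascade

The cascade resolves each source-species gene against an externally supplied
candidate table (in production a biomaRt-style export; here always a local
TSV with the same contract — live database clients are deliberately not part
of any default path, for reproducibility).  Tiers, in order:

1. **unique_db** — a single candidate is accepted without scoring.
2. **protein_align** — canonical protein sequences of source and candidates
   are globally aligned (Needleman–Wunsch, affine gaps) under BLOSUM50; the
   candidate with the highest raw score wins.  Where a sequence backend
   provides no canonical flag, the longest isoform stands in for the
   canonical sequence, with length ties broken by lexicographically smallest
   sequence — a deterministic and conventional proxy.
3. **nucleotide_align** — used when the source (or every candidate) lacks a
   canonical protein.  Both sides are consulted in the same category,
   falling through curated mRNA → curated ncRNA → predicted mRNA →
   predicted ncRNA; mixing categories across sides is intentionally avoided
   so scores stay comparable within a tier.
4. **levenshtein** — with no sequences at all, the candidate with the
   smallest case-sensitive symbol edit distance is chosen.  No distance
   cutoff is applied by default (an optional maximum exists), since even a
   distant symbol is preferable to discarding a curated database candidate.
5. **lowercase** — genes with *no* candidates are matched by
   case-insensitive exact symbol equality against the target universe.
   This tier exists chiefly for long noncoding RNAs, which are
   under-represented in ortholog databases but often share a symbol across
   species up to casing; it is not restricted to lncRNA biotypes by default
   (an option restricts it).

Ties at any scored tier break by the symbol edit distance, then by
lexicographic target id, making the whole cascade deterministic.

**Bijectivity.**  Independent per-gene resolution can map several sources to
one target.  A greedy pass resolves each contested target in favour of the
best claim — unique database hits first, then tier precedence
(protein > nucleotide > levenshtein > lowercase), then alignment score
(edit distance inverted), then lexicographic source id — and re-resolves
each displaced source against its remaining candidates, iterating until
stable.  Because a displaced source permanently excludes every target it
has lost, each iteration strictly shrinks some candidate set (or unassigns
a gene), so termination is guaranteed.  The iteration order over contested
targets is sorted, so the result is reproducible bit-for-bit.

**Direction.**  The source defaults to the human-style universe — mouse
nomenclature is rewritten into human symbols — but the direction is purely
a matter of which GTF is passed as which side.

## Alignment primitives

* Gap penalties default to `gap_open = 10`, `gap_extend = 4` (opening a gap
  costs 14, each further position 4), mirroring the defaults of the
  alignment routines common in this ecosystem; both are configurable.
* Nucleotide scoring defaults to `match = +1`, `mismatch = −1`.  Ambiguity
  codes score `p·match + (1−p)·mismatch` with
  `p = |S_a ∩ S_b| / (|S_a|·|S_b|)`, the standard expected-identity
  weighting over ambiguity sets.
* Candidates are ranked by **raw** score; a length-normalised similarity is
  available but off by default, since within one tier all candidates are
  scored against the same source sequence.
* Sequences are uppercased and `U` maps to `T` before nucleotide scoring.
* The optimised aligner and edit distance are backed by widely used
  implementations; both are verified exactly against independent
  brute-force dynamic programs (three-state Gotoh recursion; full-table
  edit distance) on hundreds of random pairs in the test suite.

## Annotation handling

Only `gene` features of an Ensembl-dialect GTF are read; `gene_name` falls
back to `gene_id`, `gene_type` is accepted as a synonym for `gene_biotype`.
"Predicted" genes are removed before assignment.  Since prediction status is
not encoded uniformly, removal is driven by (a) an explicit predicted flag
when the GTF source column marks prediction and (b) configurable symbol
patterns, defaulting to `^Gm[0-9]+$` and `Rik$` for mouse-style universes
and empty for human-style ones.  This is a declared convention, not a
reconstruction of any particular database release.

## QC, normalisation, harmonisation

Per-cell gates: detected genes within [300, 6 000], total counts within
[500, 15 000], mitochondrial percentage ≤ 5 — all bounds read strictly, so
boundary-equal cells are **kept**.  Mitochondrial genes are recognised by
the symbol prefixes `MT-`/`mt-` (configurable).  Normalisation is
`ln(1 + 10⁴ · x / cell_total)`; the constant follows the standard tutorial
default and is explicit in the interface.  Cell QC runs before gene
harmonisation; matrices are matched to the table by symbol (id-based
matching available), genes outside the table are dropped, target-side genes
are renamed to source symbols, and the merge takes the intersection of gene
sets in the first matrix's order with cell ids prefixed by sample.

## Integration metrics

The embedding is PCA (default 30 components, arpack, sign-fixed by the
largest-magnitude loading) of the top-2 000 dispersion-ranked highly
variable genes, z-scored and clipped at 10.  Clustering builds a k = 20
nearest-neighbour graph (self included), weights edges by the Jaccard
overlap of neighbour lists, prunes weights below 1/15, and runs Leiden
modularity optimisation (RB-configuration) at resolution 0.3 with a fixed
seed.

Components and conventions:

* **silhouette** — mean per-cell silhouette over the SNN clusters,
  Euclidean distances; rescaled to [0, 1] as `(s+1)/2` inside the
  bioconservation composite.
* **batch ASW** — per cell-type group, mean of `1 − |silhouette w.r.t.
  species|`; groups containing a single species contribute 1 (a group that
  only one species possesses cannot be "unmixed").
* **graph connectivity** — per group, the largest connected component of
  the group-induced kNN subgraph over the group size; singleton groups
  contribute 1.
* **PC regression comparison** — `Var_c(X) = Σ varexpl_i · R²(PC_i ~ c)`;
  the score is the relative drop of `Var_species` from the uncorrected to
  the corrected representation, clipped to [0, 1].  A covariate explaining
  no variance before correction yields 0 with a warning.
* **kBET** — chi-square goodness-of-fit of each sampled cell's k-neighbour
  species composition against the global composition; the score is the
  acceptance fraction at α = 0.05.  This is the neighbourhood-test form of
  kBET, not the original protocol's k-sweep — a documented simplification.
* **LISI** — per-cell inverse Simpson index of neighbourhood label
  probabilities under a Gaussian kernel calibrated per cell to perplexity
  30 (SNE-style binary search).  Medians are normalised so that higher is
  always better: iLISI (species) as `(med−1)/(L−1)`, cLISI (cell types) as
  `(L−med)/(L−1)`.
* **cell-cycle conservation** — `1 − |ΔVar_cc|/Var_cc(pre)`, clipped to
  [0, 1], with the cycle covariate supplied as metadata (synthetic worlds
  carry a known score; real data would use a standard score computed
  upstream) so the metric is testable without gene-list machinery.
* **isolated-label F1** — isolated labels are cell types present in the
  fewest batches; each is scored by its best cluster F1 across a sweep of
  Leiden resolutions (0.1–2.0).  When every label spans every batch, all
  labels are isolated by this minimum rule; the code warns and reports.
* **NMI** — arithmetic-mean normalisation; reported alongside the
  composites but not part of either.

**Composites.**  The species mixing score is the unweighted mean of
{batch ASW, graph connectivity, PCR comparison, kBET, iLISI, cell-cycle
conservation}; the bioconservation score the unweighted mean of {cLISI,
isolated-label F1, rescaled silhouette}; the total is
`0.5·SMS + 0.5·BCS`.  The within-composite weights are a declared choice
(configurable by passing component subsets); the 0.5/0.5 top-level
weighting is fixed.  Absent components are skipped and flagged rather than
imputed.

**Correction baseline.**  Full anchor-based integration is out of scope;
the built-in baseline subtracts, per gene and species, the species mean and
adds the global mean (genes absent within a species are left untouched
there).  This removes exactly the additive per-gene species offsets the
simulator plants, which is sufficient to demonstrate that the metric suite
responds correctly to correction.  Externally corrected embeddings can be
injected (`--corrected-embedding`) to evaluate third-party integrations.

## Synthetic worlds

The generator emulates the statistical structure the pipeline assumes:
conserved orthologs whose true pairing is decodable from sequence
(per-species divergence from a shared ancestor at rate 0.05 versus decoys
at 0.5 — margins so wide that recovery is deterministic at the default
lengths of 120 aa / 240 nt), species-specific symbol casing (uppercase vs
title-case, `MT-`/`mt-` for mitochondrial genes), scheduled sequence
withholding that forces known genes down to the nucleotide and Levenshtein
tiers, and candidate-free lncRNA-style genes for the lowercase tier.

Counts are Gamma–Poisson draws (negative binomial, mean 3, dispersion 2 —
shallow-coverage droplet scale) around per-cell-type programs shared across
species: 12 marker genes per type at 6-fold elevation, log-normal
per-species per-gene offsets (σ = 0.3), and a uniform [0, 1] cell-cycle
covariate scaling a tenth of the genes by up to 2×.  Default scale is 200
genes, 3 cell types, 100 cells per type per species (600 cells plus 7
planted QC violations) — sizes at which the full pipeline, including two
metric evaluations, runs in seconds while every statistic of interest is
far from its sampling noise floor.

Because 200-gene matrices cannot meaningfully face thresholds meant for
20 000-gene transcriptomes, each bundle carries QC thresholds derived from
its own expected detected-gene and total-count ranges (0.5×/1.3× and
0.3×/3× of the analytic per-type expectations; the mitochondrial gate stays
at 5%).  Violation cells are constructed arithmetically against those
thresholds to break exactly one gate each, with ≥5σ margins separating
genuine cells from every gate.

**What passing does not show.**  The simulator draws independent genes (no
gene–gene correlation, no UMI saturation, no ambient RNA or doublets), uses
additive species offsets rather than the complex nonlinear batch structure
of real cross-species data, and its sequence model is i.i.d. substitution
without indels or domain structure.  Perfect recovery and near-ceiling
mixing scores on these worlds certify the machinery — tier logic, conflict
resolution, bookkeeping, metric arithmetic — not performance on real
genomes, where candidate quality and sequence annotation drive results.

## Degenerate inputs and numerical conventions

Absence of a sequence is a value, not an error; all-zero cells abort
normalisation with a pointer to QC; empty gene intersections warn and
return empty matrices; single-label silhouette raises; single-batch iLISI
returns 0 and kBET 1; zero-variance covariates return the documented
neutral scores with warnings.  Every stochastic step (PCA solver, Leiden,
kBET sampling, simulation) takes an explicit seed, and repeated runs with
identical inputs produce byte-identical tables, matrix directories and
reports.

## Known limitations

* One species pair per table; many-to-many ortholog groups, synteny and
  tree-based inference are out of scope.
* The lowercase tier assumes symbol conventions differing only by case;
  species pairs with unrelated nomenclatures gain nothing from it.
* kBET and LISI are the simplified forms described above and may differ
  numerically from the original implementations on identical data.
* The species-centering baseline is linear; it is a reference point for the
  metric suite, not a substitute for anchor- or graph-based integration.
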
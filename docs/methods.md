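# Methods notes

This note records the scientific assumptions, parameter choices and
numerical conventions behind `scfamap`, at the level of detail a
maintainer or reviewer needs to judge what the package does and does not
claim.

## Pathway model and genotype calling

Butyrate and propionate biosynthesis are modelled as eight gene cascades
named by entry metabolite (Glu, Ace, Lys, 4-Ami for butyrate; Pro, Acr,
WWC, SP for propionate). Each cascade has a fixed roster of required
genes; a genome is called positive only when every required gene has a
homology hit surviving two filters:

1. **Keyword curation.** Free-text annotations for genes with notoriously
   ambiguous homologs (`bcd`, `but`, `ptb`, `hbd` by default) are matched
   against include/exclude keyword lists. Matching is case-insensitive
   substring matching — the minimal reading of "keyword criteria", chosen
   over regexes so that rule files stay trivially auditable. Genes without
   a rule always pass.
2. **Score cutoff.** A hit is retained iff its full-sequence bit score is
   at least `score_frac` (default **0.5**) times the *lowest* reference
   score among experimentally characterized model strains for that gene.
   The boundary value is retained (`≥`, not `>`). The full-sequence bit
   score is used rather than per-domain scores: it is the standard cutoff
   unit of tabular profile-HMM output and requires no domain bookkeeping.

The complete-gene-set requirement makes calls conservative: one missing
gene vetoes the pathway, and paralogs of a single gene can never produce a
positive call on their own.

**Single-pathway resolution.** Genomes complete for ≥2 pathways of the
same product are scored per pathway by the mean, over the roster, of
(best genome hit score ÷ mean model-strain score for that gene). The
top-ratio pathway wins; any pathway within `tie_margin` (default **0.1**,
dimensionless ratio units) of the top is retained as well. The margin
exists because genuine multi-pathway genomes occur in gut taxa and a
hard argmax would erase them; `tie_margin=0` forces exactly one pathway
per product (exact ties broken deterministically by registry order), and
`tie_margin=∞` disables resolution entirely. Butyrate and propionate are
resolved independently — a genome may carry one route for each product.

The shipped registry (`src/scfamap/data/pathways.yaml`) transcribes the
canonical enzymology of the eight routes, including the shared-gene
structure (terminal `but` shared by the four butyrate routes; `bcd` by
three of them; the methylmalonyl-CoA core `mcmA`/`mcmB`/`mce` by the two
succinate routes). `etfAB`, `acrC` and `mmdD` are excluded from rosters
because public database annotations for them are too inconsistent to
support presence calls; the exclusion list is config-driven so users can
revisit it. The model-strain scores in the shipped file are **synthetic
representative values** (the file header says so): the classifier consumes
only per-gene minima and means, so any consistent score set exercises the
same logic, but real analyses should substitute scores from an actual
profile-HMM search of characterized producers.

## Catalogs

Nucleotide gene sequences from pathway-positive genomes are deduplicated
at 100% identity ("nonredundant" read conservatively; no clustering
threshold is applied, and entries differing by one base stay separate).
Identical sequences merge with the union of source genomes. Entry ids are
deterministic (gene symbol + SHA-1 content hash prefix) so rebuilt
catalogs are stable references. The rplB catalog admits candidates with
homology scores ≥ **400** bits (boundary retained) — rplB, the 50S
ribosomal protein L2 gene, is near-universal and near-single-copy in gut
bacteria, which is what qualifies it as the genome-equivalent denominator.

## The abundance estimator

Per sample and pathway:

    P_genomes = [ Σ_genes (h_gene/l_gene) / l_pathway ]
                ÷ [ Σ_rplB (h/l) ] × 100

- counts are primary, mapped alignments only (secondary, supplementary and
  unmapped records are skipped), so a read contributes at most once;
- catalog genes with no reads contribute 0 (no imputation);
- all rplB entries pool into one community-wide denominator — there is no
  per-taxon rplB matching, consistent with treating rplB as a depth proxy;
- estimates above 100% are reported, never clipped: they are the expected
  signature of multi-copy pathway genes;
- a sample with zero rplB signal has *undefined* abundance and raises an
  error — it is never reported as 0, which would be a different claim.

**Shared-gene apportionment.** For a gene in k pathways with observed
count `h_o`, each pathway receives `h_o · Σh_s/Σh_m`, where `Σh_s` sums
the same sample's single-pathway gene counts for that pathway and `Σh_m`
sums them over all k pathways. Apportionment never pools across samples.
When `Σh_m = 0` the formula is undefined; the count is split equally among
the k pathways and a warning is logged. Equal splitting is the only
fallback that preserves count conservation without inventing evidence;
the warning keeps it auditable.

Under the single-copy assumption the estimator is, in expectation,
independent of pathway length and of uniform count rescaling, and equals
the carrier genome fraction; the acceptance checks verify all three
properties plus exact agreement (1e-12 relative) with an independent
plain-loop implementation.

## Community analysis

Validation is species-level (genome calls stand for their species; if
genomes of one species disagree, the species counts as predicted positive
and the disagreement is logged). "Producer" means ≥1 assigned pathway for
the product after resolution. Unknown phenotypes never enter TP/FP/TN/FN
rates. Species left ambiguous by resolution (≥2 assigned pathways of one
product) are excluded from validation by default, matching the logic of
keeping the confusion matrix interpretable; a flag re-includes them.
Taxon aggregation reports per-family/phylum species fractions
(species-denominated — the genome-vs-species denominator choice is
configurable only by pre-aggregating input tables) and abundance-weighted
producer shares; the four producer/neither shares partition classified
abundance exactly.

## Synthetic communities

`simulate.py` generates the study conditions the estimator assumes, with
one deliberate violation knob each:

| parameter | default | meaning |
|---|---|---|
| `n_genomes` | 60 | community size |
| `carriage` | Ace 0.12, Lys 0.04, Glu 0.02, 4-Ami 0.02, SP 0.11, Pro 0.04, Acr 0.01, WWC 0.01 | per-pathway carriage probability; ~20% butyrate / ~17% propionate carriers with Ace and SP dominant, as in gut strain collections |
| `multi_pathway_rate` | 0.02 | probability a carrier adds a second same-product pathway (creates genuine multi-pathway genomes and shared-gene ambiguity) |
| `gene_length_range` | 600–1800 bp | typical bacterial gene lengths |
| `rplb_length` | 830 bp | rplB length |
| `depth` | 0.5 reads/bp | mean sequencing depth at abundance 1 |
| `copy_number_violation_rate` | 0.0 | fraction of carriers with doubled pathway genes (drives estimates >100%) |
| `sequence_reuse_rate` | 0.25 | chance a genome reuses the gene's canonical sequence (exercises catalog dedup) |
| `abundance_sigma` | 1.5 | lognormal spread: long-tailed abundances, few species dominate |
| `unassigned_fraction` | 0.05 | community fraction not represented by any genome |

Read counts are Poisson with mean `abundance × length × depth` per catalog
entry (length-proportional recruitment); rplB is single-copy per genome.
Hit tables give carried genes scores at 80–110% of the mean model score
and interleave below-cutoff decoys plus high-scoring hits with
non-specific annotations, so both filters do real work; classification of
simulated tables recovers the generating truth exactly, which is a test of
the classifier, not of the generator.

What the generator does **not** emulate: read-level errors and mapping
ambiguity (counts are drawn, not aligned), overdispersion beyond Poisson,
strain-level gene gain/loss within species, horizontal transfer placing
pathway fragments in non-producers, and correlated taxonomic/abundance
structure beyond the family assignment heuristic. Passing tests therefore
demonstrate correctness of the arithmetic and calling logic under the
stated model — not robustness to mapper artefacts or annotation noise in
real data.

## Numerical conventions and degenerate inputs

- Oracle-equivalence tolerances: 1e-12 relative (estimator), 1e-9 absolute
  (count conservation).
- Ties in resolution break by registry order; catalog order is
  (gene, content-hash) — both make outputs independent of input ordering.
- Empty hit list → empty output; empty catalog → warning, not an error;
  zero rplB → error (see above); genome hitting no registry gene → profile
  with empty pathway sets.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; reruns are bit-identical. Manifests carry a wall-clock
  timestamp as provenance; reproducibility comparisons therefore ignore
  exactly that field.
- Problem sizes in the shipped checks (100 oracle fixtures, 1000
  apportionment cases, 50 recovery replicates, 500 oracle genomes,
  2000-species validation, 300-genome/40-sample community run) were chosen
  as the smallest sizes at which the stochastic assertions have comfortable
  statistical margins.

## Known limitations

- Pathway presence is metabolic *potential*, not flux: regulation,
  substrate availability and ecological context decide realized SCFA
  output.
- The 50%-of-minimum score cutoff is inherited from established practice;
  an additional empirical score-drop-off criterion is not modelled beyond
  making `score_frac` configurable, because it has no closed-form
  definition.
- Exact-identity deduplication means closely related alleles remain
  separate catalog entries; reads mapping ambiguously between them are the
  mapper's problem, not visible to this package.
- The count unit (reads vs read pairs) is whatever the upstream counter
  produced; the estimator is agnostic, but mixed units across samples
  would silently bias comparisons.
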
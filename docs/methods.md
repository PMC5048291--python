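# Methods

## Scope and data model

The pipeline analyses a cohort of samples with somatic missense variants
given in protein coordinates (1-based, matching mutation nomenclature such
as Q61R).  An *interface* is a set of contact positions of one protein
toward a partner (another protein, a small molecule, or DNA/RNA), each
position annotated with the contact types it makes; interfaces carry the
percent identity of the structural template they were derived from.  All
tables move as TSV (FASTA for sequences, JSON for catalogs and configs);
clinical tables use ICGC-style donor column names.

### Confidence tiers

Protein–protein interfaces are used only when the template identity is
≥ 70% (`high`); below that they are excluded outright rather than
down-weighted, because interface placement on remote protein templates is
unreliable.  Chemical and nucleic-acid binding sites are generally placed
correctly even on remote homologs, so they are retained down to 30%
identity (`medium_low`).  A variant whose stated reference residue
disagrees with the sequence is dropped with a logged warning rather than
an error — real variant tables contain isoform mismatches — while a
variant naming an unknown protein is an error.  A variant at a position
shared by two interfaces of the same protein counts toward both
interfaces' tallies; reports flag this convention.

## Pair-potential scoring

The scorer is trained from a table of (amino acid, contact type)
co-occurrence counts.  With a pseudocount (default 1) added to every cell
of the full 20 × n_types grid, joint and marginal frequencies give

    log_odds(a, t) = log2( f(a, t) / (f(a) · f(t)) )

A substitution ref→alt at a position with contact types T scores
`Σ_{t∈T} [log_odds(alt, t) − log_odds(ref, t)]`; the sign is the predicted
direction (negative disabling, positive enabling).  Scores are exactly
antisymmetric in (ref, alt) and additive along substitution paths, which
the test suite checks on random tables.  When several variants hit the
same (sample, interface), the combined effect is the **sum** of site
scores — a deliberate choice where a vaguer "combination" could be meant:
sums preserve the sign semantics and the algebraic properties above.
Contact-type alphabets are coarse by design (protein partners:
hydrophobic/polar/charged/aromatic; chemicals: metal/nucleotide
moiety/other organic; nucleic acids: four bases + backbone) so a
desk-scale contact table is trainable.  The trained values are this
package's own; downstream stages depend only on the sign convention and
additivity, not on any particular parameterisation.

## Background models and enrichment

Two permutation nulls preserve different aspects of the observed mutation
process:

* **BM1** — each substitution keeps its sample, protein, reference and
  alternate amino acid, and moves to a position of the same protein drawn
  uniformly among those bearing the same reference residue.  Per protein,
  the (ref, alt) multiset is conserved exactly, as are per-sample counts.
* **BM2** — each substitution keeps its sample and protein, moves to a
  uniform position, takes the reference from the sequence there and a
  uniform non-reference alternate.

"Perturbed" means ≥ 1 annotated interface event regardless of score
magnitude; the score is used for direction and profiles only (an optional
magnitude filter exists but is off by default).  For each interface the
background rate is estimated as

    Pr = (mean unique background samples with an event + 1) / (N + 1)

averaged over R shuffle replicates (default 10; R = 1 reproduces a
single-realization design).  The +1 pseudocount keeps Pr positive for
interfaces never hit in the background — without it the binomial test is
undefined — at the cost of a slight conservative bias (~1/N).  The
observed count c of unique perturbed samples is tested with the inclusive
upper tail P(X ≥ c), X ~ Binomial(N, Pr), computed via the survival
function; the inclusive tail is the standard enrichment convention.
q-values are Benjamini–Hochberg within each background model across all
tested interfaces in one batch; an interface is significant when q ≤ 0.01
in **both** models and c ≥ 20 unique samples (both configurable; 10 is the
conventional relaxed sample floor).  Results are ranked by c descending.

A *whole-protein* control mode annotates events on any position of either
partner of a protein–protein pair, quantifying what interface-level
resolution adds over gene-level counting.

### A property of BM1 worth knowing

BM1 redistributes a driver's variants only among same-residue positions.
If the protein is short (or the composition concentrated), each residue
class has few positions and a large fraction of shuffled driver variants
lands back on the interface, inflating the BM1 background for exactly the
interfaces that carry signal.  At realistic human protein lengths
(hundreds of residues) the effect is small; the enrichment benchmarks
therefore simulate 400-residue proteins.  On real data this makes BM1 the
stringent null for mutational hotspots at rare residues — intended
behaviour, not an artefact.

## Profiles and the differential screen

The fingerprint matrix crosses interfaces with cancer types (primary
tissue/histology label pairs): each cell holds the number of unique
perturbed samples and the median combined score (midpoint convention for
even counts, NA for empty cells).  Cell counts sum over types to the
interface's cohort-wide c.  The display subset takes the top 30 most
perturbed interfaces from each of the top 30 cancer types by sample count,
then retains those perturbed in ≥ 20 samples of at least one top type and
significant under both background models; ties break by (count desc,
interface id) for determinism.  When one protein binds several chemicals
at significant interfaces, the partner perturbed in the most unique
samples is marked primary; the rest stay in the full table.

Interfaces whose perturbation differs between cancers are screened with a
Kruskal–Wallis test on combined-score distributions across the cancer
types with ≥ 5 perturbed samples (NA with fewer than two qualifying
types).  The choice of test here is a stand-in — the analysis this mirrors
does not name one — and every output carrying it is labelled accordingly.

## Subtypes and mutual exclusivity

Samples are clustered on their interface score vectors (0 where
unperturbed) by hierarchical **complete-linkage** clustering.  The metric
is correlation distance (1 − Pearson) by default and the dendrogram is cut
at raw cophenetic height 0.9; the metric and the cutoff interpretation are
genuinely open choices, so both are config options and are recorded in the
run metadata.  Constant profiles, where correlation is undefined, are
placed at distance 0 from identical profiles and 1 from everything else.
Note that correlation distance is degenerate on two-interface profiles
(every centered vector is a multiple of (1, −1)); cluster on the densified
matrix over all interfaces.

Mutual exclusivity of two interfaces is the lower hypergeometric tail
P(X ≤ n11) of their co-occurrence count given the margins — a one-tailed
Fisher exact test pointed at under-representation only (a co-occurrence
mode exists, off by default).  Pairs are tested when each member is
perturbed in ≥ 20 unique samples pan-cancer, or ≥ 10 within a cancer type
for the per-type screen; by default only both-model significant interfaces
enter.  BH-FDR runs over the whole batch; significance is q < 0.1.  The
exact null probability of flagging an independent pair (15% marginal rates,
1000 samples) is 0.079 — under the nominal 0.1 because the discrete Fisher
p is conservative.

## Survival analysis

Samples join to donors by an inner join; donor rows missing any of
(age, sex, vital status, disease status, survival time) are dropped with a
logged count, and conflicting duplicate sample→donor mappings are an
error.  Alive donors are right-censored at last follow-up (deceased ⇒
event observed); times pass through in the input's units (days for
ICGC-style tables).  Group contrasts report: two-tailed Fisher exact p on
status (p = 1 with a warning on degenerate margins), two-sided
Mann–Whitney U on survival times (exact for small untied samples),
Kaplan–Meier curves with a multivariate logrank test, and a Cox
proportional-hazards fit (lifelines) with age, sex and cancer type as
covariates — cancer type enters as a categorical covariate rather than a
stratum, with dummy encoding against the first level and constant dummies
dropped.  Convergence failures are raised, never swallowed.  For contrasts
between two mutually exclusive interface groups, samples perturbed at both
are dropped with a logged count.  Across a batch of survival screens,
BH-adjusted q-values are reported alongside raw p.

## The synthetic-data generator

The generator provides every input with known planted structure:

* **Proteome** — i.i.d. sequences, uniform amino-acid composition by
  default (neutral for the shuffle nulls; configurable), lengths fixed or
  uniform in a range.
* **Contact table** — log-normal cell weights (σ = 0.6, total 100k), so
  the trained potential has log-odds of both signs essentially everywhere,
  which direction forcing requires.
* **Catalog** — interfaces with distinct positions on one protein,
  partner classes drawn from a mix (default 0.5/0.4/0.1
  protein/chemical/dna_rna), 1–2 contact types per position, template
  identities uniform in [70, 100] by default so every generated interface
  is analyzable; the confidence logic over the full identity range is
  exercised separately.
* **Cohort** — passenger variants Poisson(background_rate) per sample,
  placed uniformly over the proteome's positions (exchangeable within each
  protein — exactly the null BM1/BM2 assume) with uniform non-reference
  alternates.  Planted drivers are exact: `round(fraction × N)` samples
  each receive one variant at a contact position whose alternate has the
  forced score sign (an error if no such substitution exists — never a
  silent neutral plant); exclusivity pairs get disjoint sample sets; one
  planted variant per (sample, interface).  Sample tables carry
  `planted_<interface>` ground-truth columns.
* **Clinical** — exponential survival times with hazard
  `baseline × group multiplier × exp(β_age (age − 60) + β_sex [female])`,
  ages ~ N(60, 12²) clipped to [20, 90]; an exact fraction of donors is
  censored uniformly before their event time and recorded alive.

Fixed seeds give byte-identical outputs; the pipeline splits one root seed
per stage via `numpy.random.SeedSequence`.

### What the synthetic benchmarks do and do not show

They establish correctness of the statistics (oracle agreement, exact
conservation laws, type-I control, planted-structure recovery) under the
generator's assumptions: positionally exchangeable passengers, uniform
composition, independent samples, exponential survival with proportional
hazards.  Real cohorts violate several of these — trinucleotide mutational
signatures, per-sample mutation-rate heterogeneity, hypermutators,
non-uniform residue composition, interface catalogs with correlated
coverage — so passing here demonstrates the machinery, not calibration on
real data.  Nucleotide-level signatures, copy number and expression are
deliberately out of the generator's scope.

## Default problem sizes

The bundled demo runs 300 samples × 40 interfaces (seconds).  The
benchmark cohorts use 1000 samples × 200 interfaces × 50 proteins of 400
residues with a background of ~0.005 perturbations per interface per
sample, 3 shuffle replicates, drivers planted at 3% — sizes chosen so
planted counts (30) sit comfortably above the 20-sample significance floor
while background counts (~5) sit far below it.

## Known limitations

* The scorer is a coarse self-trained potential: sign conventions and
  algebra match interaction-score servers used in the field, numerical
  values do not.
* The differential-across-cancers test is a stand-in choice (see above).
* No gene-level driver tests beyond the whole-protein control; no
  competing risks, time-varying covariates, or missing-data imputation in
  the survival stage; no plotting (tables are the interface for figures).
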
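# mutiface

Somatic missense mutations rarely make sense one gene at a time: the same
protein can drive disease through different molecular interfaces — with
other proteins, with small molecules (ATP, GTP, metal ions), or with
DNA/RNA.  `mutiface` is a pipeline for **interface-level analysis of
somatic missense cohorts**: it maps per-sample protein variants onto a
catalog of structural interfaces, scores each hit as *enabling* or
*disabling* with a statistical pair potential, identifies interfaces
perturbed in significantly more samples than permutation backgrounds
predict, profiles those perturbations across cancer types, clusters
samples into interface-defined subtypes, screens interface pairs for
mutual exclusivity, and relates the subtypes to survival.

It is aimed at computational cancer-genomics and structural-bioinformatics
researchers who want a tested, fully synthetic-benchmarkable
implementation of this analysis shape: every statistical stage can be run
against cohorts with *planted* ground truth (drivers, exclusive pairs,
group hazards) generated by the built-in simulator.

## The method

1. **Annotation.** A variant (sample *s*, protein *p*, position *i*,
   ref→alt) yields an event on every non-excluded interface of *p* whose
   contact positions include *i*.  Protein–protein interfaces require a
   structural template at ≥ 70% sequence identity; chemical and DNA/RNA
   sites are kept down to 30%.

2. **Scoring.** From a contact-frequency table, the pair potential is
   `log_odds(a, t) = log2 f(a,t) / (f(a) f(t))` over amino acids *a* and
   contact types *t*; a substitution scores
   `Σ_t [log_odds(alt, t) − log_odds(ref, t)]` (negative = disabling,
   positive = enabling), and multiple variants on one (sample, interface)
   sum into a combined score.

3. **Enrichment.** Two shuffled backgrounds: **BM1** reassigns each
   substitution among same-residue positions of the same protein; **BM2**
   uses any position with a random alternate.  With per-interface
   background rate `Pr = (mean background hits + 1)/(N + 1)`, the observed
   count *c* of unique perturbed samples out of *N* is tested with the
   upper binomial tail `P(X ≥ c), X ~ Bin(N, Pr)`; q-values are
   Benjamini–Hochberg per model, and an interface is significant when
   q ≤ 0.01 under **both** models and c ≥ 20 samples.

4. **Profiles, subtypes, exclusivity.** Per cancer type each interface
   gets (n perturbed samples, median combined score); samples are
   clustered by complete linkage on correlation distance of their score
   vectors (dendrogram cut at depth 0.9); interface pairs perturbed in
   ≥ 20 samples pan-cancer (≥ 10 per cancer type) are screened for mutual
   exclusivity with a one-tailed Fisher exact test, significant at
   BH q < 0.1.

5. **Survival.** Interface- or cluster-defined groups are compared by
   two-tailed Fisher on vital/disease status, Mann–Whitney on survival
   times, Kaplan–Meier + logrank, and a Cox proportional-hazards model
   with age, sex and cancer type as covariates.

## Worked example

Run the bundled demonstration: a 300-sample synthetic cohort (4 cancer
types) with three planted driver interfaces, one mutually exclusive pair
(IF0001 disabling / IF0002 enabling) and a planted 2× hazard on the
IF0001 group.

```python
from mutiface.pipeline import demo_config, run_all
import pandas as pd

run_all(demo_config(outdir="run", seed=7))
print(pd.read_csv("run/significant_interfaces.tsv", sep="\t")
        [["interface_id", "c", "q_bm1", "q_bm2"]])
```

```
interface_id  c        q_bm1        q_bm2
      IF0002 91 3.025464e-54 2.112890e-94
      IF0001 90 2.264971e-53 1.265224e-87
      IF0003 76 8.276218e-57 2.189401e-74
```

Exactly the three planted drivers are called significant: each is
perturbed in 76–91 unique samples (plant fraction × 300 plus passengers)
against a background rate of a few samples, so both background models give
vanishing q-values.  The mutual-exclusivity screen flags the planted pair
and nothing else (`mutual_exclusivity_pan.tsv`):

```
interface_a interface_b  n11  n10  n01            q  significant
     IF0001      IF0002    1   89   90 6.493388e-16         True
     IF0001      IF0003   23   67   53 6.646664e-01        False
```

(the single `n11` co-occurrence is a passenger variant landing on the
partner interface).  The survival contrast between the two exclusive
groups (`survival_contrasts.tsv`) recovers the planted hazard:

```
        contrast  n_a  n_b  logrank_p   cox_hr    cox_p
IF0001_vs_IF0002   89   90   0.000017 0.446878 0.000006
```

`cox_hr` ≈ 0.45 is the hazard of the IF0002 group relative to IF0001 —
i.e. the IF0001 group dies at ≈ 2.2× the rate, matching the planted
multiplier of 2.

The same pipeline is scriptable stage by stage:

```bash
mutiface run-all --seed 7 --outdir run          # bundled demo config
mutiface simulate --seed 1 --outdir run         # tables only
mutiface enrich --variants run/variants.tsv --proteome run/proteome.fasta \
    --catalog run/catalog.json --n-samples 300 --seed 1 --out enrichment.tsv
mutiface mutex --perturbations run/perturbations.tsv --samples run/samples.tsv \
    --scope pan-cancer --out mutex.tsv
```

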
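# dinet

Differential promoter-capture interactome analysis.

`dinet` is for regulatory genomicists who have promoter-capture Hi-C
(HiCap-style) interaction calls from the same cells in two states — say,
untreated blood stem-like cell lines and their chemotherapy-treated
counterparts — plus a patient cohort with genotypes and a toxicity
phenotype, and who want to know **which enhancer variants rewire which
promoters' interaction neighborhoods**. It implements:

1. **Network rewiring statistics.** Per cell line and condition, promoters,
   promoter-interacting regions (PIRs) and variant probes become nodes of a
   simple graph; an edge is a significant interaction (≥ 4 supporting read
   pairs, Bonferroni-adjusted *p* < 0.001) in at least one replicate. For a
   node *x* with neighbor sets *A* and *B* in the two condition networks,

       JI(x)  = |A ∩ B| / |A ∪ B|          (Jaccard index)
       OCE(x) = |A ∩ B| / min(|A|, |B|)    (overlap coefficient)

   A gene is **differentially interacting (DI)** when OCE < 1,
   0 < JI ≤ 0.5 and its mean TPM exceeds 0.2. OCE is the stricter measure:
   a promoter that only loses interactions keeps OCE = 1 (JI = 0.5 for one
   of two lost), so DI genes must have genuinely *replaced* part of their
   neighborhood.

2. **Cohort allele-difference filtering.** Patients are split into high-
   and low-toxicity cohorts (HT/LT) by k-means (k = 2) on three nadir
   blood-count phenotypes. Per variant, alt-allele counts/frequencies per
   cohort are contrasted by ACdiff = |AC.LT − AC.HT| / (AC.LT + AC.HT) and
   the analogous AFdiff; candidates need both > 0.25 and |AC.LT − AC.HT| > 1.

3. **Motif disruption.** Each variant is scored against a PWM collection
   with an information-content-weighted, min–max-normalized score; the
   effect size ES = score(alt) − score(ref) at the best window/strand, and
   |ES| ≥ 0.4 is "strong". Final candidate (variant, gene, TF) triplets
   additionally require the gene and the TF to be expressed (TPM > 0.2).

4. **Enrichment tests.** Fisher's exact test asking whether genes connected
   to candidate-variant-bearing PIRs are more often DI than genes connected
   to rest-variant-bearing PIRs, plus generic gene-set (trait) enrichment
   and bedtools-fisher-style interval enrichment for enhancer marks.

Because real patient WGS of this kind is access-restricted, the package
ships a first-class **synthetic-data generator** (`dinet.synthetic_data`)
that plants DI genes, divergent-frequency candidate variants inside their
PIRs, and PWM consensus sites disrupted by the alternate alleles — so every
stage is testable end to end with known ground truth.

## Worked example

```python
import dinet

truth = dinet.simulate_truth(seed=0)            # 200 genes, 100 variants, 54/42 cohort
result = dinet.run_synthetic_end_to_end(truth)

print("cohort sizes (HT, LT):", result.assignment.sizes)
print("DI genes called:", len(result.comparison.di_genes), "of", len(truth.di_genes), "planted")
for k, v in result.recovery.items():
    print(f"{k}: {v:.3f}")
e = result.enrichment
print(f"DI fraction candidate-connected: {e.extra['di_fraction_candidate']:.3f}")
print(f"DI fraction rest-connected:      {e.extra['di_fraction_rest']:.3f}")
print(f"Fisher p = {e.p_value:.3g}, odds ratio = {e.odds_ratio:.1f}")
```

prints

```
cohort sizes (HT, LT): (54, 42)
DI genes called: 20 of 20 planted
di_precision: 1.000
di_recall: 1.000
di_f1: 1.000
candidate_sensitivity: 1.000
candidate_specificity: 0.988
candidate_fpr: 0.012
DI fraction candidate-connected: 0.765
DI fraction rest-connected:      0.042
Fisher p = 9.51e-10, odds ratio = 73.7
```

Reading: k-means recovered the planted 54/42 toxicity split; all 20 planted
DI genes were recalled with no false calls; the cohort filter found every
planted divergent variant with one false positive (1.2% FPR); and promoters
connected to candidate-variant PIRs changed their interaction profile far
more often than the rest (76.5% vs 4.2% DI), which the Fisher test flags at
p ≈ 1e-9 — the planted analogue of the enrichment the method is built to
detect.

The same stages are scriptable from the shell:

```bash
dinet simulate --outdir ds --seed 5               # synthetic dataset + truth.json
dinet cohort   --phenotypes ds/phenotypes.tsv --vcf ds/genotypes.vcf --out ds/stats.tsv
dinet network  --interactions ds/interactions.tsv --cell CMK --expr ds/expression.tsv --out ds/di.tsv
dinet motifs   --vcf ds/genotypes.vcf --genome ds/genome.fa --pwms ds/motifs.jaspar --out ds/disruptions.tsv
dinet enrich   --interactions ds/interactions.tsv --cell CMK --expr ds/expression.tsv \
               --vcf ds/genotypes.vcf --stats ds/stats.tsv --out ds/enrich.json
```

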
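# visscreen

Analysis toolkit for **retroviral insertional-mutagenesis resistance
screens** read out by viral integration site sequencing (VIS-NGS).

In such a screen, a cell population carrying random single-copy retroviral
integrations is cultured under a drug. Integrations that disrupt or
activate a resistance-relevant gene give their clone a fitness advantage,
so the corresponding integration locus becomes over-represented in treated
cultures relative to untreated controls. Sequencing the LTR–genome
junctions of each sample turns the question "which genes mediate
resistance?" into a locus-level counting problem. `visscreen` implements
that analysis end to end for screens of ER-positive breast-cancer cells
under endocrine agents (tamoxifen, fulvestrant) and CDK4/6 inhibitors
(palbociclib, ribociclib, abemaciclib):

* **read preparation** — error-tolerant removal of the 5′ LTR and 3′
  linker adapters by semiglobal edit distance (error rate 0.25 of the
  matched adapter length; untrimmed reads discarded; minimum 36 bp);
* **VIS calling** — MAPQ ≥ 20 filtering, pooled single-linkage collapsing
  of read positions within a 1000 bp window into shared loci, reads-per-
  million (RPM) quantification, nearest-gene annotation;
* **screen statistics** — the filtering cascade (singleton removal,
  pLN1/pLN2 biological-replicate concordance, within-treatment replicate
  concordance) followed by two complementary per-locus tests against the
  untreated controls: a two-sided Fisher exact test on detection frequency
  and a Student t-test on mean RPM coverage, at exploratory (p < 0.1) and
  significant (p < 0.05) tiers; candidate genes are enrichment-supported
  loci collapsed by nearest gene, then categorized by detection in the
  held-out verification arms;
* **single-cell validation** — fraction of cells positive at ≥ 1 CPM per
  candidate gene, compared between parental and drug-resistant populations
  with a Pearson chi-squared test and Bonferroni correction;
* **synthetic screens** — a Wright–Fisher generative model (fitness-
  weighted multinomial passaging) with junction-read simulation and known
  ground truth, so every stage is testable without external data.

For the Fisher test on a 2×2 detection table with margins fixed, the
two-sided p-value is computed by exact enumeration:

p = Σ_{k : P(k) ≤ P(a)} P(k),  P(k) = C(r₁,k)·C(r₂,c₁−k) / C(n,c₁)

and the coverage comparison is the pooled two-sample t statistic
t = (x̄₁ − x̄₂) / √(s_p²(1/n₁ + 1/n₂)) with n₁+n₂−2 degrees of freedom.

## Worked example

Simulate a small screen with known truth — 60 clones, 4 with a fulvestrant
fitness advantage and 2 with a ribociclib advantage (per-passage weight
1.6) — then run the screen:

```python
from visscreen.experiments import planted_screen_recovery

r = planted_screen_recovery(1, reads_per_sample=5_000, n_clones=60,
                            n_fulv=4, n_ribo=2)
print(r["output"].stage_counts)
print(r["output"].candidates[["gene", "supporting_loci", "treatments"]])
print(r["sensitivity"], r["neutral_candidate_rate"])
```

prints

```
{'loci_total': 60, 'singletons_removed': 0, 'replicate_discordant_removed': 0,
 'treatment_discordant_removed': 0, 'loci_tested': 60, 'candidate_genes': 6}
    gene supporting_loci  treatments
GENE0015        VIS00006 fulvestrant
GENE0091        VIS00012 fulvestrant
GENE0152        VIS00020 fulvestrant
GENE0289        VIS00046  ribociclib
GENE0298        VIS00047  ribociclib
GENE0361        VIS00053 fulvestrant
1.0 0.0
```

All 60 integrations are recovered as loci; exactly the 6 planted resistant
clones (and no neutral clone) surface as candidate genes — sensitivity
1.0 at a 0.0 neutral false-positive rate. Per-locus tables carry the
Fisher and t statistics; e.g. a neutral locus detected in all samples has
`fisher_p = 1.0` while showing the compositional RPM depletion caused by
the expanding resistant clones — which is why candidate selection requires
the enriched direction.

The same stages are available from the shell:

```sh
visscreen simulate --seed 3 --n-clones 40 --reads-per-sample 800 --out sim/
visscreen screen --alignments sim/alignments/*.sam \
    --sample-sheet sim/sample_sheet.tsv --annotation sim/genes.bed --out screen/
visscreen validate-scrna --counts counts.tsv --labels labels.tsv \
    --candidates screen/candidate_genes.tsv --out validation/
```

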
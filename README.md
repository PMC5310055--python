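# tmau

Choline-challenge analysis and rare-variant prioritization for
trimethylaminuria (TMAU) cohorts.

TMAU is an inborn error of metabolism in which trimethylamine (TMA), the
fishy-smelling amine that gut bacteria release from dietary choline, is not
oxidized to odorless TMA-N-oxide (TMAO) by the liver enzyme FMO3. Clinics
diagnose it with a choline challenge: after a fixed oral choline dose,
timed urine collections are assayed for TMA and TMAO, and the TMAO fraction

    r = [TMAO] / ([TMA] + [TMAO])

is compared against the healthy reference (r ≥ 0.90; a subject with
r < 0.90 meets the TMAU criterion). Loss-of-function *FMO3* variants
explain many cases but not all, so exome sequencing of affected cohorts is
screened for candidate variants in other genes.

`tmau` implements that whole desk-side workflow for a small multi-sample
exome cohort:

- **metabolic** — peak-TMA sample selection, oxidation ratio, TMAU
  classification, cohort summary;
- **variants** — multi-sample VCF → dense subjects × variants zygosity
  matrix (multiallelic splitting, male X/Y hemizygosity normalization) and
  SIFT/PolyPhen-2/MAF annotation tables;
- **cascade** — the filter cascade: cohort presence with a required
  homozygote → predicted-pathogenic (SIFT deleterious *or* PolyPhen-2
  damaging) → two branches: oxidoreductase-pathway genes with MAF < 0.05,
  and variants outside known TMA genes (*FMO3*, *PYROXD2*, *DMGDH*)
  homozygous in ≥ 2 subjects with MAF < 0.05;
- **catalog_network** — lookup of catalogued TMAU alleles (with a side
  channel for off-exome assays), and expansion of seed genes through a
  STRING-style scored interaction network (score ≥ 0.4, top 10
  interactors) followed by a rare-deleterious scan of the neighborhood;
- **concordance** — exome vs. orthogonal (Sanger/Taqman-style) genotype
  match rates;
- **report** — per-subject variant totals by category, ordered by
  metabolic severity;
- **synth** — synthetic cohorts with planted variants and leave-one-out
  decoys (ground truth for every filter), plus a fixture transcribed from
  the published study tables.

## Worked example

```sh
tmau fixture --out fixture/          # write the transcribed-table bundle
tmau metabolic --urine fixture/urine.tsv --out profiles.tsv
# n=10 n_TMAU=10 ratio range 0.13-0.87
tmau cascade --vcf fixture/cohort.vcf --annotations fixture/annotations.tsv \
  --sexes fixture/subjects.tsv \
  --oxidoreductase-genes fixture/oxidoreductase_genes.txt --out cascade.json
# MAIN            cohort_presence          SNPs=18 indels=2
# MAIN            pathogenic               SNPs=17 indels=2
# OXIDOREDUCTASE  oxidoreductase_genes     SNPs=5 indels=1
# OXIDOREDUCTASE  rare                     SNPs=4 indels=1
# SHARED          exclude_known_tma_genes  SNPs=17 indels=2
# SHARED          shared_any_carrier       SNPs=11 indels=1
# SHARED          shared_homozygous        SNPs=10 indels=1
# SHARED          rare                     SNPs=9 indels=1
```

All ten subjects meet the TMAU criterion, with oxidation ratios spanning
0.13 (most severely impaired) to 0.87. The cascade ends with 4 rare
pathogenic SNPs plus 1 indel in oxidoreductase-pathway genes and 9 rare
pathogenic SNPs plus 1 indel shared homozygously by two subjects in genes
with no known TMA role. The same library calls are available in Python:

```python
from tmau import study_fixture, profile_cohort, run_cascade, summarize_cohort

fx = study_fixture()
print(summarize_cohort(profile_cohort(fx.urine_samples)))
# CohortSummary(n=10, n_tmau=10, min_ratio=0.13, max_ratio=0.87)
```

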
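# Methods

## Metabolic classification

The choline challenge yields a pre-challenge urine collection (interval 0)
and three consecutive 8-hour post-challenge collections (intervals 1–3).
TMA is quantified in every collection; TMAO only in the post-challenge
collection with the highest TMA concentration (ties broken toward the
earliest interval; the pre-challenge sample is excluded from peak
selection by default, configurable).

The outcome is the TMAO fraction of total TMA species,
`r = TMAO / (TMA + TMAO)`, not the raw quotient `TMAO/TMA`. The two
readings are sometimes conflated in clinical shorthand; the fraction is
implemented because reference values are quoted on a 0–1 scale with a
0.90 cut-off, and the raw quotient is exposed separately
(`tmao_tma_quotient`). The fraction is scale-invariant, so concentration
units cancel. A subject meets the TMAU criterion when `r < 0.90`
*strictly*; the boundary value classifies as normal. Both the threshold
and strictness can be adjusted via the `threshold` parameter.

## Genotype representation

Genotypes are held as a dense subjects × variants matrix of zygosity
states: `HOM_REF`, `HET`, `HOM_ALT`, `HEMI_REF`, `HEMI_ALT`, `MISSING`.
Conventions:

- Coordinates are 1-based hg19-style; a leading `chr` prefix is stripped.
- The VCF ALT allele is treated as the minor allele throughout; no
  per-cohort allele-frequency flipping is attempted.
- Multiallelic records are split into one column per ALT allele because
  every filter is per-allele; splitting conserves per-sample ALT dosage.
- Male genotypes on X/Y are normalized to hemizygous states, whether the
  caller coded them as haploid (`1`) or as diploid homozygous (`1/1`).
  Pseudo-autosomal regions are not modelled. A het-coded male X call is
  retained as `HET` so the anomaly stays visible rather than being
  silently repaired. Hemizygous-ALT satisfies any "homozygous for the
  minor allele" requirement, since a one-allele genotype cannot be
  heterozygous.
- A variant is a SNP iff both alleles are single bases; otherwise an
  indel. Indels use left-anchored VCF representation.

## Filter cascade

Defaults (all in `CascadeConfig`):

| parameter | default | rationale |
|---|---|---|
| `maf_threshold` | 0.05 | standard "rare" cut-off against reference-panel frequencies |
| `sift_deleterious_max` | 0.05 | SIFT's conventional deleterious cut-off |
| `polyphen_damaging_min` | 0.446 | PolyPhen-2's possibly-damaging lower bound |
| `pathogenicity_rule` | EITHER | a variant is a candidate if either predictor flags it |
| `require_cohort_homozygote` | true | recessive-model presence filter |
| `min_sharing_subjects` | 2 | recurrence raises prior of a causal role |
| `missing_maf_policy` | TREAT_AS_RARE | novel variants absent from panels are the object of interest; such keys are kept |
| `known_tma_genes` | FMO3, PYROXD2, DMGDH | excluded from the discovery (SHARED) branch |

Design choices made where the procedure was genuinely open:

- **Presence rule.** The default is "observed with at least one cohort
  homozygote" rather than "found in all subjects": single-subject
  candidate variants are legitimate discovery output under a recessive
  model, and `ALL_SUBJECTS` remains available via configuration.
- **Predictor precedence.** When a categorical SIFT/PolyPhen call and a
  numeric score are both present, the call wins; at load time the pair is
  validated for consistency with the conventional thresholds, so the
  precedence only matters for externally supplied tables. A variant with
  neither call nor score is *not* deleterious — pathogenicity must be
  demonstrated, not assumed. This matters for protein-truncating
  variants, which neither tool scores: they do not pass the
  pathogenicity filter and should be assessed via the catalog route.
- **Branch order.** The SHARED branch applies rarity last
  (exclusion → any-carrier sharing → homozygous sharing → rarity); the
  OXIDOREDUCTASE branch applies gene-set inclusion then rarity. Because
  every filter is a pure set intersection the terminal sets are
  order-independent; the recorded intermediate counts follow this fixed
  order so step tables are comparable across runs.
- **Sharing zygosity.** Both an any-carrier and a homozygous-only sharing
  pass are recorded, the homozygous pass feeding the terminal set, since
  the recessive reading of "shared rare variant" is the stricter and more
  interpretable one.

Survivor sets are nested along each branch by construction, SNPs and
indels are tallied separately at every step, and on small inputs the
cascade is verified against an independent brute-force implementation.

## Catalog lookup and interactome scan

Catalogued known variants are matched by exact (chrom, pos, ref, alt) key
against the matrix; entries not captured by the exome (e.g. an intronic
allele typed by an allele-specific assay) resolve through an
extra-genotypes side channel keyed by rsID. Hemizygous-ALT tallies as
homozygous.

Seed-gene expansion mirrors a STRING query consumed offline: per seed,
neighbors with combined score ≥ 0.4 (default), ranked by descending score,
truncated to the top 10; ties at the cut break lexicographically by gene
symbol, since the upstream service's internal ordering is not reproducible
offline. Seeds are members of their own expansion. The subsequent variant
scan keeps rare deleterious variants with *any* carrier zygosity — unlike
the cascade trunk it does not require a cohort homozygote, so
heterozygous-only candidates survive here. Edge lists on the 0–1000
integer score scale are auto-detected and rescaled.

## Concordance

A (subject, variant, platform) pair is compared when both the exome side
and the orthogonal call are non-missing, and matches when zygosity is
identical. Two opt-in relaxations: `lenient_hemi` treats
hemizygous/homozygous pairs as equivalent (for platforms that report male
X calls diploid), and `count_missing_as_mismatch` moves missing-side
pairs into the denominator. A comparison with an empty denominator raises
rather than reporting a vacuous rate.

## Synthetic cohorts and the transcribed fixture

`generate_cohort` emulates the cohort-scale *marginals* of exome data:
background variants draw MAF ~ U(0, 0.5), per-subject genotypes
binomially from the MAF (Hardy–Weinberg), and missingness is injected as
an exact cell count at a default rate of 0.19, inside the 15–23%
per-subject missing-rate band reported for SNP sites in the study data.
It does not emulate linkage, population structure, per-site coverage
bias, or annotation errors — so passing tests demonstrate the correctness
of the filtering logic, not robustness to real-data artifacts.
Background variants are annotated benign/tolerated; discrimination
pressure on each individual filter comes from planted decoys, which are
constructed leave-one-out (each decoy satisfies all criteria of its
target branch except exactly one), making filter-ordering bugs visible
as truth-label flips. Plants are never masked by injected missingness.
Generation is fully deterministic given the seed, down to written bytes.

The study fixture transcribes the published per-subject tables: subject
demographics and oxidation ratios; the known FMO3/PYROXD2 alleles with
their per-subject zygosity marks; the novel oxidoreductase, interactome
and shared variants; a minimal scored network around the FMO3 / PYROXD2 /
DMGDH seeds; and 29 + 30 orthogonal validation calls across two platform
labels. Urine concentrations are not published; they are back-solved from
each printed two-decimal ratio as TMA = 100·(1−r), TMAO = 100·r, which is
exact because the ratio is scale-invariant. Interactome carriers are
encoded heterozygous, following the results narrative (and the per-subject
mark table) over a table footnote that labels all novel-variant carriers
homozygous. The stop-gain FMO3 allele carries no SIFT/PolyPhen scores, as
neither tool scores truncating variants. Genotype-level content beyond
the printed marks (e.g. reference cells, unprinted alleles for the novel
variants) is synthetic reconstruction.

## Numerical and degenerate-input choices

- Oxidation ratio with TMA = TMAO = 0 is an error, not 0 or NaN.
- Report rendering fixes ratios to two decimals and MAFs to four
  significant digits in TSV output, with stable sort orders, so repeated
  renders are byte-identical.
- Equal metabolic ratios order subjects by id in the report (the source
  tables leave such ties unexplained).
- Empty gene set under an INCLUDE filter warns and returns the empty set.
- Duplicate variant keys, MAF outside [0, 0.5], predictor call/score
  conflicts, hemizygous calls on female or autosomal cells, and plants
  referencing unknown subjects are all hard errors at construction time.

## Problem sizes

The bundled checks run the full fixture (10 subjects, 30 variants), the
brute-force cascade comparison on random matrices of ≤ 50 variants, the
plant/decoy battery across 20 seeds at 100 background variants, and a
Hardy–Weinberg sanity check at 500 subjects — sizes chosen because every
pipeline property being asserted is already fully exercised at this
scale; the cohort-level counts reported for the parent 669-exome call set
depend on external data and are out of scope.

## Known limitations

- No read-level or caller-level modelling (alignment, base quality,
  joint calling); genotypes are taken as given.
- SIFT/PolyPhen-2 scores and MAFs are consumed, never computed; the
  pipeline inherits their blind spots (non-missense variants, panel
  coverage).
- Pseudo-autosomal X regions are treated as hemizygous in males.
- The interaction network is a static edge list; evidence channels,
  direction and homology-based inference are out of scope.
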
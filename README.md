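# methcordance

Analysis toolkit for **matched two-tissue DNA methylation studies** — cohorts
in which every individual is profiled in two surrogate tissues (the motivating
design: buccal epithelial cells, BEC, and peripheral blood mononuclear cells,
PBMC, in children), with array genotypes for the same samples. It answers the
questions such designs are built for:

* How variable is DNAm across individuals, and does one tissue vary more?
* Which CpGs covary between tissues, so one tissue can stand in for the other?
* How much of that covariation is driven by local genetic variation (cis-mQTL)?
* Which CpGs are differentially methylated between the tissues, consistently
  across cohorts?

It is aimed at epigenetics groups running paired-tissue EWAS-support analyses,
and ships a synthetic-data generator with planted, recorded ground truth so
the entire pipeline is testable end to end without access to restricted
cohort data.

## The statistics at the core

* **Reference range** — per-CpG variability as the spread between the 10th
  and 90th percentile of beta values across individuals,
  `RR = Q90(β) − Q10(β)`; robust to outlier samples. Global tissue
  comparisons use paired Wilcoxon signed-rank tests over probes; probewise
  dispersion differences use the Fligner–Killeen test with
  Benjamini–Hochberg FDR.
* **Informative sites** — CpGs with `RR ≥ 0.05` in both tissues whose
  cross-tissue Spearman ρ exceeds a cohort-specific cutoff derived by
  fitting a two-component Gaussian mixture to ρ of highly variable CpGs
  (`RR > 0.10`): the cutoff is `μ_high − 2σ_high` of the concordant
  component. Per-cohort calls are intersected into a consensus set.
* **cis-mQTL** — SNP–CpG pairs < 5 kb apart, tested by Spearman correlation
  of beta on additive dosage after SNP QC (missingness ≤ 5 %, MAF ≥ 5 %,
  HWE exact test) and CpG variability filtering (`RR ≥ 0.05`). The effect
  size is the OLS slope of beta on dosage — DNAm change per allele. Hits:
  `FDR ≤ 0.05` and `|effect| ≥ 0.025`. Discovery hits are re-tested in an
  independent cohort (validation-only FDR; pairs monomorphic or with < 2
  heterozygotes are untestable) and classified tissue-specific vs shared.
* **Differential methylation** — per-CpG paired Wilcoxon signed-rank
  between tissues, `FDR ≤ 0.05` and `|Δβ| ≥ 0.05`; the consensus keeps
  CpGs significant with the same sign in every dataset, including a
  subsampled rendition of the larger cohort that equalises sample size.
* **Enrichment & categorization** — permutation tests (10,000 draws,
  add-one empirical p) for set overlap and genomic-feature composition, and
  an eight-way CpG categorization from the informative / differential /
  mQTL-associated flags, with overlap tabulation against user-supplied
  EWAS hit lists.

## Worked example

```python
from methcordance import SimConfig, RunConfig, run_all

sim = SimConfig(n_cpgs=4000, n_snps=800, cohort_sizes=[79, 16], seed=7)
result = run_all(RunConfig(sim=sim, seed=7, out_dir="scratch/demo"))
s = result["summary"]

v = s["variability"]["cohort1"]
print(f"median reference range (discovery): BEC {v['median_rr_a']:.3f}, PBMC {v['median_rr_b']:.3f}")
print(f"rho threshold (discovery): {s['concordance']['cohort1']['rho_threshold']:.3f}")
print(f"consensus informative sites: {s['n_informative_consensus']}")
print(f"validated cis-mQTL sharing: {s['mqtl']['sharing']}")
print(f"consensus differential CpGs: {s['n_consensus_differential']}")
print(f"mQTL effect recovery MAE (PBMC): {s['recovery']['mqtl_effect_mae_pbmc']:.4f}")
```

prints

```
median reference range (discovery): BEC 0.221, PBMC 0.113
rho threshold (discovery): 0.843
consensus informative sites: 332
validated cis-mQTL sharing: {'PBMC_specific': 164, 'BEC_specific': 32, 'shared': 22}
consensus differential CpGs: 1156
mQTL effect recovery MAE (PBMC): 0.0110
```

Reading this: the BEC-like tissue is planted with twice the individual-level
variation of the PBMC-like tissue, and the recovered median reference ranges
(0.221 vs 0.113) reflect that. The mixture-model ρ cutoff (0.843 here; it is
data-derived and shifts with the noise structure) gates the consensus
informative set of 332 CpGs. Validated cis-mQTL split into tissue-specific
and shared pairs, and the per-allele effect estimates land within ~0.01 beta
units of the planted truth on average. `scratch/demo/` holds every stage
table (variability, concordance, mQTL records, differential consensus,
enrichment, per-CpG categories) as TSV plus `summary.json`.

The same pipeline runs from the command line on on-disk cohorts:

```bash
methcordance simulate --out data --seed 7
methcordance run --config run.yaml --out results_dir
```

where `run.yaml` lists either `sim: {...}` parameters or `cohorts:` paths,
plus any thresholds to override. Per-stage subcommands (`variability`,
`concordance`, `mqtl`, `differential`, `adjust-cells`, `enrich`, `classify`,
`ewas-overlap`) expose each stage separately.

## Layout

```
src/methcordance/
  data_io.py             TSV/VCF ingest, core containers, probe QC
  simulate.py            synthetic paired-cohort generator + truth table
  cell_adjust.py         reference-based deconvolution and residualization
  variability.py         reference range, Fligner-Killeen, subsampling study
  concordance.py         cross-tissue rho, mixture threshold, informative calls
  mqtl.py                SNP QC, cis pairing, discovery/validation scans
  differential.py        paired signed-rank scans and consensus
  enrichment_classify.py permutation enrichment and CpG categories
  pipeline.py            run_all orchestration with per-stage seeds
  cli.py                 click command-line interface
```

See `docs/methods.md` for the generative model, parameter defaults, numerical
conventions and known limitations.
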
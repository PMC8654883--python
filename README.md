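# dentist

Quality control for GWAS summary statistics against an LD reference panel.

## The problem

Summary-statistics methods (conditional/joint analysis, fine-mapping,
polygenic scoring) combine per-variant z-scores from a GWAS with a linkage-
disequilibrium (LD) correlation matrix estimated from a reference cohort.
Errors in either input — effect-allele mislabeling ("allelic errors"),
genotyping or imputation errors, or plain ancestry mismatch between the GWAS
sample and the reference — make the z-scores and the LD matrix mutually
inconsistent, which can fabricate or destroy signals downstream.

This package detects such inconsistencies variant by variant.  Under the
null, the z-scores of `m` variants are multivariate normal with covariance
equal to the LD correlation matrix **R**.  The observed z-score of variant
`i` is therefore predictable from the z-scores of neighbouring variants
**t**:

    ẑᵢ  = R_it R_tt⁻¹ z_t
    T_d = (zᵢ − ẑᵢ)² / (1 − R_it R_tt⁻¹ R_itᵀ)   ~  χ²(1)

A variant whose observed z-score sits many standard deviations from its
LD-predicted value (P below 5×10⁻⁸) is flagged.  `R_tt` is pseudo-inverted by
a rank-truncated eigendecomposition (retaining a proportion `θ_k = 0.5` of
the effective rank), and predictors in near-perfect LD with the target
(r² > 0.95) are excluded, for numerical stability.

Because errors can corrupt the predictors too, the pipeline is iterative:
variants in 2 Mb windows (500 kb overlap) are randomly split into two halves
that predict each other; each iteration removes the worst offenders —
capped at 0.5% per iteration within each GWAS-significance stratum, with the
significant stratum (P_GWAS < 0.01) never losing a larger share than the
non-significant one — and a final unconstrained pass removes everything
still failing the threshold.

A synthetic-data module simulates the whole experiment (block-LD genotypes
via a haplotype Markov chain, polygenic traits, marginal GWAS, allelic and
genotyping error injection, ancestry-mismatch knob), so every claim the
package makes is testable without downloading any cohort.

## Worked example

`examples/01_simulate_inject_and_qc.py` simulates a 2,000-variant GWAS
(n = 5,000; 50 causal variants explaining 20% of trait variance), mislabels
the effect allele at 0.5% of variants, and cleans the data in two stages:

```text
injected effect-allele swaps at 10 of 2000 variants
standard QC (delta-AF > 0.1): removed 8 variants, 8 of the 10 flips
LD-discrepancy QC: removed 2 of 1992 remaining variants (0.10%)
power on remaining flips:    50%
fold enrichment:             498x (true-error rate among removed vs among all variants)
error-free causal variants removed: 0 of 50
note: flip at snp001105 survives with |z| = 0.2 (null variant; undetectable by design)
```

The allele-frequency filter catches flips whose MAF is far from 0.5; the
LD-discrepancy test catches the flip it cannot see (here one with |z| = 2.2),
and the only flip surviving both is a null variant whose sign carries no
information.  No true causal variant is lost.

Other examples: `02_null_calibration.py` (T_d is χ²(1)-calibrated on clean
data: mean ≈ 0.99, KS ≈ 0.01, nothing removed), `03_file_based_workflow.py`
(PLINK bed/bim/fam + COJO `.ma` text file in, TSV report and JSON run
manifest out), `04_reference_heterogeneity.py` (mean T_d rises with the
simulator's ancestry-mismatch knob).

## Library layout

| module | contents |
|---|---|
| `dentist.sumstats` | COJO `.ma` reading/writing, allele harmonization (strand flips, palindromic handling), ΔAF filter, TSV report |
| `dentist.panel` | PLINK 1 bed/bim/fam I/O, allele frequencies, HWE test, windowed LD matrices, truncated eigendecomposition and its quadratic forms |
| `dentist.core` | sliding-window plan, random partitions, predictor selection, the T_d statistic |
| `dentist.pipeline` | `QCParams`, the iterative partition–test–remove loop, `run_dentist`, `scan_once` |
| `dentist.simulation` | `SimConfig`, panel-pair generator, phenotype + marginal GWAS, error injection, standard QC, power/enrichment evaluation |
| `dentist.config` | YAML configs for `QCParams`/`SimConfig`, reproducibility manifests |

All functions are importable from the top level (`from dentist import
run_dentist, ...`).  Everything is deterministic given the seeds in
`QCParams`/`SimConfig`.

## Acceptance script

`scripts/acceptance.py` re-derives the package's two headline numbers from
scratch by simulation — the percentage of variants removed on error-free
data with in-sample LD (conservativeness), and the power to detect
effect-allele swaps among genome-wide-significant variants — and writes them
as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runs in a few minutes on one CPU; all randomness derives from `--seed`.

## Scope

The package covers QC of summary statistics against a reference panel and
the simulation machinery to validate it.  It does not run downstream tools
(COJO, FINEMAP, LDSC), does not read dosage/BGEN or PLINK 2 formats, and
does not model imputation uncertainty; see `docs/methods.md` for the model,
parameter guidance and known limitations.
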
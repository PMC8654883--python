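# Methods

## Model

Let `z = (z_1, …, z_m)'` be marginal GWAS z-scores.  Under the null of no
association, `z ~ N(0, Σ)` with `Σ` the LD correlation matrix of the
variants in the GWAS cohort.  Conditioning on the z-scores `z_t` of a set of
variants **t**,

    z_i | z_t  ~  N( Σ_it Σ_tt⁻¹ z_t ,  1 − Σ_it Σ_tt⁻¹ Σ_it' ).

Replacing `Σ` by the correlation matrix `R` estimated from a reference
panel gives the working model.  The test statistic for variant `i` is

    T_d(i) = (z_i − ẑ_i)² / (1 − R_it R_tt⁻¹ R_it'),   ẑ_i = R_it R_tt⁻¹ z_t,

referred to the upper tail of χ²(1).  The same formula is applied under the
alternative (associated variants); this is an approximation — the exact
conditional mean under the alternative depends on the unknown genetic
architecture — and its cost is a bias term: if variant `i` carries signal
with expected z-score μ and its predictors recover a fraction of it, the
non-centrality of T_d(i) is of order `(1 − leverage) · μ²`, where
`leverage = R_it R_tt⁻¹ R_it'`.  Well-tagged variants (leverage near 1) are
therefore safe; poorly tagged, strongly associated variants are the
method's known false-positive mode.  The stratified caps below exist to
protect them.

`R_tt` estimated from finite panels is near rank-deficient, so its inverse
is computed through a truncated eigendecomposition: with eigenpairs
`(w_j, v_j)` sorted by descending eigenvalue, effective rank
`q = #{w_j > 1e-8 · w_max}`, and `k = max(1, ⌊θ_k · q⌋)` retained pairs,

    R_it R_tt⁺ z_t  = Σ_{j≤k} (1/w_j)(R_it v_j)(v_j' z_t)
    R_it R_tt⁺ R_it' = Σ_{j≤k} (1/w_j)(R_it v_j)².

A useful identity: because `R⁺ R R⁺ = R⁺`, the truncated predictor is
*exactly* calibrated under the null when `R` is the true covariance — the
residual variance of the truncated prediction equals `1 − leverage_k`.
Truncation therefore costs power against errors, not null calibration.

## Pipeline

1. Variants are tiled into 2 Mb windows advancing by 1.5 Mb (500 kb
   overlap) per chromosome; each variant is *tested* in the single window
   whose centre is nearest (ties to the earlier window) but serves as a
   *predictor* in every window containing it.
2. Each iteration: per window, surviving variants are split uniformly at
   random into two near-equal halves; each variant is predicted from the
   opposite half (excluding predictors with r² > 0.95 to the target).
3. Removal is stratified by GWAS significance at P_GWAS = 0.01 (boundary
   values go to the protected stratum).  In the non-significant stratum,
   variants with P_DENTIST < 5×10⁻⁸ are removed, capped at the top 0.5% by
   descending T_d; the removed proportion x% is then applied as the cap for
   the significant stratum (never exceeding 0.5%).  Caps round down.
4. After 10 iterations, a final unconstrained pass removes every surviving
   variant with P_DENTIST < 5×10⁻⁸.

Variants untestable in a round (window with <2 survivors, empty predictor
set) pass that round.  P values are computed from T_d; threshold
comparisons are done on the T_d scale (`chi2.isf(5e-8, 1) ≈ 29.72`) so that
underflow of extremely small P values cannot affect decisions.

Determinism: every partition derives from
`SeedSequence([master_seed, iteration, window_id])`, so runs reproduce
byte-identically and per-window work is order-independent.  Parallel
execution is not implemented (the target workloads here run in seconds to
minutes on one CPU); the seeding scheme is what would keep it deterministic.

### Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| `p_dentist_threshold` | 5×10⁻⁸ | removal threshold on the discrepancy P |
| `p_gwas_cutoff` | 0.01 | stratification boundary (boundary protected) |
| `per_iteration_cap` | 0.005 | max removed share per stratum per iteration |
| `n_iterations` | 10 | constrained iterations before the final pass |
| `theta_k` | 0.5 | retained share of `R_tt`'s effective rank |
| `window_bp` / `overlap_bp` | 2 Mb / 500 kb | sliding-window geometry |
| `r2_cap` | 0.95 | predictor exclusion above this r² to the target |
| `maf_min` | 0.001 | variants below this reference MAF are not tested |
| `denom_floor` | 10⁻⁶ | lower bound on 1 − leverage |
| `rank_key` | `"td"` | removal priority within a stratum (`"p_gwas"` optional) |

The removal-priority key is a deliberate design choice: the published
description ranks variants by P_GWAS within strata but does not name the
key used for the "top x%" cut; removing by descending T_d matches the
algorithm's stated intent (drop the most discrepant variants first) and is
exposed as `rank_key` for users who prefer the literal P_GWAS ordering.

Other conventions: allele matching tries variant id first, then
chromosome+position; multi-allelic panel sites are skipped; palindromic
(A/T, C/G) variants are kept and flagged by default (dropping those with
MAF > 0.4 is opt-in) since ΔAF and T_d themselves catch undetected strand
errors; a z/P inconsistency in the input is a warning, not a drop, because
published files often truncate P values.  Missing hard calls are
mean-imputed per variant before LD (keeps `R` positive semi-definite,
unlike pairwise-complete correlation); dosages are standardized by sample
mean/SD, not 2p(1−p).

## Synthetic data

`simulate_panel_pair` generates haplotypes by a first-order Markov chain:
LD blocks of 20–50 variants (2 kb spacing, so blocks span 40–100 kb), MAF
uniform on [0.01, 0.5], within-block adjacent haplotype correlation ρ drawn
uniformly from [0.90, 0.96], zero correlation across block boundaries.
Genotypes are sums of two independent haplotypes; GWAS and reference panels
are independent draws from the same model.  The trait is
`y = g + e` with 50 causal variants, standardized-genotype effects from
N(0,1), and `var(g)/var(y)` rescaled to exactly `h² = 0.20`; the marginal
GWAS is per-variant OLS.

The high adjacent ρ is load-bearing.  Chain correlations decay
geometrically with distance, so adjacent ρ controls how redundantly any
variant is tagged.  Real sequence-density data gives every common variant
several near-perfect proxies (that is why the method needs an r² > 0.95
predictor-exclusion rule at all).  With weaker adjacent LD (ρ ≈ 0.5–0.9) a
strongly associated variant whose flanking tags happen to land in its own
partition half is predicted through distance-2+ neighbours, its leverage
drops to ~ρ⁴, and the `(1 − leverage) μ²` bias can cross the removal
threshold — causal variants then get removed at ~0.1–0.2%, an artifact of
desk-scale under-tagging rather than a property of the method.  At
ρ ∈ [0.90, 0.96] the clean-data behaviour matches the method's published
operating characteristics (nothing removed, T_d mean ≈ 1).

Error injection:

- **Allelic errors** swap the A1/A2 labels and leave every value untouched
  — the file then attributes the effect to the wrong allele.  After
  harmonization the z-score comes out negated and the frequency
  complemented; ΔAF becomes |1 − 2f|, which is why the standard QC catches
  flips away from MAF 0.5 and the discrepancy test is needed near 0.5.
- **Genotyping errors** replace the dosages of an `f_error` share of
  individuals at selected variants with draws from Binomial(2, AF)
  conditioned to differ from the current value: approximately
  AF-preserving, LD-attenuating (self-correlation ≈ 1 − f_error for common
  variants; stronger attenuation for rare ones, where the forced-different
  draw inflates variance).  The GWAS is re-run on the corrupted copy while
  the reference keeps the clean copy — with an identically corrupted
  reference the attenuation cancels algebraically in T_d and the error
  would be undetectable, contradicting the detectability these errors are
  known to have.
- **Heterogeneity knob** (`heterogeneity = η`): the reference is an
  ancestry-diverged cohort whose LD *phase* differs — each within-block
  transition has its correlation sign inverted with probability `0.2 η`.
  Sign rotation preserves LD magnitude while inverting the direction of
  every correlation straddling a rotated link, so the reference makes
  confident but wrong predictions and mean T_d inflates monotonically in η
  (≈1.17 → 1.48 over η = 0 → 0.3 in the shipped check).  Mechanisms that
  merely weaken reference LD (frequency drift, ρ damping, panel mixtures)
  were tried and *deflate* the statistic — attenuated predictions shrink
  the numerator faster than they enlarge the denominator — so they are
  deliberately not part of the knob.

What a green simulation does *not* establish: the generator has no
long-range LD beyond blocks, no MAF-LD coupling, no imputation dosage
uncertainty, a stylised (single-parameter) divergence model, and
block-independent causal placement.  Power and enrichment numbers
transfer qualitatively, not quantitatively, to real cohorts.

## Numerical choices

- Effective rank threshold: eigenvalues above `1e-8 × w_max` count toward
  `q`; `k = max(1, ⌊θ_k q⌋)` (floor for conservatism, minimum 1).
- `denom_floor = 1e-6` guards leverage ≈ 1 after truncation noise.
- χ²(1) tail: scipy's `sf` down to the smallest normal double; a fully
  underflowed P is reported as the smallest subnormal rather than 0, and
  all threshold logic uses the T_d scale.
- The per-window LD matrix is computed once and cached; per-target
  eigendecompositions are recomputed only for targets with a non-empty
  r² > 0.95 exclusion set (grouped by identical exclusion sets).
- Removal ties (equal T_d) break by dataset order, keeping reports
  byte-stable across repeated runs.

## Known limitations

- Strongly associated variants that are genuinely poorly tagged in the
  reference can be removed by the final unconstrained pass (the
  `(1 − leverage) μ²` bias); this is inherent to the approximate
  conditional model and is the price of the final pass's strictness.
- Harmonization cannot resolve palindromic variants' strand; they are
  flagged, not solved.
- The HWE filter needs individual-level GWAS genotypes; with summary data
  only, the ΔAF filter is the sole pre-filter.
- PLINK 1 hard calls only; no BGEN/pgen/dosage input.
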
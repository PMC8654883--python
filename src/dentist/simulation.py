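"""Synthetic GWAS + reference-panel generator and error-injection utilities.

The generator emulates, at desk scale, the ingredients of the error-detection
experiments: diploid genotypes with block-wise LD, a quantitative trait driven
by common causal variants, a marginal (one-variant-at-a-time) GWAS, allelic
errors (effect-allele swaps in the summary file), genotyping errors
(corruption of a fraction of individuals' genotypes), the standard QC filters
(HWE P < 1e-6, delta-AF > 0.1), and power / fold-enrichment evaluation.

Haplotypes are generated by a first-order Markov chain along each LD block
with a target adjacent allelic correlation rho; an individual's genotype is
the sum of two independent haplotypes, so adjacent dosages inherit the same
correlation.  The reference panel is drawn from the same haplotype-frequency
model when the heterogeneity knob is 0, and from a model with a share of
LD-phase-rotated transitions otherwise — emulating the pattern-level LD
disagreement of an ancestry-mismatched reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ReferencePanel, hwe_pvalues
from .sumstats import HarmonizedDataset, SummaryDataset, delta_af_filter

logger = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Stated world of the simulation experiments.

    Defaults mirror the published design: a trait with 50 common causal
    variants explaining 20% of phenotypic variance, errors injected at 0.5%
    of variants per error type, genotyping-error rate f_error in
    {0.05, 0.1, 0.15}, and GWAS / reference samples of ~5,000 individuals
    (the reference size at which the truncated-SVD prediction is reliable).
    Block sizes (20-50 variants), adjacent haplotype correlation rho ~
    U(0.9, 0.96), 2 kb spacing (blocks span 40-100 kb) and MAF ~ U(0.01, 0.5) are this package's
    desk-scale emulation of sequence-density common-variant LD.  The high
    adjacent rho matters: in a first-order Markov chain, correlation decays
    geometrically with distance, so only a high adjacent value reproduces
    the multi-proxy tagging redundancy of real sequence data (where every
    common variant has several near-perfect LD partners — the reason the
    predictor-selection rule must exclude r^2 > 0.95 at all).  With weaker
    adjacent LD, a strongly associated variant whose flanking tags land in
    its own partition half is predicted poorly and its (1-leverage)-scaled
    statistic can cross the removal threshold — a desk-scale artifact, not a
    property of the method on sequence data.
    """

    n_gwas: int = 5000
    n_ref: int = 5000
    m: int = 5000
    block_size_range: tuple = (20, 50)
    rho_range: tuple = (0.9, 0.96)
    maf_range: tuple = (0.01, 0.5)
    m_causal: int = 50
    h2_total: float = 0.20
    f_variant_error: float = 0.005
    f_error: float = 0.10
    heterogeneity: float = 0.0
    bp_spacing: int = 2000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.h2_total < 1) and self.m_causal > 0:
            raise ValueError("h2_total must be in (0, 1)")
        if not (0 <= self.f_variant_error < 1):
            raise ValueError("f_variant_error must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    causal_effects: np.ndarray = field(default_factory=lambda: np.array([]))
    causal_ids: list = field(default_factory=list)
    allelic_error_ids: list = field(default_factory=list)
    genotyping_error_ids: list = field(default_factory=list)
    f_error: dict = field(default_factory=dict)
    clean_summary: SummaryDataset | None = None


@dataclass
class EvalReport:
    """Power / enrichment summary of a QC run against simulation truth."""

    power_allelic: float | None
    power_genotyping: float | None
    power_allelic_gwsig: float | None
    power_genotyping_gwsig: float | None
    removed_fraction: float
    fold_enrichment: float | None
    causal_loss_fraction: float | None


# ---------------------------------------------------------------------------
# Genotype generation
# ---------------------------------------------------------------------------

def _draw_blocks(cfg: SimConfig, rng) -> list[int]:
    lo, hi = cfg.block_size_range
    sizes = []
    left = cfg.m
    while left > 0:
        s = int(rng.integers(lo, hi + 1))
        sizes.append(min(s, left))
        left -= sizes[-1]
    return sizes


def _block_model(size: int, cfg: SimConfig, rng):
    """Per-site counted-allele frequencies and a feasible adjacent rho."""
    lo, hi = cfg.maf_range
    rho = float(rng.uniform(*cfg.rho_range))
    base = float(rng.uniform(lo, hi))
    freqs = np.clip(base + rng.normal(0.0, 0.02, size=size), lo, hi)
    # feasibility of the Markov transition for each adjacent pair; jitter the
    # next-site frequency toward the previous one when infeasible
    for j in range(1, size):
        p, q = freqs[j - 1], freqs[j]
        for _ in range(100):
            hi_t = q + rho * np.sqrt(q * (1 - q) * (1 - p) / p)
            lo_t = q - rho * np.sqrt(q * (1 - q) * p / (1 - p))
            if 0.0 <= lo_t and hi_t <= 1.0:
                break
            q = 0.5 * (q + p)
            freqs[j] = q
        else:
            logger.warning("infeasible (rho, MAF) pair; pinning site frequency")
            freqs[j] = p
    return freqs, rho


def _chromosome_model(cfg: SimConfig, rng):
    """Frequencies and per-transition rho for one chromosome-long chain.

    Within-block transitions carry the block's rho; transitions straddling a
    block boundary carry rho = 0, so blocks are mutually independent.
    """
    sizes = _draw_blocks(cfg, rng)
    freqs = np.empty(cfg.m)
    rho_t = np.zeros(max(cfg.m - 1, 0))
    start = 0
    for size in sizes:
        f, rho = _block_model(size, cfg, rng)
        freqs[start : start + size] = f
        if size > 1:
            rho_t[start : start + size - 1] = rho
        start += size
    return freqs, rho_t


def _sample_haplotypes(freqs: np.ndarray, rho, n_hap: int, rng) -> np.ndarray:
    """First-order Markov chain along the block, vectorised over haplotypes.

    ``rho`` is a scalar or a per-transition array (length ``len(freqs)-1``).
    Transition probabilities are clipped into [0, 1]; for the feasibility-
    adjusted frequencies produced by the block model the clip never binds.
    """
    size = len(freqs)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (max(size - 1, 0),))
    H = np.empty((n_hap, size), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, size):
        p, q = freqs[j - 1], freqs[j]
        r = rho[j - 1]
        t1 = np.clip(q + r * np.sqrt(q * (1 - q) * (1 - p) / p), 0.0, 1.0)
        t0 = np.clip(q - r * np.sqrt(q * (1 - q) * p / (1 - p)), 0.0, 1.0)
        prob = np.where(H[:, j - 1] == 1, t1, t0)
        H[:, j] = rng.random(n_hap) < prob
    return H


def _rotate_phase(rho_t: np.ndarray, eta: float, rng) -> np.ndarray:
    """LD-phase mismatch: flip the sign of a share of reference transitions.

    With probability 0.2 * ``eta`` each within-block transition of the
    reference model has its correlation sign inverted.  Through chain
    transitivity a single inverted link flips the sign of every correlation
    straddling it — the reference then asserts strong LD of the wrong phase,
    the signature of an ancestry-mismatched panel.  Sign rotation preserves
    LD magnitude; simply weakening reference LD would not do, because an
    attenuated reference shrinks predictions and *deflates* the discrepancy
    statistic rather than inflating it.
    """
    rho_ref = rho_t.copy()
    flip = (rng.random(len(rho_t)) < 0.2 * eta) & (rho_t != 0.0)
    rho_ref[flip] *= -1.0
    return rho_ref


def simulate_panel_pair(cfg: SimConfig, rng=None):
    """Generate a GWAS panel, a reference panel, and a truth skeleton.

    Both panels are drawn from the same haplotype-frequency model when
    ``cfg.heterogeneity`` is 0 (independent samples, matching LD in
    expectation).  A positive knob makes the reference an ancestry-diverged
    sister population whose LD *phase* differs: a share of within-block
    transitions (probability 0.2 x knob each) carries inverted correlation
    sign, so the reference asserts strong LD of the wrong direction for
    pairs straddling those links.  Confidently wrong reference LD is what
    inflates the discrepancy statistic on clean variants — the denominator
    1 - leverage stays small while the prediction points the wrong way — and
    the inflation grows with the knob.  For in-sample LD experiments simply
    reuse the GWAS panel as its own reference.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eta = cfg.heterogeneity
    freqs, rho_t = _chromosome_model(cfg, rng)
    # the counted allele is the minor or major allele at random; the label
    # flip is applied to dosages after sampling (2 - g) so it cannot perturb
    # the Markov transition feasibility, and it is shared between panels
    flip = rng.random(cfg.m) < 0.5

    Hg = _sample_haplotypes(freqs, rho_t, 2 * cfg.n_gwas, rng)
    G = (Hg[::2] + Hg[1::2]).astype(np.int8)
    G[:, flip] = 2 - G[:, flip]

    rho_ref = _rotate_phase(rho_t, eta, rng) if eta > 0 else rho_t
    Hr = _sample_haplotypes(freqs, rho_ref, 2 * cfg.n_ref, rng)
    Gref = (Hr[::2] + Hr[1::2]).astype(np.int8)
    Gref[:, flip] = 2 - Gref[:, flip]
    m = cfg.m
    pos = (np.arange(m, dtype=np.int64) + 1) * cfg.bp_spacing
    base_idx = rng.integers(0, 4, size=m)
    # the other allele is any non-identical, non-complementary base, keeping
    # simulated variants strand-unambiguous
    other = np.empty(m, dtype="U1")
    for i, b in enumerate(base_idx):
        choices = [c for c in range(4) if c != b and c != 3 - b]
        other[i] = _BASES[choices[rng.integers(0, len(choices))]]
    variants = pd.DataFrame(
        {
            "id": [f"snp{i+1:06d}" for i in range(m)],
            "chrom": cfg.chrom,
            "pos": pos,
            "a1": _BASES[base_idx],
            "a2": other,
        }
    )
    gwas = ReferencePanel(genotypes=G, variants=variants)
    ref = ReferencePanel(genotypes=Gref, variants=variants.copy())
    return gwas, ref, SimTruth()


# ---------------------------------------------------------------------------
# Phenotype and GWAS
# ---------------------------------------------------------------------------

def simulate_phenotype(
    panel: ReferencePanel, m_causal: int, h2_total: float, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quantitative trait from standardized causal genotypes.

    Causal effects are drawn from N(0,1) on standardized dosages; the genetic
    score is rescaled so its realized variance share is exactly ``h2_total``,
    and the residual noise is made empirically orthogonal to it.  Returns
    (phenotype, causal_idx, causal_effects).
    """
    if m_causal == 0:
        y = rng.normal(size=panel.n_samples)
        return y, np.array([], dtype=int), np.array([])
    if not (0 < h2_total < 1):
        raise ValueError("h2_total must be in (0, 1)")
    maf = panel.maf()
    common = np.where(maf >= 0.01)[0]
    if m_causal > len(common):
        raise ValueError("not enough common variants for the requested m_causal")
    causal = np.sort(rng.choice(common, size=m_causal, replace=False))
    effects = rng.normal(size=m_causal)
    X = panel.genotypes[:, causal].astype(np.float64)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    g = X @ effects
    g = g - g.mean()
    g *= np.sqrt(h2_total / g.var())
    e = rng.normal(size=panel.n_samples)
    e = e - e.mean()
    e -= g * (e @ g) / (g @ g)  # empirically orthogonal residual
    e *= np.sqrt((1.0 - h2_total) / e.var())
    y = g + e
    return y, causal, effects


def gwas_scan(panel: ReferencePanel, phenotype: np.ndarray) -> SummaryDataset:
    """Marginal GWAS: per-variant simple linear regression of y on dosage.

    Returns a SummaryDataset aligned to the panel (same ids, alleles and
    positions; freq is the panel's counted-allele frequency).  Monomorphic
    variants are dropped.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    n = len(y)
    if n != panel.n_samples:
        raise ValueError("phenotype length does not match panel samples")
    X = panel.genotypes.astype(np.float64)
    xm = X.mean(axis=0)
    yc = y - y.mean()
    sxx = (X * X).sum(axis=0) - n * xm**2
    poly = sxx > 0
    sxy = X.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        syy = float(yc @ yc)
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
    z = np.where(se > 0, beta / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    v = panel.variants
    df = pd.DataFrame(
        {
            "snp": v["id"].to_numpy(),
            "a1": v["a1"].to_numpy(),
            "a2": v["a2"].to_numpy(),
            "freq": panel.af,
            "b": beta,
            "se": se,
            "p": p,
            "n": n,
            "z": z,
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
        }
    )
    df = df[poly & np.isfinite(z)].reset_index(drop=True)
    return SummaryDataset(df=df, source="gwas_scan")


def harmonized_from_scan(summary: SummaryDataset, panel: ReferencePanel) -> HarmonizedDataset:
    """Fast path aligning a ``gwas_scan``/error-injected summary to a panel.

    Assumes ids match the panel and alleles are either identical or exactly
    swapped (the allelic-error case), which holds for simulator output; the
    general resolver in ``sumstats.harmonize`` covers arbitrary files.
    """
    pv = panel.variants
    lookup = pd.Series(np.arange(len(pv)), index=pv["id"].to_numpy())
    df = summary.df.copy()
    df["panel_index"] = lookup.reindex(df["snp"].to_numpy()).to_numpy()
    df = df[np.isfinite(df["panel_index"])].copy()
    df["panel_index"] = df["panel_index"].astype(int)
    panel_a1 = pv["a1"].to_numpy()[df["panel_index"]]
    swapped = df["a1"].to_numpy() != panel_a1
    df.loc[swapped, "z"] = -df.loc[swapped, "z"]
    df.loc[swapped, "b"] = -df.loc[swapped, "b"]
    df.loc[swapped, "freq"] = 1.0 - df.loc[swapped, "freq"]
    df["sign_flip"] = swapped
    df["palindromic"] = False
    df["freq_ref"] = panel.af[df["panel_index"]]
    df["delta_af"] = np.abs(df["freq"] - df["freq_ref"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return HarmonizedDataset(df=df)


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

def inject_allelic_errors(
    summary: SummaryDataset,
    fraction: float,
    rng,
    candidates: np.ndarray | None = None,
) -> tuple[SummaryDataset, list]:
    """Mislabel the effect allele at a random ``fraction`` of variants.

    The A1/A2 columns are swapped while the reported effect, frequency and
    P value are left untouched — the file now attributes the effect to the
    wrong allele.  Once such a record is harmonized to a reference panel,
    its z-score comes out negated and its frequency complemented relative to
    the truth (and delta-AF becomes |1-2f|, which is how the standard QC
    catches flips away from MAF 0.5).  Swapping the same variant twice
    restores the original record.

    The number altered is round(fraction * m).  ``candidates`` optionally
    restricts the draw (e.g. to genome-wide-significant variants).  Returns
    the altered dataset and the flipped variant ids.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    df = summary.df.copy()
    pool = np.arange(len(df)) if candidates is None else np.asarray(candidates)
    n_flip = min(int(round(fraction * len(df))), len(pool))
    chosen = rng.choice(pool, size=n_flip, replace=False) if n_flip else np.array([], dtype=int)
    a1 = df["a1"].to_numpy().copy()
    a2 = df["a2"].to_numpy().copy()
    a1[chosen], a2[chosen] = a2[chosen], a1[chosen].copy()
    df["a1"], df["a2"] = a1, a2
    flipped_ids = df["snp"].to_numpy()[np.sort(chosen)].tolist()
    return SummaryDataset(df=df, source=summary.source), flipped_ids


def inject_genotyping_errors(
    panel: ReferencePanel,
    variant_fraction: float,
    f_error: float,
    rng,
) -> tuple[ReferencePanel, list]:
    """Corrupt genotypes at a random ``variant_fraction`` of variants.

    At each selected variant, a random ``f_error`` share of individuals have
    their dosage replaced by a Binomial(2, AF) draw conditioned to differ from
    the current value — approximately AF-preserving but LD-breaking, which is
    the signature the discrepancy test exploits.  Returns the corrupted panel
    (a copy) and the affected variant ids; re-run ``gwas_scan`` on it to
    obtain the erroneous summary statistics.
    """
    if not (0 <= f_error < 1):
        raise ValueError("f_error must be in [0, 1)")
    g = panel.genotypes.copy()
    m = panel.n_variants
    n = panel.n_samples
    n_var = int(round(variant_fraction * m))
    chosen = np.sort(rng.choice(m, size=n_var, replace=False)) if n_var else np.array([], dtype=int)
    af = panel.af
    n_ind = int(round(f_error * n))
    for j in chosen:
        if n_ind == 0:
            continue
        rows = rng.choice(n, size=n_ind, replace=False)
        p = float(af[j])
        pmf = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        cur = g[rows, j]
        new = np.empty(n_ind, dtype=np.int8)
        for val in (0, 1, 2):
            sel = cur == val
            if not sel.any():
                continue
            probs = pmf.copy()
            probs[val] = 0.0
            probs = probs / probs.sum()
            new[sel] = rng.choice(3, size=int(sel.sum()), p=probs)
        g[rows, j] = new
    ids = panel.variants["id"].to_numpy()[chosen].tolist()
    return ReferencePanel(genotypes=g, variants=panel.variants.copy()), ids


# ---------------------------------------------------------------------------
# Standard QC and evaluation
# ---------------------------------------------------------------------------

def standard_qc(
    h: HarmonizedDataset,
    gwas_panel: ReferencePanel | None = None,
    hwe_threshold: float = 1e-6,
    delta_af_threshold: float = 0.1,
) -> tuple[HarmonizedDataset, dict]:
    """Pre-QC: HWE on individual-level data (when available), then delta-AF.

    A variant failing both filters is attributed to HWE (the first applied).
    Returns the surviving dataset and a removal tally per filter.
    """
    tally = {"hwe": 0, "delta_af": 0}
    out = h
    if gwas_panel is not None:
        pvals = hwe_pvalues(gwas_panel)
        bad = pvals[out.df["panel_index"].to_numpy()] < hwe_threshold
        tally["hwe"] = int(bad.sum())
        out = HarmonizedDataset(df=out.df[~bad].reset_index(drop=True))
    out, removed = delta_af_filter(out, delta_af_threshold)
    tally["delta_af"] = len(removed)
    return out, tally


def evaluate(
    results: pd.DataFrame,
    truth: SimTruth,
    gwsig_threshold: float = 5e-8,
) -> EvalReport:
    """Power, fold enrichment and causal-loss from a QC run.

    Power per error type is the fraction of injected-error variants present
    in ``results`` (i.e. surviving any upstream QC) that were removed; the
    genome-wide-significant variants' power restricts to P_GWAS < 5e-8 as
    reconstructed from |z_obs|.  Fold enrichment is the true-error rate among
    removed variants divided by the true-error rate among all tested
    variants.
    """
    ids = results["variant_id"].to_numpy()
    removed = results["removed"].to_numpy().astype(bool)
    zabs = np.abs(results["z_obs"].to_numpy())
    z_gwsig = stats.norm.isf(gwsig_threshold / 2.0)
    gwsig = zabs > z_gwsig

    def _power(error_ids, mask=None):
        sel = np.isin(ids, list(error_ids))
        if mask is not None:
            sel &= mask
        denom = int(sel.sum())
        if denom == 0:
            return None
        return float(removed[sel].sum() / denom)

    error_ids = set(truth.allelic_error_ids) | set(truth.genotyping_error_ids)
    is_error = np.isin(ids, list(error_ids))
    n_removed = int(removed.sum())
    if n_removed > 0 and is_error.mean() > 0:
        fold = float((is_error & removed).sum() / n_removed / is_error.mean())
    elif n_removed == 0:
        fold = 0.0
    else:
        fold = None

    causal_loss = None
    if len(truth.causal_ids):
        sel = np.isin(ids, list(truth.causal_ids))
        if sel.sum():
            causal_loss = float(removed[sel].sum() / sel.sum())

    return EvalReport(
        power_allelic=_power(truth.allelic_error_ids),
        power_genotyping=_power(truth.genotyping_error_ids),
        power_allelic_gwsig=_power(truth.allelic_error_ids, gwsig),
        power_genotyping_gwsig=_power(truth.genotyping_error_ids, gwsig),
        removed_fraction=float(removed.mean()) if len(removed) else 0.0,
        fold_enrichment=fold,
        causal_loss_fraction=causal_loss,
    )
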
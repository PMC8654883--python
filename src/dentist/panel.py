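"""Reference genotype panels: PLINK 1 I/O, allele frequencies, HWE and LD.

The panel is the source of the LD correlation matrix R used to predict each
variant's z-score from its neighbours.  Genotypes are additive dosages of the
counted allele (A1), stored as int8 with -1 marking missing hard calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 bed, SNP-major

# 2-bit code -> A1 dosage: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


@dataclass
class ReferencePanel:
    """Genotype matrix (n_samples x m variants) plus variant metadata.

    ``variants`` columns: id, chrom, pos, a1 (counted allele), a2.
    """

    genotypes: np.ndarray  # int8, -1 = missing
    variants: pd.DataFrame

    def __post_init__(self):
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError("variant metadata length does not match genotype columns")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def af(self) -> np.ndarray:
        """Counted-allele frequency over non-missing entries (NaN if all missing)."""
        g = self.genotypes
        miss = g < 0
        counts = (g.shape[0] - miss.sum(axis=0)).astype(float)
        total = np.where(miss, 0, g).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, total / (2.0 * counts), np.nan)

    @property
    def missingness(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=0)

    def maf(self) -> np.ndarray:
        af = self.af
        return np.minimum(af, 1.0 - af)


@dataclass
class LDWindow:
    """A window's LD correlation matrix over its member variants."""

    window_id: int
    start: int
    end: int
    members: np.ndarray  # panel column indices, sorted by position
    R: np.ndarray  # correlation matrix, unit diagonal


@dataclass
class TruncatedEigen:
    """Rank-truncated eigendecomposition of an LD matrix R_tt.

    ``w`` holds the retained k eigenvalues in descending order, ``V`` the
    corresponding orthonormal eigenvectors as columns.  ``q`` is the effective
    rank of the full matrix and ``theta_k = k/q`` the retained proportion.
    """

    w: np.ndarray
    V: np.ndarray
    k: int
    q: int
    theta_k: float


# ---------------------------------------------------------------------------
# PLINK 1 binary I/O
# ---------------------------------------------------------------------------

def read_plink(prefix) -> ReferencePanel:
    """Read a PLINK 1 bed/bim/fam file triple given the shared path prefix.

    The bed file must be in SNP-major mode (the PLINK 1.9 default).  The bim
    A1 allele is the counted allele: dosage 2 means two copies of A1.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not PLINK 1 SNP-major bed)")
    bytes_per_var = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_var * m:
        raise ValueError(
            f"{prefix}.bed: size {body.size} does not match {n} samples x {m} variants"
        )
    codes = body.reshape(m, bytes_per_var)
    # unpack 2-bit fields, little-endian within each byte
    expanded = np.empty((m, bytes_per_var * 4), dtype=np.uint8)
    for shift in range(4):
        expanded[:, shift::4] = (codes >> (2 * shift)) & 0b11
    geno = _CODE_TO_DOSAGE[expanded[:, :n]].T.copy()  # n x m

    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return ReferencePanel(genotypes=geno, variants=variants)


def write_plink(panel: ReferencePanel, prefix) -> None:
    """Write a panel as PLINK 1 bed/bim/fam (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = panel.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    n = panel.n_samples
    fam = pd.DataFrame(
        {
            "fid": [f"F{i+1}" for i in range(n)],
            "iid": [f"I{i+1}" for i in range(n)],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    g = panel.genotypes
    code = np.empty_like(g, dtype=np.uint8)
    for dosage, c in _DOSAGE_TO_CODE.items():
        code[g == dosage] = c
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.ones((pad, g.shape[1]), dtype=np.uint8)])  # 01 = missing
    codeT = code.T  # m x padded-n
    packed = (
        codeT[:, 0::4]
        | (codeT[:, 1::4] << 2)
        | (codeT[:, 2::4] << 4)
        | (codeT[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Per-variant statistics
# ---------------------------------------------------------------------------

def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg goodness-of-fit P value from genotype counts.

    1-df chi-squared test of the observed (hom, het, hom) counts against the
    proportions expected at the observed allele frequency.  Monomorphic sites
    have no definable heterozygote deficit and return P = 1 by convention.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("zero total genotype count")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(panel: ReferencePanel) -> np.ndarray:
    """Vectorised HWE P values for every variant in a panel."""
    g = panel.genotypes
    n_bb = (g == 0).sum(axis=0).astype(float)
    n_ab = (g == 1).sum(axis=0).astype(float)
    n_aa = (g == 2).sum(axis=0).astype(float)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n)
        exp_aa = n * p**2
        exp_ab = 2 * n * p * (1 - p)
        exp_bb = n * (1 - p) ** 2
        chi2 = (
            (n_aa - exp_aa) ** 2 / exp_aa
            + (n_ab - exp_ab) ** 2 / exp_ab
            + (n_bb - exp_bb) ** 2 / exp_bb
        )
    pvals = stats.chi2.sf(chi2, df=1)
    mono = (p <= 0) | (p >= 1) | ~np.isfinite(chi2)
    pvals = np.where(mono, 1.0, pvals)
    return pvals


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def standardized_dosages(panel: ReferencePanel, indices: np.ndarray) -> np.ndarray:
    """Mean-imputed, standardized dosage matrix for the given columns.

    Missing hard calls are replaced by the variant mean before
    standardization, which keeps the resulting correlation matrix positive
    semi-definite (pairwise-complete correlations need not be).
    Standardization uses the sample mean/SD, not 2p(1-p).
    """
    g = panel.genotypes[:, indices].astype(np.float64)
    miss = g < 0
    if miss.any():
        g[miss] = np.nan
        means = np.nanmean(g, axis=0)
        inds = np.where(miss)
        g[inds] = means[inds[1]]
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance column after imputation")
    return (g - mu) / sd


def compute_ld(
    panel: ReferencePanel,
    members: np.ndarray,
    window_id: int = 0,
    start: int | None = None,
    end: int | None = None,
) -> LDWindow:
    """Pearson LD correlation matrix over the given panel columns.

    Zero-variance (monomorphic after imputation) columns are excluded with a
    warning.  The diagonal is forced to exactly 1.
    """
    members = np.asarray(members)
    g = panel.genotypes[:, members].astype(np.float64)
    miss = g < 0
    if miss.any():
        g[miss] = np.nan
        means = np.nanmean(g, axis=0)
        inds = np.where(miss)
        g[inds] = means[inds[1]]
    sd = g.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("excluding %d zero-variance variants from LD window", int((~keep).sum()))
        members = members[keep]
        g = g[:, keep]
    if len(members) < 2:
        raise ValueError("an LD window needs at least 2 polymorphic members")
    R = np.corrcoef(g, rowvar=False)
    np.fill_diagonal(R, 1.0)
    pos = panel.variants["pos"].to_numpy()[members]
    order = np.argsort(pos, kind="stable")
    members = members[order]
    R = R[np.ix_(order, order)]
    if start is None:
        start = int(pos.min())
    if end is None:
        end = int(pos.max())
    return LDWindow(window_id=window_id, start=start, end=end, members=members, R=R)


# ---------------------------------------------------------------------------
# Truncated eigendecomposition of R_tt
# ---------------------------------------------------------------------------

def truncated_eigen(
    R_tt: np.ndarray,
    theta_k: float = 0.5,
    eps_rank: float = 1e-8,
    assume_symmetric: bool = False,
) -> TruncatedEigen:
    """Rank-truncated eigendecomposition used to pseudo-invert R_tt.

    The effective rank q counts eigenvalues above ``eps_rank`` times the
    largest; k = max(1, floor(theta_k * q)) top eigenpairs are retained.
    theta_k = 0.5 is the practical default: LD matrices estimated from a
    reference sample are near rank-deficient and the trailing eigenspace is
    dominated by sampling noise.  ``assume_symmetric`` skips the symmetry
    validation for callers (like the pipeline's inner loop) that construct
    R_tt as a principal submatrix of a correlation matrix.
    """
    R_tt = np.asarray(R_tt, dtype=np.float64)
    if R_tt.ndim != 2 or R_tt.shape[0] != R_tt.shape[1]:
        raise ValueError("R_tt must be square")
    if not assume_symmetric and not np.allclose(R_tt, R_tt.T, atol=1e-8):
        raise ValueError("R_tt is not symmetric")
    w, V = np.linalg.eigh(R_tt)
    w = w[::-1]
    V = V[:, ::-1]
    wmax = max(w[0], 0.0)
    if wmax <= 0:
        raise ValueError("R_tt has no positive eigenvalues")
    q = int((w > eps_rank * wmax).sum())
    k = max(1, int(np.floor(theta_k * q)))
    k = min(k, q)
    return TruncatedEigen(w=w[:k].copy(), V=V[:, :k].copy(), k=k, q=q, theta_k=theta_k)


def quad_forms(
    te: TruncatedEigen, R_it: np.ndarray, z_t: np.ndarray
) -> tuple[float, float]:
    """The two pseudo-inverse quadratic forms of the prediction model.

    prediction_term = sum_j (1/w_j)(R_it v_j)(v_j' z_t)  -> R_it R_tt^+ z_t
    leverage_term   = sum_j (1/w_j)(R_it v_j)^2          -> R_it R_tt^+ R_it'

    Both sums run over the retained eigenpairs only.
    """
    R_it = np.asarray(R_it, dtype=np.float64).ravel()
    z_t = np.asarray(z_t, dtype=np.float64).ravel()
    a = R_it @ te.V  # (k,)
    b = te.V.T @ z_t  # (k,)
    prediction = float(np.sum(a * b / te.w))
    leverage = float(np.sum(a * a / te.w))
    return prediction, leverage
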
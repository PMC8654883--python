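"""The discrepancy statistic: windows, partitions, predictors, and T_d.

Each variant i is tested by contrasting its observed z-score z_i with the
value predicted from the z-scores of an array of other variants t through
reference LD:

    z_pred_i = R_it R_tt^{-1} z_t
    T_d(i)   = (z_i - z_pred_i)^2 / (1 - R_it R_tt^{-1} R_it')

Under consistency between the summary data and the LD reference, T_d follows
approximately a chi-squared distribution with 1 degree of freedom.  R_tt is
pseudo-inverted through a rank-truncated eigendecomposition (see
``panel.truncated_eigen``); variants in near-perfect LD with the target
(r^2 > 0.95) are excluded from t for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import TruncatedEigen, quad_forms

#: Default sliding-window geometry: 2 Mb windows, 500 kb overlap.
WINDOW_BP = 2_000_000
OVERLAP_BP = 500_000

#: Predictors in near-perfect LD with the target are excluded above this r^2.
R2_CAP = 0.95

#: Floor for the T_d denominator, guarding leverage ~ 1 after truncation noise.
DENOM_FLOOR = 1e-6


@dataclass
class WindowPlan:
    """Sliding windows over one or more chromosomes plus variant assignment.

    ``windows`` rows are (window_id, chrom, start, end); ``assignment`` maps
    each variant to the single window whose center is nearest (ties broken
    toward the earlier window), so every variant is tested exactly once while
    overlapping windows give it predictors on both sides.
    """

    windows: list  # (window_id, chrom, start, end)
    assignment: np.ndarray  # per-variant window_id

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def segment_windows(
    chroms: np.ndarray,
    positions: np.ndarray,
    window_bp: int = WINDOW_BP,
    overlap_bp: int = OVERLAP_BP,
) -> WindowPlan:
    """Tile each chromosome with overlapping windows and assign variants.

    Windows of width ``window_bp`` advance by ``window_bp - overlap_bp``
    starting at the chromosome's first variant position; the last window is
    truncated at the chromosome end.  ``positions`` must be sorted within
    each chromosome.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    if window_bp <= overlap_bp:
        raise ValueError("window_bp must exceed overlap_bp")
    step = window_bp - overlap_bp

    windows = []
    assignment = np.full(len(positions), -1, dtype=np.int64)
    wid = 0
    # preserve first-appearance chromosome order
    seen, chrom_order = set(), []
    for c in chroms:
        if c not in seen:
            seen.add(c)
            chrom_order.append(c)
    for c in chrom_order:
        mask = chroms == c
        pos = positions[mask]
        if len(pos) == 0:
            continue
        lo, hi = int(pos.min()), int(pos.max())
        starts = []
        s = lo
        while s <= hi:
            starts.append(s)
            s += step
        chrom_windows = []
        for s in starts:
            e = min(s + window_bp - 1, hi)
            chrom_windows.append((wid, c, s, e))
            wid += 1
        windows.extend(chrom_windows)
        # nearest nominal center, ties to the earlier window, restricted to
        # windows that actually cover the variant
        centers = np.array([s + window_bp / 2.0 for (_, _, s, _) in chrom_windows])
        w_start = np.array([s for (_, _, s, _) in chrom_windows])
        w_end = np.array([e for (_, _, _, e) in chrom_windows])
        wids = np.array([w for (w, _, _, _) in chrom_windows])
        idx = np.where(mask)[0]
        for j, p in zip(idx, pos):
            covering = np.where((w_start <= p) & (p <= w_end))[0]
            if len(covering) == 0:  # truncated tail: fall back to nearest center
                covering = np.arange(len(chrom_windows))
            d = np.abs(centers[covering] - p)
            assignment[j] = wids[covering[np.argmin(d)]]
    return WindowPlan(windows=windows, assignment=assignment)


def make_partition(members: np.ndarray, rng: np.random.Generator):
    """Randomly split window members into two near-equal halves S1, S2.

    Deterministic given the generator state; |S1| = floor(n/2).
    """
    members = np.asarray(members)
    if len(members) < 2:
        raise ValueError("need at least 2 members to partition")
    perm = rng.permutation(len(members))
    half = len(members) // 2
    s1 = np.sort(members[perm[:half]])
    s2 = np.sort(members[perm[half:]])
    return s1, s2


def select_predictors(
    r_row: np.ndarray,
    candidates: np.ndarray,
    r2_cap: float = R2_CAP,
    max_predictors: int | None = None,
) -> np.ndarray:
    """Choose the predictor set t for one target variant.

    ``r_row`` holds the target's LD correlation with each candidate.
    Candidates in near-perfect LD (r^2 strictly above ``r2_cap``) are
    excluded; if more than ``max_predictors`` remain, those with the largest
    |r| to the target are kept.  Returns candidate indices in original order.
    """
    r_row = np.asarray(r_row, dtype=np.float64)
    candidates = np.asarray(candidates)
    keep = r_row**2 <= r2_cap
    kept = candidates[keep]
    if max_predictors is not None and len(kept) > max_predictors:
        absr = np.abs(r_row[keep])
        top = np.argsort(-absr, kind="stable")[:max_predictors]
        kept = kept[np.sort(top)]
    return kept


def dentist_stat(
    z_i: float,
    z_t: np.ndarray,
    R_it: np.ndarray,
    te: TruncatedEigen,
    denom_floor: float = DENOM_FLOOR,
) -> tuple[float, float, float]:
    """Observed-vs-predicted z-score test for one variant.

    Returns (z_pred, T_d, P).  T_d = (z_i - z_pred)^2 / max(1 - leverage,
    denom_floor) is referred to the upper tail of chi-squared(1).  Non-finite
    inputs raise; callers flag such variants instead of testing them.
    """
    if not np.isfinite(z_i) or not np.all(np.isfinite(z_t)):
        raise ValueError("non-finite z-scores passed to dentist_stat")
    z_pred, leverage = quad_forms(te, R_it, z_t)
    denom = max(1.0 - leverage, denom_floor)
    t_d = (z_i - z_pred) ** 2 / denom
    p = chi2_sf1(t_d)
    return z_pred, t_d, p


def chi2_sf1(t_d: float) -> float:
    """Upper tail of chi-squared(1), safe for very large statistics.

    scipy's sf is accurate down to the smallest normal double; beyond that
    (T_d around 1400) the tail underflows and we return the smallest
    subnormal instead of 0 so that P is always in (0, 1].  Threshold
    comparisons should be done on the T_d scale (see ``chi2_isf1``).
    """
    p = float(stats.chi2.sf(t_d, df=1))
    if p == 0.0:
        return float(np.nextafter(0.0, 1.0))
    return p


def chi2_isf1(alpha: float) -> float:
    """T_d value whose chi-squared(1) upper tail equals ``alpha``."""
    return float(stats.chi2.isf(alpha, df=1))
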
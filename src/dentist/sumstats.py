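"""Reading, validation and allele harmonization of GWAS summary statistics.

The input dialect is the COJO ``.ma`` text format: whitespace-delimited with
a header line ``SNP A1 A2 freq b se p N`` (case-insensitive), where A1 is the
effect allele, ``freq`` its frequency, ``b``/``se`` the per-allele effect and
its standard error, ``p`` the association P value and ``N`` the sample size.

Harmonization relabels every summary record onto the reference panel's
counted allele so that the z-score vector and the LD correlation matrix refer
to the same alleles.  An effect-allele swap negates z and complements the
frequency; strand flips are resolved through base complements; palindromic
(A/T, C/G) variants are strand-ambiguous and are kept with a flag by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_MA_FIELDS = ["snp", "a1", "a2", "freq", "b", "se", "p", "n"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Report columns, in output order.
REPORT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "z_obs",
    "z_pred",
    "T_d",
    "P_DENTIST",
    "removed",
    "removal_iteration",
    "window_id",
]


@dataclass
class SummaryDataset:
    """Per-variant GWAS summary results.

    ``df`` columns: snp, a1, a2, freq, b, se, p, n, z and, when known,
    chrom / pos (1-based).  Sorted by (chrom, pos) when positions are present.
    """

    df: pd.DataFrame
    n_invalid: int = 0
    source: str | None = None

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def has_positions(self) -> bool:
        return "chrom" in self.df.columns and "pos" in self.df.columns


@dataclass
class HarmonizedDataset:
    """Summary data aligned to a reference panel's counted alleles.

    ``df`` carries the summary columns (z and freq already relabelled onto
    the panel's counted allele) plus ``panel_index``, ``sign_flip``,
    ``palindromic``, ``freq_ref`` and ``delta_af``.
    """

    df: pd.DataFrame
    n_unmatched: int = 0
    n_dropped_palindromic: int = 0

    @property
    def n_variants(self) -> int:
        return len(self.df)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def read_ma(path, variant_map: pd.DataFrame | None = None) -> SummaryDataset:
    """Read a COJO ``.ma`` summary-statistics file.

    Parameters
    ----------
    path
        Whitespace-delimited text file with header ``SNP A1 A2 freq b se p N``
        (case-insensitive).
    variant_map
        Optional DataFrame with columns ``snp, chrom, pos`` supplying genomic
        coordinates; otherwise positions are attached at harmonization time
        from the reference panel.

    Rows failing validation (se <= 0, freq outside (0,1), p outside (0,1],
    n <= 0, non-finite values) are dropped and tallied in ``n_invalid``.
    Duplicate variant ids keep the first occurrence.  A z/p inconsistency
    beyond relative 1e-3 is warned about, not dropped (GWAS files often carry
    truncated P values).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _MA_FIELDS:
        if col not in df.columns:
            raise ValueError(f"summary file {path} is missing mandatory column {col.upper()!r}")
    df = df[_MA_FIELDS].copy()
    for col in ("freq", "b", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()

    n_raw = len(df)
    valid = (
        np.isfinite(df["freq"])
        & np.isfinite(df["b"])
        & np.isfinite(df["se"])
        & np.isfinite(df["p"])
        & np.isfinite(df["n"])
        & (df["freq"] > 0)
        & (df["freq"] < 1)
        & (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & (df["n"] > 0)
        & (df["a1"] != df["a2"])
    )
    df = df[valid].copy()

    dup = df["snp"].duplicated(keep="first")
    if dup.any():
        logger.warning("%d duplicated variant ids dropped (kept first occurrence)", int(dup.sum()))
        df = df[~dup].copy()

    if len(df) == 0:
        raise ValueError(f"summary file {path} contains no valid rows")

    df["z"] = df["b"] / df["se"]

    # warn-only consistency check between |z| and the reported two-sided P
    z_from_p = stats.norm.isf(np.clip(df["p"].to_numpy(), 1e-300, 1.0) / 2.0)
    zabs = np.abs(df["z"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(zabs - z_from_p) / np.maximum(z_from_p, 1e-12)
    inconsistent = (rel > 1e-3) & (df["p"].to_numpy() < 0.999)
    if inconsistent.any():
        logger.warning(
            "%d variants have |b/se| inconsistent with the reported P value "
            "(kept; P values may be truncated)",
            int(inconsistent.sum()),
        )

    if variant_map is not None:
        vm = variant_map[["snp", "chrom", "pos"]].astype({"snp": str})
        df = df.merge(vm, on="snp", how="left")
        df = df.sort_values(["chrom", "pos"], kind="stable")

    df = df.reset_index(drop=True)
    return SummaryDataset(df=df, n_invalid=int(n_raw - valid.sum()), source=str(path))


def write_ma(summary: SummaryDataset, path) -> None:
    """Write a SummaryDataset back to the ``.ma`` dialect (6 significant digits)."""
    out = summary.df[_MA_FIELDS].copy()
    out.columns = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _resolve_alleles(a1, a2, b1, b2):
    """Classify a summary allele pair against a panel allele pair.

    Returns (matched, sign_flip, strand_flip).  The panel counts b1.
    """
    if a1 == b1 and a2 == b2:
        return True, False, False
    if a1 == b2 and a2 == b1:
        return True, True, False
    c1, c2 = COMPLEMENT.get(a1), COMPLEMENT.get(a2)
    if c1 == b1 and c2 == b2:
        return True, False, True
    if c1 == b2 and c2 == b1:
        return True, True, True
    return False, False, False


def harmonize(
    summary: SummaryDataset,
    panel,
    drop_palindromic_ambiguous: bool = False,
) -> HarmonizedDataset:
    """Align summary statistics to a reference panel's counted alleles.

    Variants are matched by id first and by (chrom, pos) as a fallback when
    the summary data carry positions.  Allele pairs are then compared: exact
    match is kept as-is; a swapped pair negates z and complements the
    frequency; complement / swapped-complement pairs are strand flips resolved
    the same way.  Palindromic (A/T, C/G) variants are strand-ambiguous: kept
    with ``palindromic=True``, or dropped when ``drop_palindromic_ambiguous``
    is set and min(freq, 1-freq) > 0.4.  Multi-allelic panel sites (duplicate
    id or position) are skipped entirely.

    Raises ``ValueError`` when fewer than 50% of summary variants match —
    usually a genome-build mismatch.
    """
    pv = panel.variants.copy()
    pv["panel_index"] = np.arange(len(pv))
    # multi-allelic / duplicated panel sites are skipped entirely
    multi = pv.duplicated(["chrom", "pos"], keep=False) | pv.duplicated("id", keep=False)
    pv = pv[~multi]

    sdf = summary.df.copy()
    matched = sdf.merge(
        pv[["id", "panel_index", "chrom", "pos", "a1", "a2"]].rename(
            columns={"id": "snp", "chrom": "chrom_panel", "pos": "pos_panel",
                     "a1": "panel_a1", "a2": "panel_a2"}
        ),
        on="snp",
        how="inner",
    )
    if summary.has_positions():
        leftover = sdf[~sdf["snp"].isin(matched["snp"])]
        by_pos = leftover.merge(
            pv[["id", "panel_index", "chrom", "pos", "a1", "a2"]].rename(
                columns={"a1": "panel_a1", "a2": "panel_a2"}
            ),
            on=["chrom", "pos"],
            how="inner",
            suffixes=("", "_panel"),
        )
        by_pos["chrom_panel"] = by_pos["chrom"]
        by_pos["pos_panel"] = by_pos["pos"]
        matched = pd.concat(
            [matched, by_pos[matched.columns]], ignore_index=True
        )

    n_summary = len(sdf)
    keep_rows = []
    n_drop_palin = 0
    for row in matched.itertuples(index=False):
        ok, sign_flip, _strand = _resolve_alleles(row.a1, row.a2, row.panel_a1, row.panel_a2)
        if not ok:
            continue
        palin = _is_palindromic(row.a1, row.a2)
        if palin and drop_palindromic_ambiguous and min(row.freq, 1 - row.freq) > 0.4:
            n_drop_palin += 1
            continue
        keep_rows.append((row, sign_flip, palin))

    if n_summary > 0 and len(keep_rows) + n_drop_palin < 0.5 * n_summary:
        raise ValueError(
            f"only {len(keep_rows)}/{n_summary} summary variants matched the panel "
            "(likely genome-build or dataset mismatch)"
        )

    records = []
    af = panel.af
    for row, sign_flip, palin in keep_rows:
        z = -row.z if sign_flip else row.z
        b = -row.b if sign_flip else row.b
        freq = 1.0 - row.freq if sign_flip else row.freq
        freq_ref = af[row.panel_index]
        records.append(
            {
                "snp": row.snp,
                "chrom": row.chrom_panel,
                "pos": int(row.pos_panel),
                "a1": row.panel_a1,
                "a2": row.panel_a2,
                "freq": freq,
                "b": b,
                "se": row.se,
                "p": row.p,
                "n": row.n,
                "z": z,
                "panel_index": int(row.panel_index),
                "sign_flip": bool(sign_flip),
                "palindromic": bool(palin),
                "freq_ref": float(freq_ref),
                "delta_af": abs(freq - float(freq_ref)),
            }
        )
    hdf = pd.DataFrame(records)
    if len(hdf):
        hdf = hdf.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return HarmonizedDataset(
        df=hdf,
        n_unmatched=n_summary - len(keep_rows) - n_drop_palin,
        n_dropped_palindromic=n_drop_palin,
    )


def delta_af_filter(
    h: HarmonizedDataset, threshold: float = 0.1
) -> tuple[HarmonizedDataset, list]:
    """Drop variants whose |summary AF - reference AF| exceeds ``threshold``.

    The 0.1 default is the standard pre-QC cut applied alongside the HWE
    filter.  Returns the filtered dataset and the removed variant ids,
    preserving order.
    """
    bad = h.df["delta_af"].to_numpy() > threshold
    removed = h.df.loc[bad, "snp"].tolist()
    out = h.df[~bad].reset_index(drop=True)
    return (
        HarmonizedDataset(df=out, n_unmatched=h.n_unmatched,
                          n_dropped_palindromic=h.n_dropped_palindromic),
        removed,
    )


def write_report(results: pd.DataFrame, path) -> None:
    """Write the per-variant QC report as TSV.

    Columns: variant_id, chrom, pos, z_obs, z_pred, T_d, P_DENTIST,
    removed (0/1), removal_iteration (-1 if kept), window_id; rows ordered by
    (chrom, pos) for bit-stable output.
    """
    df = results.copy()
    if len(df):
        df = df.sort_values(["chrom", "pos"], kind="stable")
    df = df[REPORT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
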
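"""End-to-end file workflow: PLINK + .ma in, TSV report out.

Writes a simulated reference panel as PLINK bed/bim/fam and the GWAS results
as a COJO-style .ma text file, then reads both back, harmonizes alleles,
applies the standard pre-filters (delta-AF), runs the QC and writes the
per-variant report — the same round trip a user with real files would make.
"""

import tempfile
from pathlib import Path

import numpy as np

from dentist import (
    QCParams,
    SimConfig,
    delta_af_filter,
    gwas_scan,
    harmonize,
    read_ma,
    read_plink,
    run_dentist,
    simulate_panel_pair,
    simulate_phenotype,
    write_ma,
    write_manifest,
    write_plink,
    write_report,
)

cfg = SimConfig(n_gwas=3000, n_ref=3000, m=800, m_causal=10, seed=7)
rng = np.random.default_rng(cfg.seed)
gwas_panel, ref_panel, _ = simulate_panel_pair(cfg, rng)
y, _, _ = simulate_phenotype(gwas_panel, cfg.m_causal, cfg.h2_total, rng)
summary = gwas_scan(gwas_panel, y)

workdir = Path(tempfile.mkdtemp())
write_plink(ref_panel, workdir / "reference")
write_ma(summary, workdir / "trait.ma")
print(f"wrote {workdir}/reference.{{bed,bim,fam}} and {workdir}/trait.ma")

panel = read_plink(workdir / "reference")
summary = read_ma(workdir / "trait.ma")
harmonized = harmonize(summary, panel)
print(f"harmonized: {harmonized.n_variants} variants matched, "
      f"{harmonized.n_unmatched} unmatched")

harmonized, removed_af = delta_af_filter(harmonized, 0.1)
print(f"delta-AF > 0.1 filter removed {len(removed_af)} variants")

params = QCParams(seed=cfg.seed)
results, state = run_dentist(harmonized, panel, params)
write_report(results, workdir / "trait.dentist.tsv")
write_manifest(
    workdir / "trait.manifest.json",
    params,
    input_paths={"sumstats": workdir / "trait.ma", "bed": workdir / "reference.bed"},
    counts={"tested": int(len(results)), "removed": int(results["removed"].sum())},
)
print(f"report: {workdir}/trait.dentist.tsv  "
      f"({int(results['removed'].sum())} of {len(results)} variants flagged for removal)")
print(f"manifest with input checksums and the master seed: {workdir}/trait.manifest.json")
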
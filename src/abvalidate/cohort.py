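"""Cohort-level re-tally of orthogonal validation counts.

This is the only module meant to touch externally supplied study tables
(antibody band-intensity matrices plus matching PRM/TMT/RNA panels). When the
expected files are not present in the data directory it reports
``data unavailable`` instead of failing, so the rest of the package builds and
tests on synthetic data alone.

Expected files in the data directory (TSV, see ``read_abundance_panel`` for
the matrix layout):

* ``wb.tsv`` — antibodies x samples dominant-band intensities
* ``prm.tsv`` / ``tmt.tsv`` — proteins x samples orthogonal panels
* ``rna.tsv`` — genes x samples TPM panel for the same samples
* ``assignments.tsv`` — columns antibody_id, gene, platform (prm|tmt)
* ``rna_genomewide.tsv`` (optional) — genes x cell lines TPM matrix for the
  expressed-gene count

A ``schema.yaml`` in the directory may remap any of these file names
(``{wb: myfile.tsv, ...}``) since supplementary spreadsheet layouts vary.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import AbundancePanel, MeasurementKind, PillarConfig, PillarStatus
from .errors import DataValueError
from .io import read_abundance_panel
from .pillars import SeriesPair, orthogonal_validate

__all__ = ["CohortResult", "reproduce_orthogonal_counts", "count_expressed_genes", "run_reproduction"]

_DEFAULT_FILES = {
    "wb": "wb.tsv",
    "prm": "prm.tsv",
    "tmt": "tmt.tsv",
    "rna": "rna.tsv",
    "assignments": "assignments.tsv",
    "rna_genomewide": "rna_genomewide.tsv",
}


@dataclass
class CohortResult:
    """Tallies of the orthogonal-validation cohort.

    ``n_pass_proteomics`` / ``n_below_r_min`` split the antibodies by the
    proteomics correlation threshold; ``n_pass_rna``, ``n_fail_despite_fold``
    (low r despite adequate RNA variability) and ``n_low_fold`` (RNA
    fold-change below the gate) describe the transcriptomics route.
    """

    n_total_antibodies: int
    n_pass_proteomics: int
    n_below_r_min: int
    n_pass_rna: int
    n_fail_despite_fold: int
    n_low_fold: int
    n_genes_tpm_gt10: Optional[int] = None

    def __post_init__(self) -> None:
        counts = [
            self.n_total_antibodies, self.n_pass_proteomics, self.n_below_r_min,
            self.n_pass_rna, self.n_fail_despite_fold, self.n_low_fold,
        ]
        if any(c < 0 for c in counts):
            raise DataValueError("cohort counts must be nonnegative")
        if self.n_pass_proteomics + self.n_below_r_min > self.n_total_antibodies:
            raise DataValueError("pass + below-threshold exceeds total antibodies")


def count_expressed_genes(
    rna: Union[AbundancePanel, pd.DataFrame], tpm_threshold: float = 10.0
) -> int:
    """Number of genes whose maximum TPM across samples strictly exceeds the
    threshold (expressed in at least one cell line)."""
    if isinstance(rna, AbundancePanel):
        values = rna.values
    else:
        values = rna.to_numpy(dtype=float)
    if values.size == 0:
        return 0
    return int(np.sum(np.nanmax(values, axis=1) > tpm_threshold))


def reproduce_orthogonal_counts(
    wb: AbundancePanel,
    prm: Optional[AbundancePanel],
    tmt: Optional[AbundancePanel],
    rna: AbundancePanel,
    assignments: pd.DataFrame,
    config: Optional[PillarConfig] = None,
) -> tuple[CohortResult, pd.DataFrame]:
    """Score every antibody against its assigned proteomics panel and against
    RNA, and tally the outcomes.

    ``wb`` rows are keyed by antibody id; ``assignments`` maps each antibody
    to its target gene and its proteomics platform (``prm`` or ``tmt``).
    Antibodies whose gene is missing from the assigned panel are listed in
    the audit table as excluded, not counted.
    """
    config = config or PillarConfig()
    panels = {"prm": prm, "tmt": tmt}
    rows = []
    tally = dict.fromkeys(
        ["pass_prot", "below", "pass_rna", "fail_despite_fold", "low_fold", "total"], 0
    )
    for rec in assignments.itertuples():
        ab = str(rec.antibody_id)
        gene = str(rec.gene)
        platform = str(rec.platform).lower()
        panel = panels.get(platform)
        row: dict = {"antibody_id": ab, "gene": gene, "platform": platform}
        if panel is None or ab not in wb.genes or gene not in panel.genes:
            row["excluded"] = "missing antibody, gene, or panel"
            rows.append(row)
            continue
        band = wb.series(ab)
        shared = [s for s in wb.sample_ids if s in panel.sample_ids]
        orth = np.array([panel.series(gene)[panel.sample_ids.index(s)] for s in shared])
        band_shared = np.array([band[wb.sample_ids.index(s)] for s in shared])
        res_p = orthogonal_validate(SeriesPair(band_shared, orth, shared), config)
        row["r_proteomics"] = res_p.metrics.get("pearson_r")
        row["status_proteomics"] = res_p.status.value
        tally["total"] += 1
        if res_p.status is PillarStatus.ENHANCED:
            tally["pass_prot"] += 1
        elif res_p.status is PillarStatus.NOT_VALIDATED:
            tally["below"] += 1
        rna_shared = [s for s in wb.sample_ids if s in rna.sample_ids]
        if gene in rna.genes and len(rna_shared) >= 3:
            orth_r = np.array([rna.series(gene)[rna.sample_ids.index(s)] for s in rna_shared])
            band_r = np.array([band[wb.sample_ids.index(s)] for s in rna_shared])
            res_r = orthogonal_validate(SeriesPair(band_r, orth_r, rna_shared), config)
            row["r_rna"] = res_r.metrics.get("pearson_r")
            row["rna_fold"] = res_r.metrics.get("fold_change")
            row["status_rna"] = res_r.status.value
            if res_r.status is PillarStatus.ENHANCED:
                tally["pass_rna"] += 1
            elif res_r.status is PillarStatus.NOT_VALIDATED:
                tally["fail_despite_fold"] += 1
            elif "fold-change" in res_r.note:
                tally["low_fold"] += 1
        rows.append(row)
    audit = pd.DataFrame(rows)
    result = CohortResult(
        n_total_antibodies=tally["total"],
        n_pass_proteomics=tally["pass_prot"],
        n_below_r_min=tally["below"],
        n_pass_rna=tally["pass_rna"],
        n_fail_despite_fold=tally["fail_despite_fold"],
        n_low_fold=tally["low_fold"],
    )
    return result, audit


def run_reproduction(
    data_dir: Union[str, Path], config: Optional[PillarConfig] = None
) -> dict:
    """End-to-end cohort re-tally from a data directory.

    Returns ``{"status": "data unavailable"}`` when the directory or its
    required tables are absent. Because the original analysis does not state
    whether correlations were computed on linear or log-transformed values,
    both variants are computed and reported side by side.
    """
    config = config or PillarConfig()
    data_dir = Path(data_dir)
    files = dict(_DEFAULT_FILES)
    if (data_dir / "schema.yaml").exists():
        files.update(yaml.safe_load((data_dir / "schema.yaml").read_text()) or {})
    required = ["wb", "rna", "assignments"]
    if not data_dir.is_dir() or any(not (data_dir / files[k]).exists() for k in required):
        return {"status": "data unavailable", "data_dir": str(data_dir)}
    wb = read_abundance_panel(data_dir / files["wb"], MeasurementKind.BAND_INTENSITY)
    rna = read_abundance_panel(data_dir / files["rna"], MeasurementKind.TPM)
    prm = tmt = None
    if (data_dir / files["prm"]).exists():
        prm = read_abundance_panel(data_dir / files["prm"], MeasurementKind.PRM_RATIO)
    if (data_dir / files["tmt"]).exists():
        tmt = read_abundance_panel(data_dir / files["tmt"], MeasurementKind.TMT_INTENSITY)
    assignments = pd.read_csv(data_dir / files["assignments"], sep="\t")
    out: dict = {"status": "ok", "variants": {}}
    for name, cfg in {
        "linear": replace(config, log_transform=False),
        "log2": replace(config, log_transform=True),
    }.items():
        result, audit = reproduce_orthogonal_counts(wb, prm, tmt, rna, assignments, cfg)
        out["variants"][name] = result
        out.setdefault("audit", {})[name] = audit
    gw = data_dir / files["rna_genomewide"]
    if gw.exists():
        df = pd.read_csv(gw, sep="\t", index_col=0)
        out["n_genes_tpm_gt10"] = count_expressed_genes(df)
    return out
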
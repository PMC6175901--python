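"""Readers and writers for the package's tabular formats.

All files are plain text: comma- or tab-separated depending on extension
(.csv / .tsv), decimal point, UTF-8. Gene and sample identifiers are opaque
strings; no identifier mapping is attempted.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AbundancePanel,
    Band,
    LaneProfile,
    MeasurementKind,
    Pillar,
    PillarConfig,
    PillarResult,
    PillarStatus,
    Sample,
    SampleKind,
    ValidationReport,
)
from .errors import ConfigurationError, DataValueError, DuplicateKeyError, FormatError
from .gel import LadderCalibration, SliceSet

__all__ = [
    "read_abundance_panel",
    "write_abundance_panel",
    "read_lane_table",
    "write_lane_table",
    "read_slice_sets",
    "write_slice_sets",
    "write_report",
    "read_report",
    "load_config",
]

PathLike = Union[str, Path]


def _sep(path: PathLike) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".tsv":
        return "\t"
    if suffix in (".csv", ".txt"):
        return ","
    raise FormatError(f"cannot infer delimiter from extension {suffix!r} (use .csv or .tsv)")


def read_abundance_panel(path: PathLike, measurement_kind: MeasurementKind) -> AbundancePanel:
    """Parse a genes x samples matrix: header row of sample IDs, first column
    gene IDs, numeric nonnegative body (empty cells allowed -> NaN)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise DuplicateKeyError(f"{path}: duplicate gene identifiers {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        bad = df.map(lambda v: not _is_number(v))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValueError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        ) from None
    neg = np.argwhere(np.nan_to_num(values, nan=0.0) < 0)
    if neg.size:
        r, c = neg[0]
        raise DataValueError(
            f"{path}: negative value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    samples = [Sample(str(c)) for c in df.columns]
    return AbundancePanel(
        measurement_kind=measurement_kind,
        genes=[str(g) for g in df.index],
        samples=samples,
        values=values,
    )


def _is_number(v) -> bool:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return True
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_abundance_panel(panel: AbundancePanel, path: PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame(panel.values, index=panel.genes, columns=panel.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep=_sep(path), float_format="%.17g")


def read_lane_table(
    path: PathLike, calibration: Optional[LadderCalibration] = None
) -> list[LaneProfile]:
    """Parse a lane table into per-(antibody, sample) lane profiles.

    Columns: ``antibody_id``, ``sample_id``, exactly one of ``mw_kda`` /
    ``migration`` per row, ``intensity``, optional ``loading_control``.
    Rows giving only a migration distance require a ladder calibration.
    Bands within a lane come out sorted by descending apparent MW.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    required = {"antibody_id", "sample_id", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    has_mw = "mw_kda" in df.columns
    has_mig = "migration" in df.columns
    if not has_mw and not has_mig:
        raise FormatError(f"{path}: need a mw_kda or migration column")
    lanes: dict[tuple[str, str], LaneProfile] = {}
    for i, row in df.iterrows():
        mw = row.get("mw_kda") if has_mw else np.nan
        mig = row.get("migration") if has_mig else np.nan
        mw_given = pd.notna(mw)
        mig_given = pd.notna(mig)
        if mw_given and mig_given:
            raise FormatError(f"{path} row {i}: both mw_kda and migration given")
        if not mw_given and not mig_given:
            raise FormatError(f"{path} row {i}: neither mw_kda nor migration given")
        if mig_given:
            if calibration is None:
                raise ConfigurationError(
                    f"{path} row {i}: migration given but no ladder calibration supplied"
                )
            mw = calibration.apparent_mw(float(mig))
        key = (str(row["antibody_id"]), str(row["sample_id"]))
        lane = lanes.get(key)
        if lane is None:
            lc = row.get("loading_control")
            lane = lanes[key] = LaneProfile(
                antibody_id=key[0],
                sample_id=key[1],
                bands=[],
                loading_control_intensity=float(lc) if pd.notna(lc) else None,
            )
        lane.bands.append(Band(float(mw), float(row["intensity"])))
    for lane in lanes.values():
        lane.bands.sort(key=lambda b: -b.apparent_mw_kda)
    return list(lanes.values())


def write_lane_table(lanes: Sequence[LaneProfile], path: PathLike) -> None:
    rows = []
    for lane in lanes:
        for b in lane.bands:
            rows.append(
                {
                    "antibody_id": lane.antibody_id,
                    "sample_id": lane.sample_id,
                    "mw_kda": b.apparent_mw_kda,
                    "intensity": b.intensity,
                    "loading_control": lane.loading_control_intensity,
                }
            )
    path = Path(path)
    pd.DataFrame(
        rows, columns=["antibody_id", "sample_id", "mw_kda", "intensity", "loading_control"]
    ).to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def read_slice_sets(path: PathLike) -> dict[str, SliceSet]:
    """Read capture-MS peptide counts.

    TSV/CSV columns: cell_line, replicate, slice_index, mw_low, mw_high,
    protein, peptide_count. Returns one :class:`SliceSet` per cell line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    required = {
        "cell_line", "replicate", "slice_index", "mw_low", "mw_high", "protein", "peptide_count",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, SliceSet] = {}
    for cell_line, sub in df.groupby("cell_line", sort=False):
        grid = (
            sub[["slice_index", "mw_low", "mw_high"]]
            .drop_duplicates()
            .sort_values("slice_index")
        )
        slices = [
            (int(r.slice_index), float(r.mw_low), float(r.mw_high))
            for r in grid.itertuples()
        ]
        n_slices = len(slices)
        reps = sorted(sub["replicate"].unique())
        rep_pos = {r: i for i, r in enumerate(reps)}
        counts: dict[str, np.ndarray] = {}
        for prot, psub in sub.groupby("protein", sort=False):
            arr = np.zeros((len(reps), n_slices), dtype=int)
            for r in psub.itertuples():
                arr[rep_pos[r.replicate], int(r.slice_index) - 1] += int(r.peptide_count)
            counts[str(prot)] = arr
        out[str(cell_line)] = SliceSet(cell_line=str(cell_line), slices=slices, counts=counts)
    return out


def write_slice_sets(slice_sets: Sequence[SliceSet], path: PathLike) -> None:
    rows = []
    for ss in slice_sets:
        for prot, arr in ss.counts.items():
            for rep in range(arr.shape[0]):
                for idx, lo, hi in ss.slices:
                    rows.append(
                        {
                            "cell_line": ss.cell_line,
                            "replicate": rep + 1,
                            "slice_index": idx,
                            "mw_low": lo,
                            "mw_high": hi,
                            "protein": prot,
                            "peptide_count": int(arr[rep, idx - 1]),
                        }
                    )
    path = Path(path)
    pd.DataFrame(
        rows,
        columns=[
            "cell_line", "replicate", "slice_index", "mw_low", "mw_high", "protein", "peptide_count",
        ],
    ).to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def write_report(reports: Sequence[ValidationReport], path: PathLike) -> None:
    """Write validation reports as JSON plus a TSV summary next to it.

    The JSON round-trips losslessly through :func:`read_report`; the TSV has
    one row per antibody with the per-pillar status and ``n_enhanced``.
    """
    path = Path(path)
    doc = [
        {
            "antibody_id": r.antibody_id,
            "n_enhanced": r.n_enhanced,
            "pillars": [
                {
                    "pillar": pr.pillar.value,
                    "status": pr.status.value,
                    "metrics": pr.metrics,
                    "note": pr.note,
                }
                for pr in r.pillar_results
            ],
        }
        for r in reports
    ]
    path.write_text(json.dumps(doc, indent=1) + "\n")
    rows = []
    for r in reports:
        row = {"antibody_id": r.antibody_id}
        for p in Pillar:
            row[p.value] = r.status_of(p).value
        row["n_enhanced"] = r.n_enhanced
        rows.append(row)
    cols = ["antibody_id"] + [p.value for p in Pillar] + ["n_enhanced"]
    pd.DataFrame(rows, columns=cols).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


def read_report(path: PathLike) -> list[ValidationReport]:
    doc = json.loads(Path(path).read_text())
    out = []
    for entry in doc:
        results = [
            PillarResult(
                pillar=Pillar(pr["pillar"]),
                status=PillarStatus(pr["status"]),
                metrics=dict(pr["metrics"]),
                note=pr.get("note", ""),
            )
            for pr in entry["pillars"]
        ]
        out.append(
            ValidationReport(
                antibody_id=entry["antibody_id"],
                pillar_results=results,
                n_enhanced=entry["n_enhanced"],
            )
        )
    return out


def load_config(path: Optional[PathLike] = None, **overrides) -> PillarConfig:
    """Build a :class:`PillarConfig` from a YAML/JSON file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(PillarConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return PillarConfig(**data)
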
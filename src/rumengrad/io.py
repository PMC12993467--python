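"""Readers and writers for the tabular inputs and the JSON result report.

Tables are TSV by default; a ``.csv`` extension switches to comma
separation. The first column always holds row labels (taxa, nutrients),
remaining columns are samples or diet groups, UTF-8 with decimal points.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AbundanceTable,
    DietSpec,
    FermentationSample,
    NutrientProfile,
    VFA_ACIDS,
    parse_ratio_label,
)

__all__ = [
    "read_table",
    "write_table",
    "read_abundance_table",
    "write_abundance_table",
    "read_diet_table",
    "read_fermentation_table",
    "write_report",
    "read_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"

PathLike = Union[str, Path]


def _sep(path: PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_table(path: PathLike) -> pd.DataFrame:
    """Read a labelled TSV/CSV table (first column = row label)."""
    return pd.read_csv(path, sep=_sep(path), index_col=0)


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write a labelled table; float values keep full repr precision."""
    df.to_csv(path, sep=_sep(path))


def read_abundance_table(path: PathLike, metadata_path: PathLike) -> AbundanceTable:
    """Load a taxon-by-sample table plus its sample metadata.

    The metadata table needs ``sample_id`` (or first-column index),
    ``group_label`` and ``concentrate_fraction`` columns. Mode is
    auto-detected: if every sample column sums to ~1 the table is taken as
    proportions, otherwise counts. A sample column missing from the
    metadata, or any negative value, is a hard error naming the culprit.
    """
    values = read_table(path)
    meta = pd.read_csv(metadata_path, sep=_sep(metadata_path))
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    else:
        meta = meta.set_index(meta.columns[0])
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    sums = values.sum(axis=0).to_numpy(dtype=float)
    mode = "proportions" if np.allclose(sums, 1.0, atol=1e-6) else "counts"
    return AbundanceTable(values=values, metadata=meta, mode=mode)


def write_abundance_table(
    table: AbundanceTable, path: PathLike, metadata_path: PathLike
) -> None:
    write_table(table.values, path)
    table.metadata.rename_axis("sample_id").to_csv(metadata_path, sep=_sep(metadata_path))


def read_diet_table(path: PathLike) -> list[DietSpec]:
    """Load a nutrient-by-group diet table into one DietSpec per group.

    Group headers are concentrate:roughage ratio strings (``"20:80"`` ->
    concentrate fraction 0.20); alternatively the table may carry an
    explicit ``concentrate_fraction`` row. Unparseable headers with no
    fraction row are a hard error.
    """
    df = read_table(path)
    df.index = df.index.astype(str).str.strip().str.lower()
    frac_row = df.loc["concentrate_fraction"] if "concentrate_fraction" in df.index else None
    nutrients = df.drop(index="concentrate_fraction", errors="ignore")
    known = {f.name for f in dataclasses.fields(NutrientProfile)}
    diets = []
    for col in df.columns:
        label = str(col).strip()
        if frac_row is not None:
            frac = float(frac_row[col])
        else:
            try:
                frac = parse_ratio_label(label)
            except ValueError as exc:
                raise ValueError(
                    f"group header {label!r} is not a 'c:r' ratio and the table "
                    "has no concentrate_fraction row"
                ) from exc
        fields = {
            k: float(v)
            for k, v in nutrients[col].items()
            if k in known and pd.notna(v)
        }
        diets.append(
            DietSpec(
                group_label=label,
                concentrate_fraction=frac,
                profile=NutrientProfile(**fields),
            )
        )
    return diets


def read_fermentation_table(path: PathLike) -> list[FermentationSample]:
    """Load per-sample fermentation rows (animal_id, group_label, ph, nh3n, acids...)."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"animal_id", "group_label", "ph", "nh3n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fermentation table lacks columns: {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        vfa = {
            acid: float(row[acid]) for acid in VFA_ACIDS if acid in df.columns and pd.notna(row[acid])
        }
        samples.append(
            FermentationSample(
                animal_id=str(row["animal_id"]),
                group_label=str(row["group_label"]),
                ph=float(row["ph"]),
                nh3n=float(row["nh3n"]),
                vfa=vfa,
                tvfa=float(row["tvfa"]) if "tvfa" in df.columns and pd.notna(row.get("tvfa")) else None,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# JSON report
# ---------------------------------------------------------------------------

def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return {
            "index": [str(i) for i in obj.index],
            "columns": [str(c) for c in obj.columns],
            "data": obj.to_numpy().tolist(),
        }
    if isinstance(obj, pd.Series):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in obj]
    return obj


def _digest(path: PathLike) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_report(
    results: Any,
    path: PathLike,
    inputs: Optional[Sequence[PathLike]] = None,
) -> None:
    """Serialise pipeline output to a versioned JSON document.

    Floats are written by ``json`` at full repr precision, so a re-read
    reproduces every coefficient bit-exactly. ``inputs`` paths, when
    given, are recorded with their SHA-256 digests for provenance.
    """
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "inputs": {str(p): _digest(p) for p in inputs} if inputs else {},
        "results": _jsonify(results),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path: PathLike) -> dict:
    """Read back a report written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
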
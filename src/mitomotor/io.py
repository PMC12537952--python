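"""CSV readers/writers with schema validation, plus the run manifest.

All tables are long-format CSV: UTF-8, comma separator, dot decimal,
header required, newline-terminated. Validation errors carry 1-based
data row numbers so a bad well or trial can be located in the source
file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from . import __version__
from .behavior import DEFAULT_CENSOR_POINT, TrialRecord
from .bioenergetics import ASSAYS, EnzymeAssayRecord, QpcrRecord
from .respirometry import PHASE_ORDER, OcrTrace, traces_from_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str  # str | float | int | bool
    required: bool = True
    check: Callable | None = None
    rule: str = ""


class SchemaError(ValueError):
    pass


TRIALS_SCHEMA = [
    ColumnSpec("animal_id", "str"),
    ColumnSpec("genotype", "str"),
    ColumnSpec("condition", "str"),
    ColumnSpec("test", "str"),
    ColumnSpec("trial", "int", check=lambda v: v >= 1, rule="trial index >= 1"),
    ColumnSpec("latency_s", "float",
               check=lambda v: 0 < v <= DEFAULT_CENSOR_POINT,
               rule=f"latency in (0, {DEFAULT_CENSOR_POINT:g}]"),
]

ENZYMES_SCHEMA = [
    ColumnSpec("sample_id", "str"),
    ColumnSpec("plate_id", "str"),
    ColumnSpec("assay", "str", check=lambda v: v in ASSAYS,
               rule=f"assay in {ASSAYS}"),
    ColumnSpec("rep1", "float", required=False),
    ColumnSpec("rep2", "float", required=False),
    ColumnSpec("nonspecific", "float"),
    ColumnSpec("is_reference", "bool"),
]

QPCR_SCHEMA = [
    ColumnSpec("sample_id", "str"),
    ColumnSpec("amplicon", "str"),
    ColumnSpec("ct1", "float", required=False,
               check=lambda v: 0 < v < 45, rule="Ct in (0, 45)"),
    ColumnSpec("ct2", "float", required=False,
               check=lambda v: 0 < v < 45, rule="Ct in (0, 45)"),
    ColumnSpec("ct3", "float", required=False,
               check=lambda v: 0 < v < 45, rule="Ct in (0, 45)"),
]

OCR_SCHEMA = [
    ColumnSpec("well_id", "str"),
    ColumnSpec("mouse_id", "str"),
    ColumnSpec("substrate", "str"),
    ColumnSpec("cycle", "int"),
    ColumnSpec("phase", "str", check=lambda v: v in PHASE_ORDER,
               rule=f"phase in {PHASE_ORDER}"),
    ColumnSpec("ocr", "float"),
    ColumnSpec("protein_ug", "float", check=lambda v: v > 0,
               rule="protein_ug > 0"),
]

_DTYPES = {"str": str, "float": float, "int": int}


def read_table(path: str | Path, schema: Sequence[ColumnSpec]) -> pd.DataFrame:
    """Read and validate a CSV against a column schema.

    Header order is irrelevant; extra columns pass through untouched.
    Missing optional values are allowed; every violated per-value check
    raises with the offending data row number and the rule text.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    names = {c.name for c in schema}
    missing = names - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {sorted(missing)}")
    errors = []
    for col in schema:
        s = df[col.name]
        if col.dtype == "bool":
            mapped = s.map({True: True, False: False, "True": True, "False": False,
                            "true": True, "false": False, 1: True, 0: False})
            if mapped.isna().any():
                row = int(mapped.index[mapped.isna()][0]) + 1
                errors.append(f"row {row}: column {col.name!r} not boolean")
            df[col.name] = mapped
            continue
        if col.dtype in ("float", "int"):
            coerced = pd.to_numeric(s, errors="coerce")
            bad = coerced.isna() & s.notna()
            if bad.any():
                row = int(bad.index[bad][0]) + 1
                errors.append(f"row {row}: column {col.name!r} unparseable "
                              f"value {s[bad].iloc[0]!r}")
            if col.required and coerced.isna().any() and not bad.any():
                row = int(coerced.index[coerced.isna()][0]) + 1
                errors.append(f"row {row}: column {col.name!r} missing value")
            df[col.name] = coerced
            s = coerced
        elif col.required and s.isna().any():
            row = int(s.index[s.isna()][0]) + 1
            errors.append(f"row {row}: column {col.name!r} missing value")
        if col.check is not None:
            valid = s.dropna()
            viol = valid[~valid.map(col.check)]
            for idx, val in viol.head(5).items():
                errors.append(f"row {int(idx) + 1}: column {col.name!r} value "
                              f"{val!r} violates rule: {col.rule}")
    if errors:
        raise SchemaError(f"{path.name}: " + "; ".join(errors))
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")
    return path


def trials_from_frame(df: pd.DataFrame,
                      censor_point: float = DEFAULT_CENSOR_POINT) -> list[TrialRecord]:
    return [
        TrialRecord(
            animal_id=str(r.animal_id), genotype=str(r.genotype),
            condition=str(r.condition), test=str(r.test),
            trial_index=int(r.trial), latency_s=float(r.latency_s),
            censored=float(r.latency_s) >= censor_point,
        )
        for r in df.itertuples()
    ]


def enzymes_from_frame(df: pd.DataFrame) -> list[EnzymeAssayRecord]:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [
        EnzymeAssayRecord(
            sample_id=str(r.sample_id), plate_id=str(r.plate_id), assay=str(r.assay),
            total_activity_rep1=_opt(r.rep1), total_activity_rep2=_opt(r.rep2),
            nonspecific_activity=float(r.nonspecific),
            is_reference=bool(r.is_reference),
        )
        for r in df.itertuples()
    ]


def qpcr_from_frame(
    df: pd.DataFrame, mt_amplicon: str = "COX1", n_amplicon: str = "B2M"
) -> list[QpcrRecord]:
    """Pair mitochondrial and nuclear triplicate rows per sample."""
    records = []
    for sample, sub in df.groupby("sample_id", sort=True):
        by_amp = {str(r.amplicon): (r.ct1, r.ct2, r.ct3) for r in sub.itertuples()}
        if mt_amplicon not in by_amp or n_amplicon not in by_amp:
            raise SchemaError(
                f"sample {sample}: need both {mt_amplicon} and {n_amplicon} rows"
            )
        clean = lambda cts: tuple(None if pd.isna(c) else float(c) for c in cts)
        records.append(QpcrRecord(sample_id=str(sample),
                                  ct_mt=clean(by_amp[mt_amplicon]),
                                  ct_n=clean(by_amp[n_amplicon])))
    return records


def ocr_traces_from_file(path: str | Path) -> list[OcrTrace]:
    return traces_from_frame(read_table(path, OCR_SCHEMA))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    inputs: dict[str, str | Path],
    parameters: dict,
    seeds: dict | None = None,
    notes: list[str] | None = None,
) -> Path:
    """One JSON manifest per output directory: command, input hashes,
    seeds, parameters, software version, UTC timestamp."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in inputs.items() if p is not None and Path(p).exists()
        },
        "parameters": parameters,
        "seeds": seeds or {},
        "notes": notes or [],
        "software_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
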
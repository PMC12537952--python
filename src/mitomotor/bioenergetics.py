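"""Mitochondrial bioenergetics indices from plate enzymology and qPCR.

Enzymatic activities (Complex I, II, IV and citrate synthase) arrive as
duplicate total-activity wells plus a non-specific control per sample.
Specific activity is the duplicate mean minus the non-specific control.
Five reference samples on every plate anchor a per-assay multiplicative
normalization that removes plate/batch effects. Mean-centered activities
(each divided by the cohort mean, so the cohort average is 1) feed two
composite indices:

    MHI = (CI + CII + CIV) / (CS + mtDNA density + 1) * 100
    MRC = mean(sqrt(CI) + sqrt(CII) + sqrt(CIV))
          / mean(cbrt(mtDNA density) + cbrt(CS)) * 100

MHI scores respiratory-chain activity per unit of mitochondrial content;
the constant 1 in the denominator balances three numerator terms against
three denominator factors, so an animal average on all five features
scores exactly 100. MRC applies surface-area (square-root) scaling to
the cristae-bound chain complexes and volume (cube-root) scaling to the
content markers.

mtDNA copy number comes from triplicate qPCR of a mitochondrial (COX1)
and a nuclear (B2M) amplicon: dCt = mean nuclear Ct - mean mito Ct, and
mtDNAcn = 2^dCt * 2 (the factor 2 accounts for the diploid nuclear
genome). mtDNA density linearizes the mitochondrial Ct as
2^Ct / (1/10^-12); note this rises with Ct as printed — an inverse
direction (2^-Ct) is available behind an explicit switch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSAYS = ("CI", "CII", "CIV", "CS")

#: a triplicate Ct is dropped when > this many cycles from the median
CT_OUTLIER_THRESHOLD = 1.0


@dataclass(frozen=True)
class EnzymeAssayRecord:
    sample_id: str
    plate_id: str
    assay: str
    total_activity_rep1: float | None
    total_activity_rep2: float | None
    nonspecific_activity: float
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")


@dataclass(frozen=True)
class QpcrRecord:
    """Triplicate Ct values for the mitochondrial and nuclear amplicons."""

    sample_id: str
    ct_mt: tuple
    ct_n: tuple

    def __post_init__(self) -> None:
        for name, cts in (("ct_mt", self.ct_mt), ("ct_n", self.ct_n)):
            vals = [c for c in cts if c is not None and np.isfinite(c)]
            if any(not 0 < c < 45 for c in vals):
                raise ValueError(f"{name} values must lie in (0, 45)")


def specific_activity(record: EnzymeAssayRecord) -> float:
    """Duplicate mean minus the non-specific (negative control) activity.

    Negative results are retained (clamping would bias the downstream
    mean-centering) and flagged by the table builder.
    """
    reps = [r for r in (record.total_activity_rep1, record.total_activity_rep2)
            if r is not None and np.isfinite(r)]
    if not reps:
        raise ValueError(f"sample {record.sample_id}: both duplicates missing")
    return float(np.mean(reps)) - record.nonspecific_activity


def plate_normalize(records: Sequence[EnzymeAssayRecord]) -> pd.DataFrame:
    """Remove plate/batch effects using the on-plate reference samples.

    Per assay, each plate's factor is (grand mean of reference specific
    activities across all plates) / (that plate's reference mean); every
    sample on the plate is multiplied by the factor. After normalization
    the reference means agree across plates, and a second application is
    the identity.

    Returns a tidy frame with columns sample_id, plate_id, assay,
    specific_activity, normalized_activity, is_reference, qc_negative.
    """
    if not records:
        raise ValueError("no enzyme records")
    rows = [
        {
            "sample_id": r.sample_id,
            "plate_id": r.plate_id,
            "assay": r.assay,
            "specific_activity": specific_activity(r),
            "is_reference": r.is_reference,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    df["qc_negative"] = df["specific_activity"] < 0
    if df["qc_negative"].any():
        bad = df.loc[df["qc_negative"], "sample_id"].tolist()
        logger.warning("negative specific activities flagged for samples %s", bad)

    df["normalized_activity"] = df["specific_activity"].astype(float)
    for assay, sub in df.groupby("assay"):
        refs = sub[sub["is_reference"]]
        plates = sub["plate_id"].unique()
        missing = set(plates) - set(refs["plate_id"].unique())
        if missing:
            raise ValueError(
                f"plate(s) {sorted(missing)} lack reference samples for assay {assay}"
            )
        grand = refs["specific_activity"].mean()
        plate_means = refs.groupby("plate_id")["specific_activity"].mean()
        factors = grand / plate_means
        df.loc[sub.index, "normalized_activity"] = (
            sub["specific_activity"] * sub["plate_id"].map(factors)
        )
    return df


def mean_center(values: pd.Series | np.ndarray) -> np.ndarray:
    """Divide by the cohort mean so the centered cohort averages 1."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ValueError("cohort mean is zero; cannot mean-center")
    return v / m


def mhi(ci: float, cii: float, civ: float, cs: float, mtdna_density: float) -> float:
    """Mitochondrial Health Index on mean-centered features.

    (CI + CII + CIV) / (CS + mtDNA density + 1) * 100; the +1 is a
    constant balancing term and is never centered.
    """
    denom = cs + mtdna_density + 1.0
    if denom <= 0:
        raise ValueError("MHI denominator must be positive")
    return (ci + cii + civ) / denom * 100.0


def mrc(
    ci: np.ndarray,
    cii: np.ndarray,
    civ: np.ndarray,
    cs: np.ndarray,
    mtdna_density: np.ndarray,
) -> float:
    """Cohort Mitochondrial Respiratory Capacity on centered features.

    mean over animals of (sqrt CI + sqrt CII + sqrt CIV) divided by the
    mean of (cbrt mtDNA density + cbrt CS), times 100.
    """
    arrs = [np.asarray(a, dtype=float) for a in (ci, cii, civ, cs, mtdna_density)]
    if any(np.any(a < 0) for a in arrs):
        raise ValueError("MRC requires non-negative centered features")
    ci, cii, civ, cs, dens = arrs
    num = np.mean(np.sqrt(ci) + np.sqrt(cii) + np.sqrt(civ))
    den = np.mean(np.cbrt(dens) + np.cbrt(cs))
    if den <= 0:
        raise ValueError("MRC denominator must be positive")
    return float(num / den * 100.0)


def mrc_per_animal(ci, cii, civ, cs, mtdna_density) -> np.ndarray:
    """Animal-wise MRC variant: same roots applied per animal."""
    arrs = [np.asarray(a, dtype=float) for a in (ci, cii, civ, cs, mtdna_density)]
    if any(np.any(a < 0) for a in arrs):
        raise ValueError("MRC requires non-negative centered features")
    ci, cii, civ, cs, dens = arrs
    return (np.sqrt(ci) + np.sqrt(cii) + np.sqrt(civ)) / (np.cbrt(dens) + np.cbrt(cs)) * 100.0


def _clean_triplicate(cts: Sequence[float], label: str, sample_id: str) -> tuple[float, bool]:
    """Average a triplicate, dropping one >1-Ct outlier from the median.

    Returns (mean Ct, spread-warning flag). Requires >= 2 usable wells.
    """
    vals = np.array([c for c in cts if c is not None and np.isfinite(c)], dtype=float)
    if vals.size < 2:
        raise ValueError(f"sample {sample_id}: fewer than 2 valid {label} Ct replicates")
    flagged = False
    if vals.size == 3:
        med = np.median(vals)
        dev = np.abs(vals - med)
        if dev.max() > CT_OUTLIER_THRESHOLD:
            keep = vals[dev <= CT_OUTLIER_THRESHOLD]
            if keep.size >= 2:
                vals = keep
            flagged = True
    if vals.max() - vals.min() > CT_OUTLIER_THRESHOLD:
        flagged = True
    return float(vals.mean()), flagged


def mtdna_cn(record: QpcrRecord) -> float:
    """mtDNA copy number per cell: 2^(dCt) * 2, dCt = mean Ct_n - mean Ct_mt."""
    mt, f1 = _clean_triplicate(record.ct_mt, "mtDNA", record.sample_id)
    n, f2 = _clean_triplicate(record.ct_n, "nDNA", record.sample_id)
    if f1 or f2:
        logger.warning("sample %s: qPCR replicate spread exceeds %.1f Ct",
                       record.sample_id, CT_OUTLIER_THRESHOLD)
    return 2.0 ** (n - mt) * 2.0


def mtdna_density(record: QpcrRecord, direction: str = "as-printed") -> float:
    """Relative mtDNA abundance per unit tissue from the mitochondrial Ct.

    ``as-printed`` evaluates 2^Ct * 10^-12 exactly as the source formula
    reads; ``inverse`` evaluates 2^-Ct * 10^-12, the direction in which
    abundance actually varies with Ct. The printed form is the default;
    the choice must be made explicitly because the two disagree.
    """
    mt, flagged = _clean_triplicate(record.ct_mt, "mtDNA", record.sample_id)
    if flagged:
        logger.warning("sample %s: mtDNA Ct replicate spread exceeds %.1f Ct",
                       record.sample_id, CT_OUTLIER_THRESHOLD)
    if direction == "as-printed":
        return 2.0**mt * 1e-12
    if direction == "inverse":
        return 2.0**-mt * 1e-12
    raise ValueError(f"unknown density direction {direction!r}")


def build_feature_table(
    enzyme_records: Sequence[EnzymeAssayRecord],
    qpcr_records: Sequence[QpcrRecord],
    density_direction: str = "as-printed",
) -> pd.DataFrame:
    """Assemble the per-animal mitochondrial feature table.

    Pipeline: specific activity -> plate normalization -> merge with
    qPCR-derived mtDNA density and copy number -> mean-center the five
    features over the full cohort -> MHI per animal, MRC per cohort and
    per animal. Only samples present in both inputs are scored.
    """
    norm = plate_normalize(enzyme_records)
    wide = (
        norm[~norm["is_reference"]]
        .pivot_table(index="sample_id", columns="assay", values="normalized_activity")
        .rename(columns=str.lower)
    )
    missing_assays = [a.lower() for a in ASSAYS if a.lower() not in wide.columns]
    if missing_assays:
        raise ValueError(f"missing assays in enzyme data: {missing_assays}")

    qrows = {}
    for rec in qpcr_records:
        qrows[rec.sample_id] = {
            "mtdnacn": mtdna_cn(rec),
            "mtdna_density": mtdna_density(rec, direction=density_direction),
        }
    qdf = pd.DataFrame.from_dict(qrows, orient="index")
    table = wide.join(qdf, how="inner")
    if table.empty:
        raise ValueError("no samples shared between enzyme and qPCR inputs")
    if table[["ci", "cii", "civ", "cs", "mtdna_density"]].isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete feature rows for samples {bad}")

    for feat in ("ci", "cii", "civ", "cs", "mtdna_density"):
        table[f"{feat}_centered"] = mean_center(table[feat])

    table["mhi"] = [
        mhi(r.ci_centered, r.cii_centered, r.civ_centered, r.cs_centered,
            r.mtdna_density_centered)
        for r in table.itertuples()
    ]
    cent = [table[f"{f}_centered"].to_numpy() for f in
            ("ci", "cii", "civ", "cs", "mtdna_density")]
    if all(np.all(c >= 0) for c in cent):
        table["mrc_per_animal"] = mrc_per_animal(*cent)
        table.attrs["mrc_cohort"] = mrc(*cent)
    else:
        table["mrc_per_animal"] = np.nan
        table.attrs["mrc_cohort"] = math.nan
        logger.warning("negative centered features; MRC undefined")
    table.index.name = "sample_id"
    return table.reset_index()
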
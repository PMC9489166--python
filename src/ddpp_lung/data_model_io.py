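"""Containers and flat-file IO for paired tumor/normal expression cohorts.

Expression lives in a TSV with gene rows and one column per tissue sample,
named ``<patient>_T`` (tumor) and ``<patient>_N`` (normal bronchial tissue).
Intensities are positive, linear scale; all log transforms happen downstream.
Clinical covariates live in a CSV with one row per patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HISTOLOGIES = ("AC", "SCC", "LCC")

#: canonical ordering of the six histology-by-treatment groups
GROUP_ORDER: tuple[tuple[str, bool], ...] = (
    ("AC", False),
    ("AC", True),
    ("SCC", False),
    ("SCC", True),
    ("LCC", False),
    ("LCC", True),
)

_CHEMO_TOKENS = {
    "0": False, "1": True,
    "false": False, "true": True,
    "nc": False, "ct": True,
    "no": False, "yes": True,
}


def group_label(key: tuple[str, bool]) -> str:
    """Human-readable label for a (histology, chemo) group, e.g. ``AC:NC``."""
    histology, chemo = key
    return f"{histology}:{'CT' if chemo else 'NC'}"


def parse_group_label(label: str) -> tuple[str, bool]:
    histology, _, arm = label.partition(":")
    if histology not in HISTOLOGIES or arm not in ("NC", "CT"):
        raise ValueError(f"unrecognized group label {label!r}")
    return histology, arm == "CT"


@dataclass
class PairedExpression:
    """Tumor and normal intensity matrices over a shared gene/patient index.

    Both matrices are genes x patients DataFrames of strictly positive,
    linear-scale intensities.  The row (gene) and column (patient) indices
    of the two matrices are identical: each patient contributed both a
    tumor and a normal tissue sample.
    """

    tumor: pd.DataFrame
    normal: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.tumor.index.equals(self.normal.index):
            raise ValueError("tumor and normal matrices have different gene indices")
        if not self.tumor.columns.equals(self.normal.columns):
            raise ValueError("tumor and normal matrices have different patient indices")
        if self.tumor.index.has_duplicates:
            dupes = self.tumor.index[self.tumor.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        for name, mat in (("tumor", self.tumor), ("normal", self.normal)):
            values = mat.to_numpy()
            if not np.isfinite(values).all():
                raise ValueError(f"{name} matrix contains missing or non-finite values")
            if (values <= 0).any():
                gene, patient = np.argwhere(values <= 0)[0]
                raise ValueError(
                    f"non-positive intensity in {name} matrix at gene "
                    f"{mat.index[gene]!r}, patient {mat.columns[patient]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tumor.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.tumor.columns)

    @property
    def n_genes(self) -> int:
        return self.tumor.shape[0]

    @property
    def n_patients(self) -> int:
        return self.tumor.shape[1]

    def subset_patients(self, patients: list[str]) -> "PairedExpression":
        return PairedExpression(self.tumor[patients], self.normal[patients])


CLINICAL_COLUMNS = ("histology", "stage", "chemo", "dfs_months", "event")


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Type and validate a clinical table indexed by patient_id.

    Stage is a nullable integer column; ``pd.NA`` encodes an undetermined
    TNM stage.  Patients with undetermined stage stay in the table (they are
    excluded from stage-stratified analyses only, downstream).
    """
    table = table.copy()
    if table.index.has_duplicates:
        raise ValueError("duplicate patient ids in clinical table")
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table missing columns {missing}")

    bad_hist = set(table["histology"].astype(str)) - set(HISTOLOGIES)
    if bad_hist:
        raise ValueError(f"unknown histology tokens {sorted(bad_hist)}")

    stage = pd.to_numeric(table["stage"], errors="coerce").astype("Int64")
    stage[~stage.isin([1, 2, 3, 4])] = pd.NA
    table["stage"] = stage

    chemo_raw = table["chemo"]
    if chemo_raw.dtype != bool:
        tokens = chemo_raw.astype(str).str.strip().str.lower()
        unknown = set(tokens) - set(_CHEMO_TOKENS)
        if unknown:
            raise ValueError(f"unrecognized chemo tokens {sorted(unknown)}")
        table["chemo"] = tokens.map(_CHEMO_TOKENS)

    table["dfs_months"] = pd.to_numeric(table["dfs_months"])
    if (table["dfs_months"] <= 0).any():
        bad = table.index[table["dfs_months"] <= 0].tolist()
        raise ValueError(f"non-positive dfs_months for patients {bad[:5]}")
    table["event"] = table["event"].astype(bool)
    return table[list(CLINICAL_COLUMNS)]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-patient clinical CSV.

    Expected columns: patient_id, histology, stage, chemo, dfs_months,
    event.  Stage tokens outside {1,2,3,4} (e.g. "NA") map to undetermined.
    """
    raw = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in raw.columns:
        raise ValueError("clinical CSV needs a patient_id column")
    return validate_clinical(raw.set_index("patient_id"))


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out.insert(0, "patient_id", out.index)
    out.to_csv(path, index=False, na_rep="NA")


def read_expression(path: str | Path) -> PairedExpression:
    """Read the paired-expression TSV, keeping patients with both tissues.

    Patients missing one of the two tissue columns are dropped with a
    warning; non-numeric, missing or non-positive intensities are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")

    tumor_cols: dict[str, str] = {}
    normal_cols: dict[str, str] = {}
    for col in df.columns:
        patient, _, tissue = col.rpartition("_")
        if tissue == "T" and patient:
            tumor_cols[patient] = col
        elif tissue == "N" and patient:
            normal_cols[patient] = col
        else:
            logger.warning("ignoring column %r: not named <patient>_T/_N", col)

    paired = sorted(set(tumor_cols) & set(normal_cols))
    for patient in sorted(set(tumor_cols) ^ set(normal_cols)):
        logger.warning("dropping patient %s: only one tissue present", patient)
    if not paired:
        raise ValueError(f"no complete tumor/normal pairs in {path}")

    for mapping in (tumor_cols, normal_cols):
        for patient in paired:
            col = mapping[patient]
            values = pd.to_numeric(df[col], errors="coerce")
            if values.isna().any():
                gene = df.index[values.isna()][0]
                raise ValueError(f"non-numeric intensity at gene {gene!r}, sample {col!r}")
            if (values <= 0).any():
                gene = df.index[values <= 0][0]
                raise ValueError(f"non-positive intensity at gene {gene!r}, sample {col!r}")

    tumor = df[[tumor_cols[p] for p in paired]].astype(float)
    tumor.columns = paired
    normal = df[[normal_cols[p] for p in paired]].astype(float)
    normal.columns = paired
    return PairedExpression(tumor=tumor, normal=normal)


def write_expression(expr: PairedExpression, path: str | Path) -> None:
    """Write the paired matrices as one TSV with `<patient>_T/_N` columns."""
    out = {}
    for patient in expr.patient_ids:
        out[f"{patient}_T"] = expr.tumor[patient]
        out[f"{patient}_N"] = expr.normal[patient]
    table = pd.DataFrame(out, index=expr.tumor.index)
    table.index.name = "gene_id"
    table.to_csv(path, sep="\t")


def partition_groups(clinical: pd.DataFrame) -> dict[tuple[str, bool], list[str]]:
    """Assign every analyzable patient to one histology-by-treatment group.

    Returns all six groups in canonical order; empty groups are kept (and
    flagged with a warning) so callers can see which correlators are
    unavailable.
    """
    groups: dict[tuple[str, bool], list[str]] = {key: [] for key in GROUP_ORDER}
    usable = clinical.dropna(subset=["histology", "chemo"])
    for patient, row in usable.iterrows():
        groups[(row["histology"], bool(row["chemo"]))].append(patient)
    for key, members in groups.items():
        if not members:
            logger.warning("group %s is empty", group_label(key))
    return groups


@dataclass
class AnalysisReport:
    """Machine-readable end-to-end analysis output (serialized to JSON)."""

    seed: int
    config: dict = field(default_factory=dict)
    correlators: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)
    immune: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    cox: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
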
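"""Cohort containers and file I/O.

The pipeline works on three aligned tables:

* a **beta matrix** — probe x subject methylation beta values in [0, 1]
  (missing values are ``NaN``, never 0);
* a **sample sheet** — one row per subject with phenotype, sex, age, batch
  and blood cell-type fractions;
* a **probe annotation** — genomic coordinates, gene assignment and the
  boolean QC exclusion flags consumed by :mod:`epidrift.qc`.

All three are plain :class:`pandas.DataFrame` objects with the conventions
below; ``validate_*`` functions enforce the invariants and raise
:class:`CohortError` with the offending identifiers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "FLAG_COLUMNS",
    "CELL_TYPES",
    "cell_fraction_columns",
    "validate_beta_matrix",
    "validate_sample_sheet",
    "validate_annotation",
    "load_cohort",
    "write_cohort",
]

#: QC exclusion flags, in the order filters are applied.
FLAG_COLUMNS = [
    "high_detection_p",
    "low_beadcount",
    "not_cpg_start",
    "masked_list",
    "sex_chromosome",
]

#: Default blood cell types for simulated cell-fraction columns
#: (reference-based deconvolution estimates in real data).
CELL_TYPES = ["CD4T", "CD8T", "B", "NK", "Mono", "Gran"]

_SHEET_FIXED = {"phenotype", "sex", "age", "batch"}


class CohortError(ValueError):
    """Raised when a cohort table violates its contract."""


def cell_fraction_columns(sheet: pd.DataFrame) -> list[str]:
    """Columns of *sheet* holding cell-type fractions (everything that is
    not phenotype/sex/age/batch), in sheet order."""
    return [c for c in sheet.columns if c not in _SHEET_FIXED]


def validate_beta_matrix(beta: pd.DataFrame, *, name: str = "beta matrix") -> None:
    if beta.index.has_duplicates:
        dups = beta.index[beta.index.duplicated()].unique().tolist()[:5]
        raise CohortError(f"{name}: duplicate probe IDs {dups}")
    if beta.columns.has_duplicates:
        dups = beta.columns[beta.columns.duplicated()].unique().tolist()[:5]
        raise CohortError(f"{name}: duplicate subject IDs {dups}")
    values = beta.to_numpy(dtype=float)
    bad = (values < 0.0) | (values > 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CohortError(
            f"{name}: beta value {values[i, j]!r} outside [0, 1] at "
            f"probe {beta.index[i]!r}, subject {beta.columns[j]!r}"
        )


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    if sheet.index.has_duplicates:
        raise CohortError("sample sheet: duplicate subject IDs")
    missing = _SHEET_FIXED - set(sheet.columns)
    if missing:
        raise CohortError(f"sample sheet: missing columns {sorted(missing)}")
    bad_pheno = ~sheet["phenotype"].isin(["case", "control"])
    if bad_pheno.any():
        raise CohortError(
            f"sample sheet: phenotype must be case/control; offending subjects "
            f"{sheet.index[bad_pheno].tolist()[:5]}"
        )
    bad_sex = ~sheet["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise CohortError(
            f"sample sheet: sex must be F/M; offending subjects "
            f"{sheet.index[bad_sex].tolist()[:5]}"
        )
    cells = cell_fraction_columns(sheet)
    if cells:
        frac = sheet[cells].to_numpy(dtype=float)
        if (frac < 0).any():
            raise CohortError("sample sheet: negative cell fraction")
        total = frac.sum(axis=1)
        off = np.abs(total - 1.0) > 1e-6
        if off.any():
            raise CohortError(
                f"sample sheet: cell fractions do not sum to 1 for subjects "
                f"{sheet.index[off].tolist()[:5]}"
            )


def validate_annotation(annot: pd.DataFrame) -> None:
    if annot.index.has_duplicates:
        raise CohortError("annotation: duplicate probe IDs")
    for col in ("chrom", "pos", "gene"):
        if col not in annot.columns:
            raise CohortError(f"annotation: missing column {col!r}")
    for col in FLAG_COLUMNS:
        if col not in annot.columns:
            raise CohortError(f"annotation: missing flag column {col!r}")
    for chrom, grp in annot.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        pos_sorted = np.sort(pos)
        if (np.diff(pos_sorted) <= 0).any():
            raise CohortError(f"annotation: non-increasing positions on {chrom}")


def load_cohort(
    beta_path: str | Path,
    sheet_path: str | Path,
    annotation_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate a cohort from disk.

    Parameters
    ----------
    beta_path
        TSV with probe IDs in the first column and one column per subject.
    sheet_path
        CSV with subject IDs in the first column.
    annotation_path
        BED-like TSV: chrom, 0-based start, end, probe ID, gene, then one
        column per QC flag (0/1).

    Returns
    -------
    (beta, sheet, annotation) aligned on subject and probe order: beta
    columns follow the sheet, beta rows follow the annotation.
    """
    beta_path, sheet_path, annotation_path = map(Path, (beta_path, sheet_path, annotation_path))
    for p in (beta_path, sheet_path, annotation_path):
        if not p.exists():
            raise CohortError(f"missing input file: {p}")

    try:
        beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    except ValueError as exc:  # malformed numerics surface here
        raise CohortError(f"{beta_path}: {exc}") from exc
    non_numeric = beta.columns[[not np.issubdtype(dt, np.number) for dt in beta.dtypes]]
    if len(non_numeric):
        raise CohortError(f"{beta_path}: non-numeric beta column(s) {list(non_numeric)[:5]}")
    sheet = pd.read_csv(sheet_path, index_col=0)
    annot = pd.read_csv(annotation_path, sep="\t", index_col="probe_id")
    annot = annot.rename(columns={"start": "start0"})
    if "pos" not in annot.columns:
        # BED start is 0-based; probe position is 1-based
        annot["pos"] = annot["start0"].astype(int) + 1
    annot[FLAG_COLUMNS] = annot[FLAG_COLUMNS].astype(bool)

    matrix_subjects = set(beta.columns)
    sheet_subjects = set(sheet.index)
    if matrix_subjects != sheet_subjects:
        only_beta = sorted(matrix_subjects - sheet_subjects)
        only_sheet = sorted(sheet_subjects - matrix_subjects)
        raise CohortError(
            f"subject ID mismatch between {beta_path.name} and {sheet_path.name}: "
            f"only in beta matrix {only_beta[:5]}, only in sheet {only_sheet[:5]}"
        )
    missing_probes = beta.index.difference(annot.index)
    if len(missing_probes):
        raise CohortError(
            f"probes absent from {annotation_path.name}: {missing_probes.tolist()[:5]}"
        )

    beta = beta.loc[:, sheet.index]
    annot = annot.loc[annot.index.intersection(beta.index, sort=False)]
    annot = annot.sort_values(["chrom", "pos"], kind="stable")
    beta = beta.loc[annot.index]

    validate_beta_matrix(beta, name=beta_path.name)
    validate_sample_sheet(sheet)
    validate_annotation(annot)
    return beta, sheet, annot


def write_cohort(
    outdir: str | Path,
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    annot: pd.DataFrame,
) -> dict[str, Path]:
    """Write beta.tsv, sheet.csv and probes.bed under *outdir*; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "sheet": outdir / "sheet.csv",
        "annotation": outdir / "probes.bed",
    }
    beta.rename_axis("probe_id").to_csv(paths["beta"], sep="\t", float_format="%.6g")
    sheet.rename_axis("subject_id").to_csv(paths["sheet"])
    bed = pd.DataFrame(
        {
            "chrom": annot["chrom"],
            "start": annot["pos"].astype(int) - 1,
            "end": annot["pos"].astype(int),
            "probe_id": annot.index,
            "gene": annot["gene"],
        }
    )
    for col in FLAG_COLUMNS:
        bed[col] = annot[col].astype(int).to_numpy()
    bed.to_csv(paths["annotation"], sep="\t", index=False)
    return paths
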
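"""Readers, writers, and subject filtering.

Phenotype tables are TSV with required columns ``id``, ``site``, ``dx``,
``qc``; diagnosis labels follow the ADHD-200 convention (TDC, ADHD-C,
ADHD-I, ADHD-HI).  Feature matrices are CSV/TSV with the subject id in the
first column and feature ids in the header.  Volumes are NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .timeseries import Parcellation, Volume4D

__all__ = [
    "DIAGNOSES",
    "FeatureMatrix",
    "read_phenotype",
    "filter_subjects",
    "read_feature_table",
    "write_feature_table",
    "read_volume",
    "write_volume",
    "read_map",
    "write_map",
    "read_parcellation",
]

DIAGNOSES = ("TDC", "ADHD-C", "ADHD-I", "ADHD-HI")
PHENOTYPE_COLUMNS = ("id", "site", "dx", "qc")


@dataclass
class FeatureMatrix:
    """Subjects x features table for one modality."""

    X: np.ndarray
    feature_ids: list[str]
    subject_ids: list[str] = field(default=None)  # type: ignore[assignment]
    modality: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2D (subjects x features)")
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature_ids length must match number of columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:04d}" for i in range(self.X.shape[0])]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length must match number of rows")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# phenotype table and exclusion rules
# ---------------------------------------------------------------------------


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype TSV; extra columns pass through untouched."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if pd.isna(row["id"]) or str(row["id"]).strip() == "":
            raise ValueError(f"{path.name} line {line}: empty subject id")
        if row["dx"] not in DIAGNOSES:
            raise ValueError(
                f"{path.name} line {line}: unknown diagnosis {row['dx']!r} "
                f"(expected one of {DIAGNOSES})"
            )
        try:
            qc = int(row["qc"])
        except (TypeError, ValueError):
            qc = -1
        if qc not in (0, 1):
            raise ValueError(
                f"{path.name} line {line}: qc must be 0 or 1, got {row['qc']!r}"
            )
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path.name}: duplicate subject ids {dupes}")
    df["qc"] = df["qc"].astype(int)
    return df


def filter_subjects(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's exclusion rules and report per-rule counts.

    Drops subjects with qc != 1, subjects of the hyperactive subtype
    (ADHD-HI), and subjects flagged as failed in preprocessing (optional
    boolean column ``failed_preproc``).  The rules are conjunctive, so the
    retained set is independent of the order in which they are applied; a
    subject violating several rules is counted under each.
    """
    bad_qc = records["qc"] != 1
    bad_subtype = records["dx"] == "ADHD-HI"
    if "failed_preproc" in records.columns:
        bad_failed = records["failed_preproc"].astype(bool)
    else:
        bad_failed = pd.Series(False, index=records.index)
    log = {
        "qc": int(bad_qc.sum()),
        "subtype": int(bad_subtype.sum()),
        "failed": int(bad_failed.sum()),
    }
    retained = records.loc[~(bad_qc | bad_subtype | bad_failed)].copy()
    return retained, log


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_feature_table(path: str | Path, modality: str = "") -> FeatureMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path.name}: duplicated feature ids")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path.name}: empty feature table")
    return FeatureMatrix(
        X=df.to_numpy(dtype=float),
        feature_ids=[str(c) for c in df.columns],
        subject_ids=[str(s) for s in df.index],
        modality=modality or path.stem,
    )


def write_feature_table(fm: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(fm.X, index=fm.subject_ids, columns=fm.feature_ids)
    df.index.name = "subject"
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def validate_subject_order(fm: FeatureMatrix, phenotype: pd.DataFrame) -> None:
    """Check that a feature table covers exactly the phenotype's subjects, in order."""
    expected = [str(s) for s in phenotype["id"]]
    if fm.subject_ids != expected:
        missing = sorted(set(expected) - set(fm.subject_ids))
        extra = sorted(set(fm.subject_ids) - set(expected))
        raise ValueError(
            f"feature table subjects do not match phenotype "
            f"(missing={missing[:5]}, extra={extra[:5]}, order matters)"
        )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def read_volume(path: str | Path, tr: float | None = None) -> Volume4D:
    """Load a 4D functional NIfTI; tr comes from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{Path(path).name}: expected 4D functional data, got {data.ndim}D")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise ValueError(
                f"{Path(path).name}: tr missing from header; supply tr explicitly"
            )
        tr = header_tr
    return Volume4D(data=data, voxel_size=tuple(float(z) for z in zooms[:3]), tr=tr)


def write_volume(vol: Volume4D, path: str | Path) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (vol.tr or 0.0,))
    nib.save(img, str(path))


def read_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a 3D map (e.g. ReHo); returns (data, voxel_size)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{Path(path).name}: expected a 3D map, got {data.ndim}D")
    zooms = img.header.get_zooms()
    return data, tuple(float(z) for z in zooms[:3])


def write_map(
    data: np.ndarray, path: str | Path, voxel_size: tuple[float, float, float] = (1, 1, 1)
) -> None:
    if np.asarray(data).ndim != 3:
        raise ValueError("maps must be 3D")
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=float), affine), str(path))


def read_parcellation(path: str | Path) -> Parcellation:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{Path(path).name}: expected a 3D parcellation, got {data.ndim}D")
    return Parcellation(labels=data)
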
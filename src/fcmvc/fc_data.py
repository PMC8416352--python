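"""Data model and I/O for subject-wise FC correlation matrices.

A dataset is a stack of per-subject ROI x ROI Pearson correlation matrices
(symmetric, unit diagonal) aligned with a subject metadata table
(diagnosis, age, sex, site).  Matrices live either in a directory of
per-subject CSV files or in a single HDF5 container; metadata is a TSV.

The Wishart observation model downstream consumes *scatter* matrices
S_i = nu * R_i, where nu is the degrees of freedom shared by all subjects
(by default the number of fMRI volumes minus one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

#: Closed diagnosis vocabulary; unknown values are accepted with a warning
#: and treated as their own category.
DIAGNOSES = ("HC", "MDD", "BD", "SCZ", "ASD", "DY")

METADATA_COLUMNS = ("subject_id", "diagnosis", "age", "sex", "site")

_SYM_TOL = 1e-10
_DIAG_TOL = 1e-10


class DataValidationError(ValueError):
    """A matrix or metadata table violates a dataset invariant."""


@dataclass(frozen=True)
class RoiSet:
    """Ordered ROI labels; the canonical row/column order of every matrix."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise DataValidationError("an RoiSet needs at least two ROIs")
        if len(set(self.labels)) != len(self.labels):
            raise DataValidationError("ROI labels must be unique")

    @property
    def p(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    diagnosis: str
    age: float
    sex: str
    site: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise DataValidationError(
                f"subject {self.subject_id}: negative age {self.age}"
            )
        if self.diagnosis not in DIAGNOSES:
            warnings.warn(
                f"subject {self.subject_id}: diagnosis {self.diagnosis!r} outside "
                f"the standard vocabulary {DIAGNOSES}; kept as its own category",
                stacklevel=2,
            )


def _check_correlation_values(values: np.ndarray, subject_id: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise DataValidationError(
            f"subject {subject_id}: matrix shape {values.shape} is not square"
        )
    asym = np.abs(values - values.T).max()
    if asym > _SYM_TOL:
        raise DataValidationError(
            f"subject {subject_id}: matrix asymmetric (max |A - A.T| = {asym:.3g})"
        )
    diag = np.diag(values)
    bad = np.where(np.abs(diag - 1.0) > _DIAG_TOL)[0]
    if bad.size:
        j = int(bad[0])
        raise DataValidationError(
            f"subject {subject_id}: diagonal entry ({j},{j}) = {diag[j]!r} != 1"
        )
    if np.abs(values).max() > 1.0 + 1e-9:
        i, j = np.unravel_index(np.argmax(np.abs(values)), values.shape)
        raise DataValidationError(
            f"subject {subject_id}: entry ({i},{j}) = {values[i, j]!r} outside [-1, 1]"
        )
    return 0.5 * (values + values.T)


@dataclass(frozen=True)
class CorrelationMatrix:
    """One subject's ROI x ROI Pearson correlation matrix R_i."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", _check_correlation_values(self.values, self.subject_id)
        )

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ScatterMatrix:
    """Wishart-sufficient form of a correlation matrix: S_i = nu * R_i."""

    subject_id: str
    values: np.ndarray
    dof: float


@dataclass(frozen=True)
class FCDataset:
    roi_set: RoiSet
    matrices: tuple[CorrelationMatrix, ...]
    metadata: tuple[SubjectRecord, ...]
    dof: float
    provenance: str = "raw"

    def __post_init__(self) -> None:
        ids_m = [m.subject_id for m in self.matrices]
        ids_r = [r.subject_id for r in self.metadata]
        if ids_m != ids_r:
            raise DataValidationError(
                "matrices and metadata are not aligned one-to-one by subject_id"
            )
        if len(set(ids_m)) != len(ids_m):
            raise DataValidationError("duplicate subject_id in dataset")
        for m in self.matrices:
            if m.p != self.roi_set.p:
                raise DataValidationError(
                    f"subject {m.subject_id}: matrix is {m.p}x{m.p}, "
                    f"expected {self.roi_set.p}x{self.roi_set.p}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def p(self) -> int:
        return self.roi_set.p

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(m.subject_id for m in self.matrices)

    @property
    def diagnoses(self) -> tuple[str, ...]:
        return tuple(r.diagnosis for r in self.metadata)

    def stack(self) -> np.ndarray:
        """All matrices as one (N, p, p) array in subject order."""
        return np.stack([m.values for m in self.matrices])

    def with_matrices(self, stacked: np.ndarray, provenance: str) -> "FCDataset":
        mats = tuple(
            CorrelationMatrix(sid, stacked[i])
            for i, sid in enumerate(self.subject_ids)
        )
        return replace(self, matrices=mats, provenance=provenance)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "diagnosis": r.diagnosis,
                    "age": r.age,
                    "sex": r.sex,
                    "site": r.site,
                }
                for r in self.metadata
            ]
        )


# ---------------------------------------------------------------------------
# matrix regularization and scatter conversion


def regularize_correlation(
    C: CorrelationMatrix, epsilon: float = 0.05
) -> CorrelationMatrix:
    """Add ``epsilon`` to the diagonal and rescale back to correlation form.

    The output is (C + eps*I) / (1 + eps): off-diagonals shrink by 1/(1+eps)
    and every eigenvalue maps to (lam + eps)/(1 + eps), so the result is
    positive definite whenever eps > 0.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be nonnegative, got {epsilon}")
    out = (C.values + epsilon * np.eye(C.p)) / (1.0 + epsilon)
    return CorrelationMatrix(C.subject_id, out)


def regularize_dataset(dataset: FCDataset, epsilon: float = 0.05) -> FCDataset:
    stacked = dataset.stack()
    p = dataset.p
    out = (stacked + epsilon * np.eye(p)) / (1.0 + epsilon)
    return dataset.with_matrices(out, provenance=f"{dataset.provenance}+regularized")


def to_scatter(C: CorrelationMatrix, dof: float) -> ScatterMatrix:
    """Scale a (positive-definite) correlation matrix to Wishart-scatter form."""
    if dof <= C.p - 1:
        raise ValueError(
            f"dof={dof} must exceed p-1={C.p - 1} for the Wishart density"
        )
    return ScatterMatrix(C.subject_id, dof * C.values, dof)


# ---------------------------------------------------------------------------
# I/O


def _read_metadata(metadata_path: Path) -> list[SubjectRecord]:
    df = pd.read_csv(metadata_path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"metadata table {metadata_path} lacks required columns: {missing}"
        )
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            diagnosis=str(row.diagnosis),
            age=float(row.age),
            sex=str(row.sex),
            site=str(row.site),
        )
        for row in df.itertuples()
    ]


def _read_matrices_csv_dir(path: Path) -> tuple[list[str], dict[str, pd.DataFrame]]:
    files = sorted(path.glob("*.csv"))
    if not files:
        raise DataValidationError(f"no per-subject CSV matrices found under {path}")
    # round_trip parsing keeps the stored doubles bit-exact
    frames = {
        f.stem: pd.read_csv(f, index_col=0, float_precision="round_trip")
        for f in files
    }
    first = next(iter(frames.values()))
    labels = [str(c) for c in first.columns]
    return labels, frames


def _read_matrices_hdf5(path: Path) -> tuple[list[str], dict[str, np.ndarray]]:
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as h5:
        labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in h5["roi_labels"][()]
        ]
        for sid in h5["matrices"]:
            out[sid] = h5["matrices"][sid][()]
    return labels, out


def read_dataset(
    matrix_path: str | Path, metadata_path: str | Path, dof: float
) -> FCDataset:
    """Load a dataset from a CSV directory or HDF5 container plus metadata TSV.

    ROI order is taken from the container header; matrices are validated
    against the CorrelationMatrix invariants and checked for a one-to-one
    match with the metadata rows.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    records = _read_metadata(metadata_path)
    if matrix_path.is_dir():
        labels, frames = _read_matrices_csv_dir(matrix_path)
        raw = {}
        for sid, frame in frames.items():
            if list(frame.columns) != labels or list(frame.index) != labels:
                raise DataValidationError(
                    f"subject {sid}: ROI labels disagree with container header"
                )
            raw[sid] = frame.to_numpy(dtype=float)
    else:
        labels, raw = _read_matrices_hdf5(matrix_path)
    roi_set = RoiSet(tuple(labels))
    by_id = {r.subject_id: r for r in records}
    missing = sorted(set(raw) - set(by_id))
    if missing:
        raise DataValidationError(f"matrices without metadata rows: {missing}")
    ordered = [r for r in records if r.subject_id in raw]
    if len(ordered) < len(records):
        dropped = [r.subject_id for r in records if r.subject_id not in raw]
        warnings.warn(f"metadata rows without matrices, skipped: {dropped}")
    matrices = tuple(
        CorrelationMatrix(r.subject_id, raw[r.subject_id]) for r in ordered
    )
    for m in matrices:
        if m.p != roi_set.p:
            raise DataValidationError(
                f"subject {m.subject_id}: matrix is {m.p}x{m.p}, "
                f"expected {roi_set.p}x{roi_set.p}"
            )
    return FCDataset(roi_set, matrices, tuple(ordered), dof=dof)


def write_dataset(
    dataset: FCDataset,
    matrix_path: str | Path,
    metadata_path: str | Path,
    fmt: str = "csv",
) -> None:
    """Write matrices (CSV directory or single HDF5 file) and the metadata TSV."""
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    labels = list(dataset.roi_set.labels)
    if fmt == "csv":
        matrix_path.mkdir(parents=True, exist_ok=True)
        for m in dataset.matrices:
            pd.DataFrame(m.values, index=labels, columns=labels).to_csv(
                matrix_path / f"{m.subject_id}.csv", float_format="%.17g"
            )
    elif fmt == "hdf5":
        matrix_path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(matrix_path, "w") as h5:
            h5.create_dataset("roi_labels", data=np.array(labels, dtype="S"))
            grp = h5.create_group("matrices")
            for m in dataset.matrices:
                grp.create_dataset(m.subject_id, data=m.values)
    else:
        raise ValueError(f"unknown matrix container format {fmt!r}")
    dataset.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def validate_dataset(dataset: FCDataset) -> dict:
    """Summary report used by the CLI ``validate-data`` subcommand."""
    stacked = dataset.stack()
    eigmins = [float(np.linalg.eigvalsh(m).min()) for m in stacked]
    counts = pd.Series(dataset.diagnoses).value_counts().to_dict()
    return {
        "n_subjects": dataset.n_subjects,
        "n_rois": dataset.p,
        "dof": dataset.dof,
        "provenance": dataset.provenance,
        "diagnosis_counts": counts,
        "min_eigenvalue": min(eigmins),
        "positive_definite_all": min(eigmins) > 0,
    }
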
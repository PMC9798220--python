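"""Readers, writers and manifest handling for cohorts and networks.

Everything is plain text: per-subject ROI x time TSV matrices, a
tab-separated cohort manifest, and P x P network TSVs with an ROI index
header.  The framework operates post-parcellation, so no imaging
formats are involved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["RoiTimeSeries", "CohortManifest", "RunConfig",
           "read_roi_timeseries", "write_roi_timeseries",
           "read_matrix", "write_matrix",
           "read_manifest", "write_manifest"]


@dataclass
class RoiTimeSeries:
    """One subject's P x T ROI signal matrix with an optional label."""

    values: np.ndarray
    subject_id: str = ""
    label: int | None = None   # 1 = patient, 0 = control
    TR: float = 3.0

    def __post_init__(self):
        X = np.asarray(self.values, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 3:
            raise ValueError("expected a P x T matrix with P >= 2, T >= 3")
        if not np.all(np.isfinite(X)):
            raise ValueError("time series contains non-finite values")
        self.values = X

    @property
    def P(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortManifest:
    """Subject records (id, label, path) plus shared dimensions."""

    records: list[dict]
    P: int
    T: int
    TR: float

    def __post_init__(self):
        ids = [r["subject_id"] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_ids in manifest")


def read_roi_timeseries(path, subject_id: str = "", label=None,
                        TR: float = 3.0) -> RoiTimeSeries:
    """Read a P x T signal matrix from TSV/CSV (rows = ROIs, no header)."""
    path = Path(path)
    delim = "\t"
    with open(path) as fh:
        first = fh.readline()
        if "," in first and "\t" not in first:
            delim = ","
    try:
        X = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as e:
        raise ValueError(f"{path}: could not parse numeric matrix: {e}") from e
    if np.isnan(X).any():
        r, c = np.argwhere(np.isnan(X))[0]
        raise ValueError(f"{path}: NaN at row {r}, column {c}")
    return RoiTimeSeries(values=X, subject_id=subject_id or path.stem,
                         label=label, TR=TR)


def write_roi_timeseries(ts: RoiTimeSeries, path) -> None:
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.10g")


def write_matrix(W: np.ndarray, path) -> None:
    """Write a square matrix as TSV with an ROI-index header row."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("expected a square matrix")
    header = "\t".join(str(i) for i in range(W.shape[0]))
    np.savetxt(path, W, delimiter="\t", fmt="%.10g", header=header,
               comments="")


def read_matrix(path, symmetric_tol: float = 1e-6) -> np.ndarray:
    W = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if W.shape[0] != W.shape[1]:
        raise ValueError(f"{path}: matrix is not square {W.shape}")
    dev = float(np.abs(W - W.T).max())
    if dev > symmetric_tol:
        import warnings
        warnings.warn(f"{path}: asymmetric read-back, max deviation {dev:g}")
    return W


def write_manifest(manifest: CohortManifest, path) -> None:
    df = pd.DataFrame(manifest.records)
    with open(path, "w") as fh:
        fh.write(f"# P={manifest.P}\tT={manifest.T}\tTR={manifest.TR}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    with open(path) as fh:
        meta = fh.readline().lstrip("# ").strip().split("\t")
    kv = dict(item.split("=") for item in meta)
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    records = df.to_dict("records")
    base = path.parent
    for r in records:
        p = base / r["path"]
        if not p.exists():
            raise FileNotFoundError(f"manifest entry missing file: {p}")
    return CohortManifest(records=records, P=int(kv["P"]), T=int(kv["T"]),
                          TR=float(kv["TR"]))


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serialisable to/from YAML.

    Defaults mirror the framework's stated settings: KNN size 11, SNF
    stopping tolerance 0.01, SVM C = 1, selection alpha 0.05, 5-fold CV.
    """

    scheme: str = "mbnf"          # {full, low, high, mbnf, concat}
    fbn_method: str = "pc"        # {pc, sr}
    ensemble_size: int = 100
    noise_amplitude: float = 0.2
    knn_k: int = 11
    snf_tol: float = 0.01
    snf_max_iter: int = 100
    snf_mode: str = "normalized"
    svm_c: float = 1.0
    alpha: float = 0.05
    n_folds: int = 5
    n_repeats: int = 10
    grid: list = field(default_factory=list)  # empty -> method default grid
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
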
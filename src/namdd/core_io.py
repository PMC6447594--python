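"""Domain containers, TSV matrix I/O and sample alignment.

The pipeline operates on three sample-aligned blocks: a methylation matrix
``X`` (N samples x P sites), an expression matrix ``Y`` (N x Q genes) and a
binary disease-status vector ``z`` (length N, 0 = normal, 1 = disease).  All
files are tab-separated with a header row of feature identifiers and a first
column of sample identifiers; samples are rows, features are columns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("namdd")


class NamddError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(NamddError):
    """Input violates a documented precondition."""


class AlignmentError(NamddError):
    """Sample identifiers cannot be reconciled across input files."""


class ParseError(NamddError):
    """A delimited matrix file contains a malformed cell."""


class ConvergenceError(NamddError):
    """An iterative solver diverged or failed to reach its target."""


@dataclass
class OmicsDataset:
    """Aligned (X, Y, z) triple with sample and feature identifiers.

    X is N x P (methylation), Y is N x Q (expression), z is length N with
    entries in {0, 1}.  Rows of all three refer to the same samples in the
    same order.
    """

    X: np.ndarray
    Y: np.ndarray
    z: np.ndarray
    sample_ids: list[str]
    site_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.z = np.asarray(self.z)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValidationError("X and Y must be 2-D matrices")
        n = self.X.shape[0]
        if self.Y.shape[0] != n or self.z.shape[0] != n:
            raise ValidationError(
                f"row counts differ: X has {n}, Y has {self.Y.shape[0]}, "
                f"z has {self.z.shape[0]}"
            )
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if not np.isin(self.z, (0, 1)).all():
            bad = sorted(set(self.z) - {0, 1})
            raise ValidationError(f"z entries must be 0 or 1, found {bad}")
        self.z = self.z.astype(int)
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match N")
        if len(self.site_ids) != self.X.shape[1]:
            raise ValidationError("site_ids length does not match P")
        if len(self.gene_ids) != self.Y.shape[1]:
            raise ValidationError("gene_ids length does not match Q")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("site_ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_sites(self) -> int:
        return self.X.shape[1]

    @property
    def n_genes(self) -> int:
        return self.Y.shape[1]


@dataclass
class AnalysisConfig:
    """Run-wide parameters for the full pipeline.

    T
        number of stability-selection resamples (half-sample refits).
    phi
        selection threshold on the edge score, in (0.5, 1]; an edge is kept
        when its selection frequency is at least phi.
    K
        maximum number of site-gene-disease paths to report.
    u, v
        shrinkage exponents (<= 1) of the elementwise and the row-group
        penalty; 1 recovers the convex soft-threshold / group lasso.
    alpha_grid, beta_grid, lambda_grid
        candidate penalty weights scanned by cross-validation.  The loss is
        the unnormalized 1/2 ||XB - Y||^2 on standardized columns, so useful
        alpha/beta values sit near the noise inner-product scale sqrt(N/2);
        the defaults bracket that scale for cohorts of a few hundred samples.
    rho
        ADMM splitting weight used by pipeline solves; larger values reach a
        stable support in proportionally fewer iterations.
    d
        sites retained per gene by univariate screening.
    n_perm
        permutations for path significance.
    """

    T: int = 100
    phi: float = 0.6
    K: int = 2000
    u: float = 0.5
    v: float = 0.5
    alpha_grid: list[float] = field(default_factory=lambda: [20.0, 35.0])
    beta_grid: list[float] = field(default_factory=lambda: [10.0, 17.0])
    lambda_grid: list[float] = field(default_factory=lambda: [0.5, 2.0, 8.0])
    n_cv_folds: int = 10
    d: int = 200
    n_perm: int = 1000
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-6
    rho: float = 20.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (0.5 < self.phi <= 1.0):
            raise ValidationError(f"phi must be in (0.5, 1], got {self.phi}")
        if self.T < 1:
            raise ValidationError(f"T must be >= 1, got {self.T}")
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if self.u > 1 or self.v > 1:
            raise ValidationError("shrinkage exponents u, v must be <= 1")
        for name in ("alpha_grid", "beta_grid", "lambda_grid"):
            grid = getattr(self, name)
            if not grid or any(g <= 0 for g in grid):
                raise ValidationError(f"{name} must be a nonempty positive list")
        if self.n_cv_folds < 2:
            raise ValidationError("n_cv_folds must be >= 2")
        if self.d < 1 or self.n_perm < 1:
            raise ValidationError("d and n_perm must be positive")
        if self.rho <= 0:
            raise ValidationError("rho must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV matrix I/O


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    bad = ~np.isfinite(pd.to_numeric(arr.ravel(), errors="coerce").astype(float))
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        i, j = divmod(flat, df.shape[1])
        raise ParseError(
            f"{path}: non-numeric or missing cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return df.astype(float)


def read_dataset(path_x: str | Path, path_y: str | Path, path_z: str | Path) -> OmicsDataset:
    """Read and sample-align the methylation, expression and status files.

    Rows are reordered so the sample identifiers match across the three
    inputs; samples missing from any file are dropped with a warning.
    """
    dfx, dfy, dfz = _read_table(path_x), _read_table(path_y), _read_table(path_z)
    shared = [s for s in dfx.index if s in set(dfy.index) & set(dfz.index)]
    if not shared:
        raise AlignmentError("no sample identifier is present in all three files")
    n_dropped = len(set(dfx.index) | set(dfy.index) | set(dfz.index)) - len(shared)
    if n_dropped:
        logger.warning("dropping %d sample(s) absent from at least one file", n_dropped)
    dfx, dfy, dfz = dfx.loc[shared], dfy.loc[shared], dfz.loc[shared]
    z = dfz.to_numpy()
    if z.shape[1] != 1:
        raise ValidationError(f"status file must have one column, got {z.shape[1]}")
    z = z[:, 0]
    if not np.isin(z, (0.0, 1.0)).all():
        bad = sorted(set(z) - {0.0, 1.0})
        raise ValidationError(f"disease status must be 0 or 1, found {bad}")
    return OmicsDataset(
        X=dfx.to_numpy(),
        Y=dfy.to_numpy(),
        z=z.astype(int),
        sample_ids=list(map(str, shared)),
        site_ids=list(map(str, dfx.columns)),
        gene_ids=list(map(str, dfy.columns)),
    )


def write_matrix(
    M: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a matrix as TSV with row identifiers and a header of column ids."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if len(col_ids) == 0 or len(row_ids) == 0:
        raise ValidationError("row_ids and col_ids must be nonempty")
    if M.shape != (len(row_ids), len(col_ids)):
        raise ValidationError(
            f"matrix shape {M.shape} does not match ids "
            f"({len(row_ids)}, {len(col_ids)})"
        )
    pd.DataFrame(M, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def write_dataset(data: OmicsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as x.tsv / y.tsv / z.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "x": out / "x.tsv",
        "y": out / "y.tsv",
        "z": out / "z.tsv",
    }
    write_matrix(data.X, data.sample_ids, data.site_ids, paths["x"])
    write_matrix(data.Y, data.sample_ids, data.gene_ids, paths["y"])
    write_matrix(data.z[:, None], data.sample_ids, ["status"], paths["z"])
    return paths
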
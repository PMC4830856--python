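"""Polychoric correlation estimation for ordinal items.

An ordinal item is modelled as a discretised latent standard-normal variable:
K - 1 strictly increasing thresholds cut the latent scale into K response
categories.  The polychoric correlation of two items is the correlation of
their latent bivariate normal, estimated in two steps:

1. thresholds from the marginal category proportions,
   ``tau_k = Phi^{-1}(cumulative proportion through category k)``;
2. maximum likelihood over rho with the thresholds held fixed, the
   likelihood being the multinomial over bivariate-normal rectangle
   probabilities of the observed contingency table.

Two-step estimation (rather than joint ML) matches standard practice in
psychometric software.  The estimate is clamped to [-0.999, 0.999] and cell
probabilities are floored at 1e-12, so perfect-association tables remain
well defined.  Pairwise-assembled matrices need not be positive definite;
:func:`nearest_pd` repairs them by eigenvalue clipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from ._kernels import _pair_rho, _polychoric_matrix_kernel
from .exceptions import DataError, DegenerateItemError, EstimationError
from .ordinal import OrdinalDataset

logger = logging.getLogger(__name__)

RHO_CLAMP = 0.999
PD_EPS = 1e-6


@dataclass
class CorrelationMatrix:
    """Symmetric correlation estimate with its sample size and provenance."""

    values: np.ndarray
    n: int
    method: str = "polychoric"  # polychoric | pearson | mixed
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise EstimationError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise EstimationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise EstimationError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise EstimationError("correlation entries must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        labels = self.labels or [f"v{i}" for i in range(self.p)]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, n: int, method: str = "polychoric") -> "CorrelationMatrix":
        import pandas as pd

        frame = pd.read_csv(path, index_col=0)
        return cls(
            values=frame.to_numpy(), n=n, method=method,
            labels=[str(c) for c in frame.columns],
        )


def estimate_thresholds(category_counts: np.ndarray) -> np.ndarray:
    """Latent-normal thresholds from marginal category counts.

    Empty leading/trailing categories are collapsed away (logged); empty
    interior categories simply contribute a repeated threshold boundary at
    the same cumulative proportion, which is collapsed as well so the
    returned thresholds are strictly increasing.
    """
    counts = np.asarray(category_counts, dtype=float)
    if counts.ndim != 1 or counts.shape[0] < 2:
        raise DataError("need counts for at least two categories")
    if np.any(counts < 0):
        raise DataError("category counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise DataError("no observations")
    nonzero = np.nonzero(counts)[0]
    if nonzero.size < 2:
        raise DegenerateItemError(
            "all observations fall in a single category (no variance)"
        )
    if nonzero.size < counts.size:
        logger.warning(
            "collapsing %d empty categories before threshold estimation",
            counts.size - nonzero.size,
        )
        counts = counts[nonzero]
    cum = np.cumsum(counts)[:-1] / total
    return ndtri(cum)


def polychoric_pair(
    table: np.ndarray, tau1: np.ndarray, tau2: np.ndarray
) -> float:
    """ML polychoric correlation for one contingency table, thresholds fixed."""
    table = np.ascontiguousarray(table, dtype=float)
    if table.ndim != 2:
        raise DataError("contingency table must be 2-D")
    if table.sum() < 1:
        raise DataError("contingency table is empty")
    tau1 = np.asarray(tau1, dtype=float)
    tau2 = np.asarray(tau2, dtype=float)
    if tau1.shape[0] != table.shape[0] - 1 or tau2.shape[0] != table.shape[1] - 1:
        raise DataError("threshold lengths do not match table dimensions")
    if not (np.all(np.isfinite(tau1)) and np.all(np.isfinite(tau2))):
        raise EstimationError("thresholds must be finite")
    if np.any(np.diff(tau1) <= 0) or np.any(np.diff(tau2) <= 0):
        raise EstimationError("thresholds must be strictly increasing")
    return float(_pair_rho(table, tau1, tau2))


def _tabulate_and_thresholds(
    codes: np.ndarray, ncat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse empty categories per item and compute padded thresholds.

    Returns (codes, ncat, tau_pad) ready for the pairwise kernel; raises
    :class:`DegenerateItemError` for a zero-variance item.
    """
    codes = np.ascontiguousarray(codes, dtype=np.int64)
    ncat = np.asarray(ncat, dtype=np.int64).copy()
    p = codes.shape[1]
    recoded = None
    for j in range(p):
        counts = np.bincount(codes[:, j], minlength=int(ncat[j]))
        observed = np.nonzero(counts)[0]
        if observed.size < 2:
            raise DegenerateItemError(
                f"item at column {j} has a single observed category"
            )
        if observed.size < counts.size:
            if recoded is None:
                recoded = codes.copy()
            remap = np.zeros(counts.size, dtype=np.int64)
            remap[observed] = np.arange(observed.size)
            recoded[:, j] = remap[codes[:, j]]
            ncat[j] = observed.size
    if recoded is not None:
        codes = recoded
    kmax = int(ncat.max())
    tau_pad = np.zeros((p, kmax - 1))
    for j in range(p):
        counts = np.bincount(codes[:, j], minlength=int(ncat[j])).astype(float)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        tau_pad[j, : ncat[j] - 1] = ndtri(cum)
    return codes, ncat, tau_pad


def polychoric_matrix(
    data: OrdinalDataset, repair: bool = True, pairwise_complete: bool = False
) -> CorrelationMatrix:
    """Pairwise polychoric correlation matrix of an ordinal dataset.

    With ``pairwise_complete`` the per-pair tables use rows complete for the
    pair (codes < 0 are treated as missing); default assumes a complete
    matrix.  The assembled matrix is repaired to positive definite by
    eigenvalue clipping when needed (logged).
    """
    if pairwise_complete:
        return _polychoric_pairwise_complete(data, repair=repair)
    codes, ncat, tau_pad = _tabulate_and_thresholds(data.values, data.n_categories)
    r_mat = _polychoric_matrix_kernel(codes, ncat, tau_pad)
    cm = CorrelationMatrix(
        values=r_mat, n=data.n_respondents, method="polychoric", labels=data.labels
    )
    if repair:
        cm = nearest_pd(cm)
    return cm


def _polychoric_pairwise_complete(
    data: OrdinalDataset, repair: bool = True
) -> CorrelationMatrix:
    p = data.n_items
    r_mat = np.eye(p)
    values = data.values
    for i in range(p):
        for j in range(i + 1, p):
            ok = (values[:, i] >= 0) & (values[:, j] >= 0)
            sub = values[np.ix_(ok, [i, j])]
            codes, ncat, tau_pad = _tabulate_and_thresholds(
                sub, data.n_categories[[i, j]]
            )
            pair_r = _polychoric_matrix_kernel(codes, ncat, tau_pad)
            r_mat[i, j] = r_mat[j, i] = pair_r[0, 1]
    cm = CorrelationMatrix(
        values=r_mat, n=data.n_respondents, method="polychoric", labels=data.labels
    )
    return nearest_pd(cm) if repair else cm


def pearson_matrix(scores: np.ndarray, labels: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation matrix for quasi-continuous columns (domain scores)."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 3:
        raise DataError("need an n x p matrix with n >= 3")
    sd = scores.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateItemError("constant column in score matrix")
    r_mat = np.corrcoef(scores, rowvar=False)
    r_mat = np.clip((r_mat + r_mat.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r_mat, 1.0)
    cm = CorrelationMatrix(
        values=r_mat, n=scores.shape[0], method="pearson", labels=labels
    )
    return nearest_pd(cm)


def nearest_pd(r: CorrelationMatrix | np.ndarray, eps: float = PD_EPS) -> CorrelationMatrix:
    """Clip eigenvalues to >= eps and rescale to unit diagonal.

    Idempotent on matrices that are already positive definite with minimum
    eigenvalue >= eps.
    """
    if isinstance(r, CorrelationMatrix):
        mat, n, method, labels = r.values, r.n, r.method, r.labels
    else:
        mat = np.asarray(r, dtype=float)
        n, method, labels = 0, "unknown", None
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise EstimationError("nearest_pd expects a symmetric matrix")
    eigval = np.linalg.eigvalsh(mat)
    if eigval[0] >= eps:
        out = mat
    else:
        logger.info(
            "repairing non-PD correlation matrix (min eigenvalue %.3e)", eigval[0]
        )
        out = mat
        # rescaling to unit diagonal can push the spectrum slightly below
        # the floor again, so clip-and-rescale until the floor holds
        for _ in range(50):
            vals, vecs = np.linalg.eigh(out)
            if vals[0] >= eps:
                break
            vals = np.clip(vals, eps * 1.05, None)
            out = (vecs * vals) @ vecs.T
            d = np.sqrt(np.diag(out))
            out = out / np.outer(d, d)
            out = (out + out.T) / 2.0
            np.fill_diagonal(out, 1.0)
    return CorrelationMatrix(values=out, n=n, method=method, labels=labels)
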
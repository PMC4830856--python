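"""Sparse Gaussian Graphical Model estimation by graphical lasso with EBIC.

The GGM encodes conditional-dependence structure: an edge between items i
and j means their partial correlation, controlling for all other items, is
nonzero.  The precision matrix Theta is estimated by maximising the
L1-penalised Gaussian log-likelihood

    log det Theta - tr(R Theta) - lambda * sum_{i != j} |theta_ij|

over symmetric positive-definite Theta (off-diagonal penalty only, so the
partial-correlation interpretation of the off-diagonals is preserved).  The
penalty lambda is chosen on a log-spaced path by minimising the Extended
Bayesian Information Criterion

    EBIC = -2 l(Theta) + E log n + 4 E gamma log p,

with l = (n/2)(log det Theta - tr(R Theta)) and E the number of nonzero
off-diagonal pairs; gamma defaults to 0.5, the conventional value in the
psychometric-network literature.  Edge weights are the partial correlations
w_ij = -theta_ij / sqrt(theta_ii theta_jj).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import (
    _ebic_value,
    _glasso_single,
    _pcor_from_theta,
    _select_path_kernel,
)
from .exceptions import EstimationError
from .polychoric import CorrelationMatrix

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.5
DEFAULT_PATH_LENGTH = 100
DEFAULT_PATH_RATIO = 0.01
GLASSO_TOL = 1e-6
GLASSO_MAX_SWEEPS = 10_000


@dataclass
class PrecisionMatrix:
    """Estimated inverse-covariance matrix and the penalty that produced it."""

    values: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise EstimationError("precision matrix must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise EstimationError("precision matrix has non-finite entries")
        if np.linalg.eigvalsh(self.values)[0] <= 0:
            raise EstimationError("precision matrix must be positive definite")


@dataclass
class LambdaPath:
    """Decreasing penalty path with per-lambda EBIC and edge counts."""

    lambdas: np.ndarray
    ebics: np.ndarray | None = None
    edge_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.size < 1 or np.any(self.lambdas <= 0):
            raise EstimationError("lambda path must contain positive values")
        if np.any(np.diff(self.lambdas) >= 0):
            if self.lambdas.size > 1:
                raise EstimationError("lambda path must be strictly decreasing")


@dataclass
class NetworkModel:
    """Partial-correlation network: weights, precision matrix, metadata."""

    weights: np.ndarray
    precision: PrecisionMatrix
    labels: list[str]
    lam: float
    ebic: float
    gamma: float
    n: int
    domains: list[str] | None = None
    path: LambdaPath | None = None

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((self.labels[i], self.labels[j], float(w)))
        return out

    # -- exports ------------------------------------------------------------
    def weights_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.weights, index=self.labels, columns=self.labels).to_csv(path)

    def edges_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\tweight\tsign\n")
            for a, b, w in self.edge_list():
                sign = "+" if w > 0 else "-"
                fh.write(f"{a}\t{b}\t{w:.10g}\t{sign}\n")

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        for i, lab in enumerate(self.labels):
            dom = self.domains[i] if self.domains else "none"
            g.add_node(lab, domain=dom)
        for a, b, w in self.edge_list():
            g.add_edge(a, b, weight=w)
        nx.write_graphml(g, path)

    def metadata(self) -> dict:
        return {
            "lambda": float(self.lam),
            "gamma": float(self.gamma),
            "ebic": float(self.ebic),
            "n": int(self.n),
            "p": int(self.p),
            "edge_count": self.edge_count,
        }

    def metadata_to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2, sort_keys=True)


def lambda_path(
    r: CorrelationMatrix,
    m: int = DEFAULT_PATH_LENGTH,
    ratio: float = DEFAULT_PATH_RATIO,
) -> LambdaPath:
    """Log-spaced penalty path from lambda_max = max |r_ij| down to ratio*lambda_max."""
    if m < 2:
        raise EstimationError("path length m must be >= 2")
    if not 0 < ratio < 1:
        raise EstimationError("ratio must lie in (0, 1)")
    off = np.abs(r.values[~np.eye(r.p, dtype=bool)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max <= 0:
        logger.warning("all off-diagonal correlations are zero; degenerate path")
        return LambdaPath(lambdas=np.array([1e-8]))
    return LambdaPath(lambdas=log_spaced_path(lam_max, m, ratio))


def log_spaced_path(lam_max: float, m: int, ratio: float) -> np.ndarray:
    """Log-spaced grid with exact endpoints lam_max and ratio*lam_max.

    The endpoints are pinned exactly so that the first fit sits at the
    null-graph threshold (an exp(log(.)) round trip can lose an ulp and
    spuriously admit the strongest edge).
    """
    lams = np.exp(np.linspace(np.log(lam_max), np.log(ratio * lam_max), m))
    lams[0] = lam_max
    lams[-1] = ratio * lam_max
    return lams


def glasso_fit(
    r: CorrelationMatrix,
    lam: float,
    tol: float = GLASSO_TOL,
    max_sweeps: int = GLASSO_MAX_SWEEPS,
) -> PrecisionMatrix:
    """Single graphical-lasso solve at a fixed penalty."""
    if lam < 0:
        raise EstimationError("lambda must be >= 0")
    theta, _, sweeps = _glasso_single(
        np.ascontiguousarray(r.values), float(lam), tol, max_sweeps
    )
    if sweeps < 0:
        raise EstimationError(
            f"graphical lasso did not converge at lambda={lam} "
            f"within {max_sweeps} sweeps"
        )
    return PrecisionMatrix(values=theta, lam=float(lam))


def ebic(
    r: CorrelationMatrix, theta: PrecisionMatrix | np.ndarray, n: int, gamma: float
) -> float:
    """Extended BIC of a precision matrix against a correlation input."""
    mat = theta.values if isinstance(theta, PrecisionMatrix) else np.asarray(theta, float)
    if mat.shape != r.values.shape:
        raise EstimationError("dimension mismatch between R and Theta")
    if n < 2:
        raise EstimationError("n must be >= 2")
    if gamma < 0:
        raise EstimationError("gamma must be >= 0")
    if np.linalg.eigvalsh(mat)[0] <= 0:
        raise EstimationError("EBIC requires a positive-definite Theta")
    value, _ = _ebic_value(
        np.ascontiguousarray(r.values), np.ascontiguousarray(mat), int(n), float(gamma)
    )
    return float(value)


def precision_to_pcor(theta: PrecisionMatrix | np.ndarray) -> np.ndarray:
    """Partial correlations w_ij = -theta_ij / sqrt(theta_ii theta_jj).

    Exact zeros in Theta stay exact zeros in the weight matrix.
    """
    mat = theta.values if isinstance(theta, PrecisionMatrix) else np.asarray(theta, float)
    if np.any(np.diag(mat) <= 0):
        raise EstimationError("precision diagonal must be positive")
    return _pcor_from_theta(np.ascontiguousarray(mat))


def select_network(
    r: CorrelationMatrix,
    n: int | None = None,
    gamma: float = DEFAULT_GAMMA,
    path: LambdaPath | None = None,
    labels: list[str] | None = None,
    domains: list[str] | None = None,
    tol: float = GLASSO_TOL,
    max_sweeps: int = GLASSO_MAX_SWEEPS,
) -> NetworkModel:
    """Fit the glasso along the path and return the EBIC-minimising network.

    EBIC is evaluated on the penalised estimate without refitting; ties
    resolve toward larger lambda (the sparser model).
    """
    n = int(n if n is not None else r.n)
    if n < 2:
        raise EstimationError("need sample size n >= 2 for EBIC selection")
    if path is None:
        path = lambda_path(r)
    theta, best_idx, ebics, edge_counts = _select_path_kernel(
        np.ascontiguousarray(r.values),
        np.ascontiguousarray(path.lambdas),
        n,
        float(gamma),
        tol,
        max_sweeps,
    )
    if best_idx < 0:
        bad = int(np.argmax(~np.isfinite(ebics)))
        raise EstimationError(
            f"graphical lasso failed to converge at lambda={path.lambdas[bad]:.6g}"
        )
    weights = _pcor_from_theta(theta)
    lam = float(path.lambdas[best_idx])
    labels = labels or r.labels or [f"v{i}" for i in range(r.p)]
    return NetworkModel(
        weights=weights,
        precision=PrecisionMatrix(values=theta, lam=lam),
        labels=list(labels),
        lam=lam,
        ebic=float(ebics[best_idx]),
        gamma=float(gamma),
        n=n,
        domains=list(domains) if domains is not None else None,
        path=LambdaPath(
            lambdas=path.lambdas, ebics=ebics, edge_counts=edge_counts
        ),
    )
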
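"""Permutation test for differences between two groups' networks.

The observed statistic compares the two groups' independently estimated
networks; under the null hypothesis that both groups come from the same
population, group labels are exchangeable, so the null distribution is
built by repeatedly pooling the respondents, reshuffling the labels
(preserving group sizes) and re-running the *entire* estimation pipeline —
polychoric matrix, glasso path and EBIC selection — for each pseudo-group.
Re-estimating everything per permutation is the expensive but faithful
choice: the null distribution must reflect estimation noise, not just
sampling noise.

Statistics
----------
* weighted:   T = | S(W_A) - S(W_B) | with global strength S = sum_{i<j} |w_ij|;
* unweighted: T = | E_A - E_B | with E the number of edges (an optional
  Hamming-distance variant counts support disagreements instead).

The p-value is the add-one permutation estimate
``p = (1 + #{T*_b >= T_obs}) / (1 + B)``, which is a valid finite-sample
p-value and is bounded below by 1/(B+1).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import _pcor_from_theta, _polychoric_matrix_kernel, _select_path_kernel
from .exceptions import DataError, DegenerateItemError, EstimationError
from .ggm import (
    DEFAULT_GAMMA,
    DEFAULT_PATH_LENGTH,
    DEFAULT_PATH_RATIO,
    GLASSO_MAX_SWEEPS,
    GLASSO_TOL,
    log_spaced_path,
)
from .ordinal import OrdinalDataset
from .polychoric import _tabulate_and_thresholds

logger = logging.getLogger(__name__)

MAX_REDRAWS = 10


@dataclass
class ComparisonResult:
    """Observed statistic, permutation distribution and p-value."""

    t_obs: float
    t_perm: np.ndarray
    p_value: float
    mode: str
    n_permutations: int
    seed: int
    group_sizes: tuple[int, int]
    n_failed_redrawn: int = 0

    def to_json(self, path: str | Path, include_permutations: bool = False) -> None:
        payload = {
            "t_obs": float(self.t_obs),
            "p_value": float(self.p_value),
            "mode": self.mode,
            "n_permutations": int(self.n_permutations),
            "seed": int(self.seed),
            "group_sizes": list(self.group_sizes),
            "n_failed_redrawn": int(self.n_failed_redrawn),
        }
        if include_permutations:
            payload["t_perm"] = [float(x) for x in self.t_perm]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def permutations_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("permutation\tstatistic\n")
            for b, t in enumerate(self.t_perm):
                fh.write(f"{b}\t{t:.10g}\n")


def global_strength(weights: np.ndarray) -> float:
    """Sum of absolute edge weights S = sum_{i<j} |w_ij|."""
    weights = np.asarray(weights, dtype=float)
    if not np.allclose(weights, weights.T, atol=1e-10):
        raise EstimationError("weight matrix must be symmetric")
    if np.any(np.diag(weights) != 0):
        raise EstimationError("weight matrix must have a zero diagonal")
    return float(np.abs(np.triu(weights, k=1)).sum())


def nct_statistic(
    w_a: np.ndarray, w_b: np.ndarray, mode: str = "weighted",
    unweighted_stat: str = "edge_count",
) -> float:
    """Two-network difference statistic in weighted or unweighted mode."""
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if w_a.shape != w_b.shape:
        raise EstimationError("weight matrices must have identical dimensions")
    if mode == "weighted":
        return abs(global_strength(w_a) - global_strength(w_b))
    if mode == "unweighted":
        sup_a = np.triu(w_a, 1) != 0
        sup_b = np.triu(w_b, 1) != 0
        if unweighted_stat == "edge_count":
            return float(abs(int(sup_a.sum()) - int(sup_b.sum())))
        if unweighted_stat == "hamming":
            return float(np.count_nonzero(sup_a != sup_b))
        raise EstimationError(f"unknown unweighted_stat {unweighted_stat!r}")
    raise EstimationError(f"unknown mode {mode!r}")


def _estimate_weights_ordinal(
    values: np.ndarray,
    ncat: np.ndarray,
    gamma: float,
    m: int,
    ratio: float,
    pd_eps: float = 1e-6,
) -> np.ndarray:
    """Polychoric matrix -> EBIC-selected glasso weights, throughput path."""
    codes, ncat2, tau_pad = _tabulate_and_thresholds(values, ncat)
    r_mat = _polychoric_matrix_kernel(codes, ncat2, tau_pad)
    eigval = np.linalg.eigvalsh(r_mat)
    if eigval[0] < pd_eps:
        vals, vecs = np.linalg.eigh(r_mat)
        vals = np.clip(vals, pd_eps, None)
        r_mat = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(r_mat))
        r_mat = r_mat / np.outer(d, d)
        r_mat = (r_mat + r_mat.T) / 2.0
        np.fill_diagonal(r_mat, 1.0)
    return _select_weights(r_mat, values.shape[0], gamma, m, ratio)


def _estimate_weights_continuous(
    values: np.ndarray, gamma: float, m: int, ratio: float
) -> np.ndarray:
    """Pearson matrix -> EBIC-selected glasso weights (domain scores)."""
    sd = values.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateItemError("constant column in score matrix")
    r_mat = np.corrcoef(values, rowvar=False)
    r_mat = np.clip((r_mat + r_mat.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r_mat, 1.0)
    eigval = np.linalg.eigvalsh(r_mat)
    if eigval[0] < 1e-6:
        vals, vecs = np.linalg.eigh(r_mat)
        vals = np.clip(vals, 1e-6, None)
        r_mat = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(r_mat))
        r_mat = r_mat / np.outer(d, d)
        np.fill_diagonal(r_mat, 1.0)
    return _select_weights(r_mat, values.shape[0], gamma, m, ratio)


def _select_weights(
    r_mat: np.ndarray, n: int, gamma: float, m: int, ratio: float
) -> np.ndarray:
    p = r_mat.shape[0]
    off = np.abs(r_mat[~np.eye(p, dtype=bool)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max <= 0:
        return np.zeros((p, p))
    lambdas = log_spaced_path(lam_max, m, ratio)
    theta, best_idx, _, _ = _select_path_kernel(
        np.ascontiguousarray(r_mat), lambdas, n, gamma, GLASSO_TOL, GLASSO_MAX_SWEEPS
    )
    if best_idx < 0:
        raise EstimationError("graphical lasso failed to converge")
    return _pcor_from_theta(theta)


def nct_permutation_test(
    data_a: OrdinalDataset | np.ndarray,
    data_b: OrdinalDataset | np.ndarray,
    n_permutations: int = 1000,
    mode: str = "weighted",
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    estimator: str = "polychoric",
    unweighted_stat: str = "edge_count",
    path_length: int = DEFAULT_PATH_LENGTH,
    path_ratio: float = DEFAULT_PATH_RATIO,
    n_jobs: int = 1,
) -> ComparisonResult:
    """Permutation network-comparison test between two samples.

    Each permutation pools the respondents, reshuffles group labels
    preserving the group sizes, and re-runs the full estimation for both
    pseudo-groups.  A permutation whose pseudo-group contains a
    zero-variance item is redrawn (up to 10 times, counted and logged).
    Per-permutation RNG streams are spawned from the master seed, so the
    result is reproducible and independent of any execution order.
    """
    results = compare_networks(
        data_a,
        data_b,
        n_permutations=n_permutations,
        modes=(mode,),
        gamma=gamma,
        seed=seed,
        estimator=estimator,
        unweighted_stat=unweighted_stat,
        path_length=path_length,
        path_ratio=path_ratio,
        n_jobs=n_jobs,
    )
    return results[mode]


def compare_networks(
    data_a: OrdinalDataset | np.ndarray,
    data_b: OrdinalDataset | np.ndarray,
    n_permutations: int = 1000,
    modes: tuple[str, ...] = ("weighted", "unweighted"),
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    estimator: str = "polychoric",
    unweighted_stat: str = "edge_count",
    path_length: int = DEFAULT_PATH_LENGTH,
    path_ratio: float = DEFAULT_PATH_RATIO,
    n_jobs: int = 1,
) -> dict[str, ComparisonResult]:
    """Run the permutation test once, reporting several statistics.

    All requested modes share the same permutations and network fits, so a
    weighted and an unweighted result cost one run.  With ``n_jobs > 1`` the
    permutations are distributed over processes; because every permutation
    owns a pre-spawned RNG stream, the result is identical for any worker
    count.
    """
    values_a, values_b, ncat = _extract_values(data_a, data_b, estimator)
    n_a, n_b = values_a.shape[0], values_b.shape[0]
    p = values_a.shape[1]
    if min(n_a, n_b) < p:
        warnings.warn(
            f"group size {min(n_a, n_b)} below the number of items {p}; "
            "estimates will be unstable",
            stacklevel=2,
        )
    if estimator == "polychoric":
        def fit(vals: np.ndarray) -> np.ndarray:
            return _estimate_weights_ordinal(vals, ncat, gamma, path_length, path_ratio)
    elif estimator == "pearson":
        def fit(vals: np.ndarray) -> np.ndarray:
            return _estimate_weights_continuous(vals, gamma, path_length, path_ratio)
    else:
        raise EstimationError(f"unknown estimator {estimator!r}")

    w_a = fit(values_a)
    w_b = fit(values_b)
    t_obs = {
        m: nct_statistic(w_a, w_b, m, unweighted_stat=unweighted_stat) for m in modes
    }

    pooled = np.vstack([values_a, values_b])
    n_total = n_a + n_b
    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(n_permutations)
    t_perm = {m: np.empty(n_permutations) for m in modes}

    def one_permutation(b: int) -> tuple[dict[str, float], int]:
        rng = np.random.default_rng(child_seeds[b])
        redrawn = 0
        for attempt in range(MAX_REDRAWS + 1):
            perm = rng.permutation(n_total)
            try:
                w_pa = fit(pooled[perm[:n_a]])
                w_pb = fit(pooled[perm[n_a:]])
            except DegenerateItemError:
                redrawn += 1
                if attempt == MAX_REDRAWS:
                    raise EstimationError(
                        f"permutation {b}: degenerate pseudo-group after "
                        f"{MAX_REDRAWS} redraws"
                    )
                continue
            break
        stats = {
            m: nct_statistic(w_pa, w_pb, m, unweighted_stat=unweighted_stat)
            for m in modes
        }
        return stats, redrawn

    if n_jobs == 1:
        per_perm = [one_permutation(b) for b in range(n_permutations)]
    else:
        from joblib import Parallel, delayed

        per_perm = Parallel(n_jobs=n_jobs)(
            delayed(one_permutation)(b) for b in range(n_permutations)
        )
    n_redrawn = 0
    for b, (stats, redrawn) in enumerate(per_perm):
        n_redrawn += redrawn
        for m in modes:
            t_perm[m][b] = stats[m]
    if n_redrawn:
        logger.info("redrew %d degenerate permutations", n_redrawn)

    out = {}
    for m in modes:
        count = int(np.sum(t_perm[m] >= t_obs[m]))
        out[m] = ComparisonResult(
            t_obs=float(t_obs[m]),
            t_perm=t_perm[m],
            p_value=(1.0 + count) / (1.0 + n_permutations),
            mode=m,
            n_permutations=n_permutations,
            seed=seed,
            group_sizes=(n_a, n_b),
            n_failed_redrawn=n_redrawn,
        )
    return out


def _extract_values(
    data_a, data_b, estimator: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if isinstance(data_a, OrdinalDataset) != isinstance(data_b, OrdinalDataset):
        raise DataError("both groups must have the same container type")
    if isinstance(data_a, OrdinalDataset):
        if data_a.labels != data_b.labels or not np.array_equal(
            data_a.n_categories, data_b.n_categories
        ):
            raise DataError("the two groups must share an identical instrument")
        ncat = data_a.n_categories
        return data_a.values, data_b.values, ncat
    values_a = np.asarray(data_a, dtype=float)
    values_b = np.asarray(data_b, dtype=float)
    if values_a.ndim != 2 or values_b.ndim != 2:
        raise DataError("inputs must be 2-D matrices")
    if values_a.shape[1] != values_b.shape[1]:
        raise DataError("the two groups must have the same columns")
    if estimator == "polychoric":
        ncat = (
            np.maximum(values_a.max(axis=0), values_b.max(axis=0)).astype(np.int64) + 1
        )
        return values_a.astype(np.int64), values_b.astype(np.int64), ncat
    return values_a, values_b, None
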
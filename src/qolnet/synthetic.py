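"""Synthetic ordinal questionnaire data with known network structure.

Generation inverts the model the estimation pipeline assumes: a latent
multivariate Gaussian with a sparse precision matrix is sampled, and each
latent variable is discretised into ordinal categories by fixed thresholds.
Because the underlying precision matrix (and thus the true partial
correlation network) is known, every pipeline stage — polychoric recovery,
glasso support selection, comparison-test calibration — can be tested
end to end.

Structures
----------
* ``chain``: items form a path graph (i, i+1 connected).
* ``random``: each pair is an edge independently with a given density.
* ``clustered``: items fall into domain blocks; blocks are fully connected
  internally with positive weights (the positive manifold of questionnaire
  domains) and sparsely, with random signs, between blocks.  The default
  block sizes (10, 4, 2, 5, 4, 2, 3, 5) mirror an 8-domain, 36-item
  instrument.

Off-diagonal weights are drawn from +-[0.2, 0.4] (detectable at study-like
sample sizes without being trivial) and the diagonal is set to 1 plus the
row-wise absolute sum, which guarantees positive definiteness by diagonal
dominance.  A two-group design multiplies group B's edge weights (partial
correlations) by a factor delta; delta = 1 gives an exchangeable null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import ndtri

from .exceptions import DataError
from .ordinal import ItemSpec, OrdinalDataset

DEFAULT_BLOCK_SIZES = (10, 4, 2, 5, 4, 2, 3, 5)
WEIGHT_LO, WEIGHT_HI = 0.2, 0.4

# SF-36-like mixed category profile used by the clustered default: binary for
# role-limitation-like blocks, 3-category for PF-like, 5-6 for the rest.
_BLOCK_NCATS = (3, 2, 5, 5, 6, 5, 2, 6)


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic two-group ordinal dataset."""

    p: int = 8
    structure: str = "chain"  # chain | random | clustered
    density: float = 0.2  # random structure only
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    n_unclustered: int = 1  # free items outside every block (clustered only)
    between_density: float = 0.05  # clustered structure only
    n_categories: tuple[int, ...] | int = 5
    threshold_scheme: str = "equiprobable"  # equiprobable | skewed
    skew_alpha: float = 1.5
    n_per_group: int = 300
    delta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure == "clustered":
            self.p = int(sum(self.block_sizes)) + int(self.n_unclustered)
        if self.p < 2:
            raise DataError("need at least two items")
        if not 0 < self.density <= 1:
            raise DataError("density must lie in (0, 1]")
        if self.delta <= 0:
            raise DataError("delta must be positive")
        ncats = self.category_counts()
        if np.any(ncats < 2):
            raise DataError("category counts must be >= 2")

    def category_counts(self) -> np.ndarray:
        if isinstance(self.n_categories, int):
            if self.structure == "clustered" and self.n_categories == 5:
                # default mixed profile per block
                out = []
                for size, ncat in zip(self.block_sizes, _BLOCK_NCATS):
                    out.extend([ncat] * size)
                out.extend([5] * self.n_unclustered)
                return np.array(out, dtype=np.int64)
            return np.full(self.p, self.n_categories, dtype=np.int64)
        counts = np.asarray(self.n_categories, dtype=np.int64)
        if counts.shape[0] != self.p:
            raise DataError("per-item category counts must have length p")
        return counts


def make_precision(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sparse precision matrix and boolean edge support for a spec.

    Diagonal dominance (theta_ii = 1 + sum_j |theta_ij|) guarantees positive
    definiteness by the Gershgorin circle theorem.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.p
    support = np.zeros((p, p), dtype=bool)
    signs = np.ones((p, p))
    if spec.structure == "chain":
        for i in range(p - 1):
            support[i, i + 1] = support[i + 1, i] = True
    elif spec.structure == "random":
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < spec.density:
                    support[i, j] = support[j, i] = True
    elif spec.structure == "clustered":
        blocks = _block_ids(spec.block_sizes, spec.n_unclustered)
        for i in range(p):
            for j in range(i + 1, p):
                if blocks[i] >= 0 and blocks[i] == blocks[j]:
                    support[i, j] = support[j, i] = True
                elif rng.random() < spec.between_density:
                    support[i, j] = support[j, i] = True
                    s = -1.0 if rng.random() < 0.5 else 1.0
                    signs[i, j] = signs[j, i] = s
    else:
        raise DataError(f"unknown structure {spec.structure!r}")

    theta = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if support[i, j]:
                w = rng.uniform(WEIGHT_LO, WEIGHT_HI)
                if spec.structure != "clustered":
                    w *= -1.0 if rng.random() < 0.5 else 1.0
                else:
                    w *= signs[i, j]
                theta[i, j] = theta[j, i] = w
    _redominate(theta)
    return theta, support


def _block_ids(block_sizes, n_unclustered: int = 0) -> np.ndarray:
    """Block id per item; unclustered free items get id -1."""
    ids = []
    for b, size in enumerate(block_sizes):
        ids.extend([b] * size)
    ids.extend([-1] * n_unclustered)
    return np.array(ids)


def _redominate(theta: np.ndarray) -> None:
    """Set diagonal to 1 + row-wise absolute off-diagonal sum, in place."""
    p = theta.shape[0]
    np.fill_diagonal(theta, 0.0)
    row = np.abs(theta).sum(axis=1)
    theta[np.diag_indices(p)] = 1.0 + row


def thresholds_for(
    ncat: np.ndarray, scheme: str = "equiprobable", alpha: float = 1.5
) -> list[np.ndarray]:
    """Per-item latent thresholds.

    ``equiprobable`` makes every category equally likely; ``skewed`` puts
    category probabilities proportional to ``alpha**k``, emulating the
    right-shifted response distributions of health items.
    """
    out = []
    for k in ncat:
        k = int(k)
        if scheme == "equiprobable":
            probs = np.full(k, 1.0 / k)
        elif scheme == "skewed":
            probs = alpha ** np.arange(k)
            probs = probs / probs.sum()
        else:
            raise DataError(f"unknown threshold scheme {scheme!r}")
        out.append(ndtri(np.cumsum(probs)[:-1]))
    return out


def sample_ordinal(
    theta: np.ndarray,
    thresholds: list[np.ndarray],
    n: int,
    seed: int | np.random.Generator = 0,
    items: list[ItemSpec] | None = None,
) -> OrdinalDataset:
    """Draw n respondents from the latent-Gaussian ordinal model.

    Sigma = Theta^{-1} rescaled to a correlation matrix; item k's response is
    the count of its thresholds lying below the latent draw (0-based code).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = theta.shape[0]
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    latent = rng.multivariate_normal(np.zeros(p), sigma, size=n, method="cholesky")
    values = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        values[:, j] = np.searchsorted(thresholds[j], latent[:, j], side="left")
    if items is None:
        items = [
            ItemSpec(label=f"v{j}", n_categories=len(thresholds[j]) + 1)
            for j in range(p)
        ]
    return OrdinalDataset(values=values, items=items)


@dataclass
class TwoGroupTruth:
    """Ground truth behind a simulated two-group dataset."""

    support: np.ndarray
    theta_a: np.ndarray
    theta_b: np.ndarray
    delta: float
    block_ids: np.ndarray | None = None

    def pcor(self, which: str = "a") -> np.ndarray:
        theta = self.theta_a if which == "a" else self.theta_b
        d = np.sqrt(np.diag(theta))
        w = -theta / np.outer(d, d)
        np.fill_diagonal(w, 0.0)
        return w

    def to_json(self, path: str | Path) -> None:
        payload = {
            "delta": self.delta,
            "edge_count": int(np.count_nonzero(np.triu(self.support, 1))),
            "support": self.support.astype(int).tolist(),
            "theta_a": self.theta_a.tolist(),
            "theta_b": self.theta_b.tolist(),
        }
        if self.block_ids is not None:
            payload["block_ids"] = self.block_ids.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)


def make_two_groups(
    spec: SyntheticSpec,
) -> tuple[OrdinalDataset, OrdinalDataset, TwoGroupTruth]:
    """Two ordinal samples: group A from Theta, group B with every edge
    weight (partial correlation) multiplied by delta.

    The off-diagonals of Theta are scaled by delta with the diagonal kept,
    so w_B = delta * w_A holds exactly; the diagonal is re-dominated
    (lifted uniformly) only in the rare case the scaled matrix loses
    positive definiteness, which attenuates the multiplier slightly.
    delta = 1 reproduces Theta exactly — an exchangeable null.
    """
    theta_a, support = make_precision(spec)
    theta_b = theta_a.copy()
    off = ~np.eye(spec.p, dtype=bool)
    theta_b[off] *= spec.delta
    min_eig = np.linalg.eigvalsh(theta_b)[0]
    if min_eig <= 1e-6:
        theta_b[np.diag_indices(spec.p)] += 1e-6 - min_eig
    assert np.linalg.eigvalsh(theta_b)[0] > 0  # guaranteed by the lift
    ncat = spec.category_counts()
    taus = thresholds_for(ncat, spec.threshold_scheme, spec.skew_alpha)
    # separate stream from the one make_precision used for the weights
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if spec.structure == "clustered":
        ids = _block_ids(spec.block_sizes, spec.n_unclustered)
        doms = ["none" if b < 0 else f"D{b + 1}" for b in ids]
    else:
        doms = ["none"] * spec.p
    items = [
        ItemSpec(label=f"v{j}", n_categories=int(ncat[j]), domain=doms[j])
        for j in range(spec.p)
    ]
    data_a = sample_ordinal(theta_a, taus, spec.n_per_group, rng, items=items)
    data_b = sample_ordinal(theta_b, taus, spec.n_per_group, rng, items=items)
    blocks = (
        _block_ids(spec.block_sizes, spec.n_unclustered)
        if spec.structure == "clustered"
        else None
    )
    truth = TwoGroupTruth(
        support=support,
        theta_a=theta_a,
        theta_b=theta_b,
        delta=spec.delta,
        block_ids=blocks,
    )
    return data_a, data_b, truth
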
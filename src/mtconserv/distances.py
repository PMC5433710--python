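"""Mean pairwise GTR+G+I distances per gene.

Model parameters (exchangeabilities, gamma shape over 4 categories,
invariant-site proportion; base frequencies taken empirically) are
fitted once per gene by composite maximum likelihood over the pairwise
nucleotide count matrices, then each unordered pair's distance is the
scalar ML branch length under the shared model.  Distances are capped
at 10 substitutions/site with a warning.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy import optimize

from .io import CodonAlignment
from .rates import discrete_gamma_rates

log = logging.getLogger(__name__)

_BASES = "ACGT"
_B_INDEX = {b: i for i, b in enumerate(_BASES)}
MAX_DISTANCE = 10.0


def _pair_counts(seqs: list[np.ndarray]) -> dict[tuple[int, int], np.ndarray]:
    counts = {}
    n = len(seqs)
    for i, j in itertools.combinations(range(n), 2):
        a, b = seqs[i], seqs[j]
        ok = (a >= 0) & (b >= 0)
        idx = a[ok] * 4 + b[ok]
        counts[(i, j)] = np.bincount(idx, minlength=16).reshape(4, 4).astype(float)
    return counts


def _encode(alignment: CodonAlignment) -> list[np.ndarray]:
    out = []
    for s in alignment.nucleotides():
        arr = np.fromiter(
            (_B_INDEX.get(ch, -1) for ch in s), dtype=int, count=len(s)
        )
        out.append(arr)
    return out


class GTRGammaI:
    """Shared-parameter GTR+G+I pairwise distance model."""

    def __init__(self, pi: np.ndarray, rates: np.ndarray = None,
                 alpha: float = 0.5, p_inv: float = 0.1, k: int = 4):
        self.pi = pi
        self.rates = np.ones(6) if rates is None else rates  # AC AG AT CG CT GT
        self.alpha = alpha
        self.p_inv = p_inv
        self.k = k
        self._decompose()

    def _decompose(self):
        S = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(self.rates, pairs):
            S[i, j] = S[j, i] = r
        Q = S * self.pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(self.pi * np.diag(Q)).sum()
        Q /= scale
        rt = np.sqrt(self.pi)
        A = (Q * rt[:, None]) / rt[None, :]
        A = (A + A.T) / 2
        self._eval, evec = np.linalg.eigh(A)
        self._left = evec / rt[:, None]
        self._right = (evec * rt[:, None]).T
        self._gamma = discrete_gamma_rates(self.alpha, self.k)

    def joint(self, t: float) -> np.ndarray:
        """Joint probability matrix diag(pi) @ P_mix(t)."""
        P = np.zeros((4, 4))
        for r in self._gamma:
            P += (self._left * np.exp(self._eval * r * t)[None, :]) @ self._right
        P *= (1.0 - self.p_inv) / self.k
        P += self.p_inv * np.eye(4)
        return self.pi[:, None] * np.clip(P, 1e-12, None)

    def pair_loglik(self, counts: np.ndarray, t: float) -> float:
        return float((counts * np.log(self.joint(t))).sum())

    def ml_distance(self, counts: np.ndarray) -> float:
        if counts.sum() == 0:
            return np.nan
        off = counts.sum() - np.trace(counts)
        if off == 0:
            return 0.0
        res = optimize.minimize_scalar(
            lambda t: -self.pair_loglik(counts, float(t)),
            bounds=(1e-6, MAX_DISTANCE),
            method="bounded",
            options={"xatol": 1e-6},
        )
        t = float(res.x)
        if t >= MAX_DISTANCE * 0.999:
            log.warning("pairwise distance capped at %.1f", MAX_DISTANCE)
            return MAX_DISTANCE
        return t


def fit_gene_distances(
    alignment: CodonAlignment, n_rounds: int = 2
) -> tuple[np.ndarray, GTRGammaI]:
    """Pairwise GTR+G+I ML distance matrix under shared gene-level
    parameters (condensed upper-triangle order like scipy's pdist)."""
    if alignment.n_taxa < 2:
        raise ValueError("need at least two sequences")
    seqs = _encode(alignment)
    counts = _pair_counts(seqs)
    total = sum(counts.values())
    pi = total.sum(axis=0) + total.sum(axis=1)
    pi = pi / pi.sum()
    model = GTRGammaI(pi)
    # initial distances from the shared model with default parameters
    dists = {ij: model.ml_distance(c) for ij, c in counts.items()}

    def objective(theta):
        rates = np.exp(np.concatenate([theta[:5], [0.0]]))
        alpha = float(np.exp(theta[5]))
        p_inv = float(1.0 / (1.0 + np.exp(-theta[6])))
        m = GTRGammaI(pi, rates, alpha, min(p_inv, 0.95))
        return -sum(
            m.pair_loglik(c, max(dists[ij], 1e-6))
            for ij, c in counts.items()
        )

    theta = np.array([0.0, 1.0, 0.0, 0.0, 1.0, np.log(0.5), -2.0])
    for _ in range(n_rounds):
        res = optimize.minimize(
            objective, theta, method="Nelder-Mead",
            options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-2},
        )
        theta = res.x
        rates = np.exp(np.concatenate([theta[:5], [0.0]]))
        alpha = float(np.exp(theta[5]))
        p_inv = float(1.0 / (1.0 + np.exp(-theta[6])))
        model = GTRGammaI(pi, rates, alpha, min(p_inv, 0.95))
        dists = {ij: model.ml_distance(c) for ij, c in counts.items()}
    n = alignment.n_taxa
    out = np.array(
        [dists[(i, j)] for i, j in itertools.combinations(range(n), 2)]
    )
    return out, model


def gene_mean_distance(alignment: CodonAlignment) -> float:
    """Arithmetic mean pairwise GTR+G+I distance of one gene."""
    dists, _ = fit_gene_distances(alignment)
    return float(np.nanmean(dists))
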
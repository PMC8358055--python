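"""Mean-field direct coupling analysis (mfDCA) over an aligned family.

The estimator is the classic naive mean-field chain: sequences are
down-weighted by local identity clustering, single and pairwise state
frequencies are regularized with a relative pseudocount, couplings are the
negative inverse of the connected-correlation matrix (one reference state
dropped per column), and each column pair is scored by direct information

    DI(s,t) = sum_{X,X'} Fdir_{s,t}(X,X') ln[ Fdir_{s,t}(X,X')
                                              / (F_s(X) F_t(X')) ]

where the two-site direct distribution Fdir ~ exp(e_{s,t}) h_s h_t' has
its auxiliary single-site fields fitted so that its marginals reproduce
the empirical F_s and F_t.  DI is a Kullback-Leibler divergence and hence
non-negative; it isolates direct co-evolutionary coupling from the
transitive correlation that contaminates plain mutual information.

The state space is the 20 residues plus the gap (q = 21); the gap serves
as the reference state in the coupling inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import AlignedFamily

__all__ = [
    "Q_STATES",
    "CouplingModel",
    "DIMatrix",
    "reweight_sequences",
    "site_frequencies",
    "infer_couplings",
    "direct_information",
    "build_dca_network",
    "dca_pipeline",
]

#: 20 residues + gap.
Q_STATES = 21


class DCAError(RuntimeError):
    """Numerical failure inside the mfDCA chain."""


@dataclass
class CouplingModel:
    """Frequencies and (optionally) couplings of the mean-field model.

    Attributes
    ----------
    f1 : (L, q) single-site frequencies, each row sums to 1.
    f2 : (L, L, q, q) pair frequencies, each (s, t) block sums to 1.
    weights : (M,) per-sequence weights from identity reweighting.
    pseudocount : relative pseudocount weight lambda in [0, 1].
    couplings : (L, L, q, q) mean-field couplings, or None before inference.
    """

    f1: np.ndarray
    f2: np.ndarray
    weights: np.ndarray
    pseudocount: float
    couplings: np.ndarray | None = None

    @property
    def n_columns(self) -> int:
        return self.f1.shape[0]

    @property
    def m_eff(self) -> float:
        """Effective number of sequences after reweighting."""
        return float(self.weights.sum())


@dataclass
class DIMatrix:
    """Symmetric direct-information scores per unordered column pair (nats)."""

    scores: np.ndarray  # (L, L), zero diagonal

    def __post_init__(self) -> None:
        s = self.scores
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("DI matrix must be square")
        if not np.allclose(s, s.T):
            raise ValueError("DI matrix must be symmetric")
        if (s < -1e-9).any():
            raise ValueError("DI scores must be non-negative")

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]

    def pairs(self) -> Iterator[tuple[int, int, float]]:
        """Yield (s, t, DI) for s < t, in descending DI order."""
        L = self.n_columns
        idx = [(s, t) for s in range(L) for t in range(s + 1, L)]
        idx.sort(key=lambda st: (-self.scores[st], st))
        for s, t in idx:
            yield s, t, float(self.scores[s, t])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, t, di) for s, t, di in self.pairs()],
            columns=["col_s", "col_t", "DI"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def reweight_sequences(fam: AlignedFamily, identity_cutoff: float = 0.8) -> np.ndarray:
    """Identity-based sequence weights: 1 / (number of neighbours >= cutoff).

    A sequence's neighbourhood includes itself, so weights lie in (0, 1]
    and their sum is the effective sequence number M_eff.
    """
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError(f"identity cutoff must be in (0, 1], got {identity_cutoff}")
    X = fam.to_indices()
    M, L = X.shape
    weights = np.empty(M)
    # block the M x M identity computation to bound memory on big families
    block = max(1, int(2e7 // (M * L)) or 1)
    ident = np.empty((M, M), dtype=bool)
    for start in range(0, M, max(block, 1)):
        stop = min(start + max(block, 1), M)
        sim = (X[start:stop, None, :] == X[None, :, :]).mean(axis=2)
        ident[start:stop] = sim >= identity_cutoff
    weights = 1.0 / ident.sum(axis=1)
    return weights


def site_frequencies(
    fam: AlignedFamily,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> CouplingModel:
    """Pseudocount-regularized single and pair frequencies.

    With relative pseudocount lambda, F_s(X) = lambda/q + (1-lambda) *
    weighted empirical fraction, and pair blocks analogously with
    lambda/q^2; the s = s diagonal block keeps its delta structure so pair
    marginals stay consistent with the single-site table.
    """
    if weights is None:
        weights = reweight_sequences(fam)
    lam = float(pseudocount)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"pseudocount must be in [0, 1], got {lam}")
    X = fam.to_indices()
    M, L = X.shape
    q = Q_STATES
    w = np.asarray(weights, dtype=float)
    if w.shape != (M,):
        raise ValueError("weights length must match the number of sequences")
    meff = w.sum()

    onehot = np.zeros((M, L, q))
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0

    f1_emp = np.einsum("m,mla->la", w, onehot) / meff
    flat = onehot.reshape(M, L * q)
    f2_emp = (flat * w[:, None]).T @ flat / meff
    f2_emp = f2_emp.reshape(L, q, L, q).transpose(0, 2, 1, 3)

    f1 = lam / q + (1.0 - lam) * f1_emp
    f2 = lam / (q * q) + (1.0 - lam) * f2_emp
    # same-column block: diagonal in the two states by construction
    for s in range(L):
        f2[s, s] = np.diag(f1[s])
    return CouplingModel(f1=f1, f2=f2, weights=w, pseudocount=lam)


def infer_couplings(model: CouplingModel) -> CouplingModel:
    """Mean-field couplings e = -C^{-1} from the connected correlations.

    The correlation matrix drops the last (gap) state of every column as
    reference; couplings are mapped back to the full q-state space with
    zeros in the reference rows/columns.
    """
    L, q = model.f1.shape
    if L < 2:
        model.couplings = np.zeros((L, L, q, q))
        return model
    r = q - 1
    f1 = model.f1[:, :r]
    C = model.f2[:, :, :r, :r].transpose(0, 2, 1, 3).reshape(L * r, L * r).copy()
    C -= np.outer(f1.reshape(-1), f1.reshape(-1))
    try:
        invC = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise DCAError(
            "correlation matrix is singular; increase the pseudocount"
        ) from exc
    e_red = -invC.reshape(L, r, L, r).transpose(0, 2, 1, 3)
    couplings = np.zeros((L, L, q, q))
    couplings[:, :, :r, :r] = e_red
    # no self couplings by convention
    for s in range(L):
        couplings[s, s] = 0.0
    model.couplings = couplings
    return model


def _fit_direct_distribution(
    W: np.ndarray, fs: np.ndarray, ft: np.ndarray, tol: float, max_iter: int
) -> np.ndarray:
    """Two-site direct distribution with marginals (fs, ft) under kernel W.

    Fixed-point iteration on the auxiliary single-site fields (equivalently
    a Sinkhorn scaling of W): mu1 ∝ fs / (W mu2), mu2 ∝ ft / (W^T mu1).
    """
    from scipy.special import logsumexp

    q = W.shape[0]
    mu2 = np.full(q, 1.0 / q)
    for _ in range(max_iter):
        mu1 = fs / (W @ mu2)
        mu1 /= mu1.sum()
        mu2 = ft / (W.T @ mu1)
        mu2 /= mu2.sum()
        P = mu1[:, None] * W * mu2[None, :]
        P /= P.sum()
        err = max(np.abs(P.sum(axis=1) - fs).max(), np.abs(P.sum(axis=0) - ft).max())
        if err < tol:
            return P
    # strongly coupled pairs make the plain scaling sublinear; escalate to an
    # over-relaxed log-domain iteration (same fixed point, faster contraction)
    logW = np.log(W)
    lfs, lft = np.log(fs), np.log(ft)
    u = np.log(mu1)
    v = np.log(mu2)
    omega = 1.9
    for _ in range(50 * max_iter):
        u += omega * (lfs - logsumexp(logW + v[None, :], axis=1) - u)
        v += omega * (lft - logsumexp(logW.T + u[None, :], axis=1) - v)
        logP = u[:, None] + logW + v[None, :]
        logP -= logsumexp(logP)
        P = np.exp(logP)
        err = max(np.abs(P.sum(axis=1) - fs).max(), np.abs(P.sum(axis=0) - ft).max())
        if err < tol:
            return P
    raise DCAError(
        f"direct-distribution marginal fit did not converge within "
        f"{max_iter} plain and {50 * max_iter} over-relaxed iterations"
    )


def direct_information(
    model: CouplingModel, tol: float = 1e-6, max_iter: int = 500
) -> DIMatrix:
    """Direct information per column pair from the fitted two-site models."""
    if model.couplings is None:
        raise ValueError("couplings not inferred yet; call infer_couplings first")
    L, q = model.f1.shape
    di = np.zeros((L, L))
    for s in range(L):
        fs = model.f1[s]
        for t in range(s + 1, L):
            ft = model.f1[t]
            W = np.exp(model.couplings[s, t])
            P = _fit_direct_distribution(W, fs, ft, tol=tol, max_iter=max_iter)
            ref = np.outer(fs, ft)
            mask = P > 0
            val = float(np.sum(P[mask] * np.log(P[mask] / ref[mask])))
            di[s, t] = di[t, s] = max(val, 0.0)
    return DIMatrix(scores=di)


def build_dca_network(
    di: DIMatrix, top_k: int | None = None, min_di: float | None = None
) -> nx.Graph:
    """DI-weighted residue-column network G_DCA.

    Exactly one retention rule must be given: the ``top_k`` highest-DI
    pairs (ties at the cut are all kept, so the edge count may exceed k)
    or every pair with DI >= ``min_di``.  Nodes are the columns incident to
    a retained pair.
    """
    if (top_k is None) == (min_di is None):
        raise ValueError("give exactly one of top_k or min_di")
    pairs = list(di.pairs())
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        if len(pairs) > top_k:
            cutoff = pairs[top_k - 1][2]
            pairs = [p for p in pairs if p[2] >= cutoff]
    else:
        pairs = [p for p in pairs if p[2] >= min_di]
    g = nx.Graph(provenance="dca")
    for s, t, w in pairs:
        g.add_edge(s, t, weight=w)
    return g


def dca_pipeline(
    fam: AlignedFamily,
    identity_cutoff: float = 0.8,
    pseudocount: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[CouplingModel, DIMatrix]:
    """Run the full mfDCA chain on one family and return (model, DI)."""
    weights = reweight_sequences(fam, identity_cutoff=identity_cutoff)
    model = site_frequencies(fam, weights=weights, pseudocount=pseudocount)
    infer_couplings(model)
    return model, direct_information(model, tol=tol, max_iter=max_iter)
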
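"""Network deconvolution: removing amplified (indirect) ceRNA edges.

Two genes with many common ceRNA partners accumulate transitive
correlation, so an observed similarity network G_obs overstates direct
interaction. Modelling the observed network as the series
G_obs = G_dir + G_dir^2 + G_dir^3 + ... (closed form
G_dir = G_obs (I + G_obs)^{-1}) lets the direct part be recovered by
mapping each eigenvalue lambda of the (scaled) observed network to
beta*lambda / (1 + beta*lambda). The scaling beta > 0 is chosen so the
largest-magnitude direct eigenvalue equals ``max_direct_eig``, which
keeps the geometric series convergent. Edges are then re-ranked by their
deconvolved (direct) score and only the strongest fraction is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CeRNANetwork

__all__ = ["DeconvolutionResult", "deconvolve_network", "rank_and_retain_edges"]

_TIE_RTOL = 1e-9


@dataclass
class DeconvolutionResult:
    """Symmetric direct-score matrix, its node order and the beta used."""

    direct_scores: np.ndarray
    node_order: list[str]
    beta: float

    def score_frame(self, net: CeRNANetwork) -> pd.Series:
        """Direct score at each observed edge position of ``net``."""
        pos = {n: i for i, n in enumerate(self.node_order)}
        ia = net.edges["gene_a"].map(pos).to_numpy()
        ib = net.edges["gene_b"].map(pos).to_numpy()
        return pd.Series(self.direct_scores[ia, ib], index=net.edges.index)


def _choose_beta(eigvals: np.ndarray, max_direct_eig: float) -> float:
    """Largest beta keeping every mapped eigenvalue within +-max_direct_eig.

    For lambda > 0 the map beta*lambda/(1+beta*lambda) grows toward 1, so
    the binding constraint is beta <= d / (lambda_max (1 - d)); for
    lambda < 0 the map diverges as beta*lambda -> -1, giving
    beta <= d / (|lambda_min| (1 + d)).
    """
    d = max_direct_eig
    lam_p = eigvals.max(initial=0.0)
    lam_n = eigvals.min(initial=0.0)
    bounds = []
    if lam_p > 0:
        bounds.append(d / (lam_p * (1.0 - d)))
    if lam_n < 0:
        bounds.append(d / (-lam_n * (1.0 + d)))
    return min(bounds) if bounds else 1.0


def deconvolve_network(
    net: CeRNANetwork, max_direct_eig: float = 0.9
) -> DeconvolutionResult:
    """Closed-form network deconvolution of the observed weighted network.

    Eigendecomposes the symmetric adjacency G_obs = V diag(lambda) V^T and
    returns direct_scores = V diag(beta*lambda/(1+beta*lambda)) V^T with
    beta chosen by :func:`_choose_beta`. Only entries at observed edge
    positions are meaningful downstream; no new edges are ever created.
    """
    if not 0 < max_direct_eig < 1:
        raise ValueError("max_direct_eig must lie in (0, 1)")
    A, order = net.adjacency_matrix()
    if not np.isfinite(A).all():
        raise ValueError("non-finite weight in adjacency matrix")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency matrix is not symmetric")
    if A.size == 0 or not A.any():
        return DeconvolutionResult(np.zeros_like(A), order, 1.0)

    lam, V = np.linalg.eigh(A)
    beta = _choose_beta(lam, max_direct_eig)
    lam_dir = beta * lam / (1.0 + beta * lam)
    D = (V * lam_dir) @ V.T
    D = (D + D.T) / 2.0
    return DeconvolutionResult(D, order, beta)


def rank_and_retain_edges(
    result: DeconvolutionResult,
    net: CeRNANetwork,
    fraction: float = 1.0 / 3.0,
    drop_nonpositive: bool = True,
) -> CeRNANetwork:
    """Keep the strongest ``fraction`` of edges by deconvolved score.

    Edges with non-positive direct score are removed first (they carry no
    direct evidence under the series model); the remaining edges are
    ranked descending and the top ``ceil(fraction * E)`` kept, together
    with any edge tying the boundary score (relative tolerance 1e-9).
    Isolated nodes are dropped from the result.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    edges = net.edges.copy()
    edges["direct_score"] = result.score_frame(net).to_numpy()
    if drop_nonpositive:
        edges = edges.loc[edges["direct_score"] > 0]
    if len(edges) == 0:
        raise ValueError("no edge left after deconvolution ranking")

    scores = np.sort(edges["direct_score"].to_numpy())[::-1]
    n_keep = math.ceil(fraction * len(scores))
    boundary = scores[n_keep - 1]
    tol = _TIE_RTOL * max(abs(boundary), 1.0)
    kept = edges.loc[edges["direct_score"] >= boundary - tol]
    return CeRNANetwork(kept)
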
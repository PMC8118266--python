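"""ceRNA pair inference.

Candidate gene pairs are screened in three steps before becoming network
edges:

1. *common regulators*: the two genes must share significantly more miRNA
   regulators than expected by chance (hypergeometric upper tail);
2. *partial correlation*: their expression must correlate positively and
   significantly after removing each gene's own copy-number effect
   (ceRNAs up-regulate each other, but copy-number co-amplification can
   fake that signal);
3. *collective regulation* (CR): the summed expression of the pair must be
   anticorrelated with its summed effective regulation, i.e. the pair is
   jointly under miRNA pressure.

Steps 2 and 3 are additionally required to hold across bootstrap
resamples. Surviving pairs form a weighted network whose edge weights are
the min-max-normalised partial correlations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CNAMatrix, ExpressionMatrix, InteractionTable
from .network import CeRNANetwork
from .regulation import ConsensusConfig, RegulationVectors, bootstrap_counts

logger = logging.getLogger(__name__)

__all__ = [
    "PairThresholds",
    "common_regulator_pvalue",
    "candidate_pair_screen",
    "partial_correlation_excluding_cna",
    "collective_regulation",
    "pair_filter",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PairThresholds:
    """Thresholds of the pairwise screen (reference defaults)."""

    partial_corr_min: float = 0.55
    partial_p_max: float = 0.01
    cr_max: float = -0.01


# ---------------------------------------------------------------------------
# common-regulator screen
# ---------------------------------------------------------------------------

def common_regulator_pvalue(
    regulators_a: set, regulators_b: set, universe: set
) -> tuple[int, float]:
    """Upper-tail hypergeometric probability of the regulator overlap.

    With population size |universe|, |A| successes and |B| draws, returns
    (overlap, P(X >= overlap)).
    """
    if not universe:
        raise ValueError("empty miRNA universe")
    if not (set(regulators_a) <= set(universe) and set(regulators_b) <= set(universe)):
        raise ValueError("regulator sets must be subsets of the universe")
    overlap = len(set(regulators_a) & set(regulators_b))
    p = float(stats.hypergeom.sf(overlap - 1, len(universe),
                                 len(regulators_a), len(regulators_b)))
    return overlap, min(p, 1.0)


def candidate_pair_screen(
    candidates: set, table: InteractionTable, alpha: float = 0.01
) -> pd.DataFrame:
    """All unordered candidate pairs sharing significantly many regulators.

    Returns a frame (gene_a, gene_b, n_common, hypergeom_p) with
    hypergeom_p < ``alpha``; the regulator universe is the miRNA set of the
    current interaction table.
    """
    reg_sets = table.regulator_sets()
    genes = sorted(g for g in candidates if g in reg_sets)
    missing = sorted(set(candidates) - set(genes))
    if missing:
        raise ValueError(f"candidate gene(s) without regulators: {missing[:5]}")
    universe = table.regulators
    n_universe = len(universe)
    if n_universe == 0:
        raise ValueError("empty miRNA universe")

    mir_pos = {m: i for i, m in enumerate(universe)}
    Z = np.zeros((len(genes), n_universe), dtype=np.int32)
    for i, g in enumerate(genes):
        Z[i, [mir_pos[m] for m in reg_sets[g]]] = 1
    sizes = Z.sum(axis=1)
    overlap = Z @ Z.T

    ia, ib = np.triu_indices(len(genes), k=1)
    ov = overlap[ia, ib]
    p = stats.hypergeom.sf(ov - 1, n_universe, sizes[ia], sizes[ib])
    p = np.minimum(p, 1.0)
    keep = p < alpha
    out = pd.DataFrame(
        {
            "gene_a": np.asarray(genes)[ia[keep]],
            "gene_b": np.asarray(genes)[ib[keep]],
            "n_common": ov[keep],
            "hypergeom_p": p[keep],
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CNA-adjusted partial correlation
# ---------------------------------------------------------------------------

def _residualize(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """OLS residual of x on c with intercept; constant c removes the mean only."""
    xc = x - x.mean()
    cc = c - c.mean()
    var = (cc * cc).sum()
    if var < _EPS:
        return xc
    return xc - ((xc * cc).sum() / var) * cc


def partial_correlation_excluding_cna(
    expr_a: np.ndarray,
    expr_b: np.ndarray,
    cna_a: np.ndarray,
    cna_b: np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation of CNA-adjusted expression residuals.

    Each expression vector is replaced by its OLS residual on the same
    gene's CNA vector (intercept included); the statistic is the Pearson
    correlation of the two residual vectors. Significance uses
    t = rho sqrt((n-4)/(1-rho^2)) on n-4 degrees of freedom (two fitted
    covariates). Returns (rho, p); rho is NaN when either residual vector
    is (numerically) constant.
    """
    expr_a, expr_b = np.asarray(expr_a, float), np.asarray(expr_b, float)
    cna_a, cna_b = np.asarray(cna_a, float), np.asarray(cna_b, float)
    n = len(expr_a)
    if not (len(expr_b) == len(cna_a) == len(cna_b) == n):
        raise ValueError("all four vectors must share one length")
    if n < 5:
        raise ValueError("need at least 5 samples for a CNA-adjusted correlation")
    ra, rb = _residualize(expr_a, cna_a), _residualize(expr_b, cna_b)
    va, vb = (ra * ra).sum(), (rb * rb).sum()
    if va < _EPS or vb < _EPS:
        return float("nan"), float("nan")
    rho = float((ra * rb).sum() / np.sqrt(va * vb))
    rho = max(-1.0, min(1.0, rho))
    df = n - 4
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def collective_regulation(
    gene_set, genes: ExpressionMatrix, reg: RegulationVectors
) -> float:
    """CR(S): Pearson correlation of per-sample summed ER and summed
    expression over the gene set; NaN when either sum is constant."""
    gene_set = list(gene_set)
    if len(gene_set) < 2:
        raise ValueError("collective regulation needs a set of >= 2 genes")
    if reg.er is None:
        raise ValueError("ER vectors not computed")
    e = genes.data.loc[gene_set].to_numpy().sum(axis=0)
    r = reg.er.loc[gene_set].to_numpy().sum(axis=0)
    e = e - e.mean()
    r = r - r.mean()
    ve, vr = (e * e).sum(), (r * r).sum()
    if ve < _EPS or vr < _EPS:
        return float("nan")
    return float((e * r).sum() / np.sqrt(ve * vr))


# ---------------------------------------------------------------------------
# full pairwise screen
# ---------------------------------------------------------------------------

def _pairwise_stats(
    G: np.ndarray,
    C: np.ndarray,
    E: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised partial correlation and CR for many pairs on one sample set.

    G, C, E are gene expression, CNA and ER matrices over the same gene
    order; ia/ib index the two pair members. Returns (rho, cr) arrays with
    NaN for degenerate vectors.
    """
    Gc = G - G.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    cvar = (Cc * Cc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(cvar > _EPS, (Gc * Cc).sum(axis=1) / cvar, 0.0)
    R = Gc - slope[:, None] * Cc  # CNA-adjusted residuals, one row per gene

    ra, rb = R[ia], R[ib]
    va, vb = (ra * ra).sum(axis=1), (rb * rb).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(
            (va > _EPS) & (vb > _EPS),
            (ra * rb).sum(axis=1) / np.sqrt(va * vb),
            np.nan,
        )

    se = G[ia] + G[ib]
    sr = E[ia] + E[ib]
    se = se - se.mean(axis=1, keepdims=True)
    sr = sr - sr.mean(axis=1, keepdims=True)
    ve, vr = (se * se).sum(axis=1), (sr * sr).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cr = np.where(
            (ve > _EPS) & (vr > _EPS),
            (se * sr).sum(axis=1) / np.sqrt(ve * vr),
            np.nan,
        )
    return np.clip(rho, -1.0, 1.0), np.clip(cr, -1.0, 1.0)


def pair_filter(
    pairs: pd.DataFrame,
    genes: ExpressionMatrix,
    cna: CNAMatrix,
    reg: RegulationVectors,
    thresholds: PairThresholds | None = None,
    consensus: ConsensusConfig | None = None,
    weight_floor: float = 0.01,
    return_stats: bool = False,
):
    """Apply the partial-correlation and CR screens with bootstrap consensus.

    ``pairs`` must come from :func:`candidate_pair_screen`. A pair
    survives when, on the full data, partial_corr > ``partial_corr_min``
    with p < ``partial_p_max`` and CR < ``cr_max``, and when each of the
    two coefficient conditions also holds in >= ``min_pass_frac`` of the
    shared resamples. Survivors become edges whose weights are the
    surviving partial correlations min-max normalised onto
    [``weight_floor``, 1]. With ``return_stats`` the full per-pair
    statistics frame (including failing pairs and per-step pass flags)
    is returned alongside the network.
    """
    thresholds = thresholds or PairThresholds()
    consensus = consensus if consensus is not None else ConsensusConfig(n_resamples=100)
    if len(pairs) == 0:
        raise ValueError("no candidate pairs to filter")

    gene_ids = sorted(set(pairs["gene_a"]) | set(pairs["gene_b"]))
    missing_cna = [g for g in gene_ids if g not in cna.data.index]
    if missing_cna:
        raise ValueError(f"gene(s) without CNA rows: {missing_cna[:5]}")
    pos = {g: i for i, g in enumerate(gene_ids)}
    G = genes.data.loc[gene_ids].to_numpy()
    C = cna.data.loc[gene_ids].to_numpy()
    E = reg.er.loc[gene_ids].to_numpy()
    ia = pairs["gene_a"].map(pos).to_numpy()
    ib = pairs["gene_b"].map(pos).to_numpy()
    n = G.shape[1]

    rho, cr = _pairwise_stats(G, C, E, ia, ib)
    degenerate = np.isnan(rho)
    if degenerate.any():
        logger.info("dropping %d pair(s) with degenerate residuals", degenerate.sum())

    df_t = n - 4
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt(df_t / np.maximum(1.0 - rho * rho, _EPS))
    pval = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(tstat), df_t))

    pass_parcor = (
        ~degenerate
        & (rho > thresholds.partial_corr_min)
        & (pval < thresholds.partial_p_max)
    )
    pass_cr = ~np.isnan(cr) & (cr < thresholds.cr_max)
    keep = pass_parcor & pass_cr

    counts = bootstrap_counts(n, consensus)
    if counts is not None:
        B = counts.shape[1]
        ok_rho = np.zeros((len(pairs), B), dtype=bool)
        ok_cr = np.zeros((len(pairs), B), dtype=bool)
        sample_idx = np.arange(n)
        for b in range(B):
            idx = np.repeat(sample_idx, counts[:, b].astype(int))
            rho_b, cr_b = _pairwise_stats(G[:, idx], C[:, idx], E[:, idx], ia, ib)
            ok_rho[:, b] = ~np.isnan(rho_b) & (rho_b > thresholds.partial_corr_min)
            ok_cr[:, b] = ~np.isnan(cr_b) & (cr_b < thresholds.cr_max)
        frac_rho = ok_rho.mean(axis=1)
        frac_cr = ok_cr.mean(axis=1)
        keep &= (frac_rho >= consensus.min_pass_frac) & (frac_cr >= consensus.min_pass_frac)
        frac = np.minimum(frac_rho, frac_cr)
    else:
        frac = np.where(keep, 1.0, 0.0)

    stats_df = pairs.copy()
    stats_df["partial_corr"] = rho
    stats_df["partial_corr_p"] = pval
    stats_df["cr"] = cr
    stats_df["consensus_frac"] = frac
    stats_df["pass_partial_corr"] = pass_parcor
    stats_df["pass_cr"] = pass_cr
    stats_df["consensus_pass"] = keep

    out = stats_df.loc[keep].drop(
        columns=["pass_partial_corr", "pass_cr", "consensus_pass"]
    ).reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no pair survived the partial-correlation/CR screen")

    w = out["partial_corr"].to_numpy()
    lo, hi = w.min(), w.max()
    if hi - lo < 1e-9:
        out["weight"] = 1.0
    else:
        out["weight"] = weight_floor + (1.0 - weight_floor) * (w - lo) / (hi - lo)
    net = CeRNANetwork(out)
    if return_stats:
        return net, stats_df
    return net


def all_candidate_pairs(candidates) -> list[tuple[str, str]]:
    """Every unordered pair of candidate genes (diagnostic helper)."""
    return list(itertools.combinations(sorted(candidates), 2))
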
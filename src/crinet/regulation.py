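"""miRNA-target regulation statistics and filters.

This stage turns a candidate miRNA-target table into the final interaction
set used for ceRNA inference:

1. *expression anticorrelation*: a miRNA should repress its target, so the
   Pearson correlation between regulator and target expression must fall
   below a negative threshold, robustly across bootstrap resamples;
2. *interaction regulation* (IR): a per-sample statistic measuring whether
   the pair has sufficient mutual expression abundance relative to the
   regulator's other targets and the target's other regulators;
3. *effective regulation* (ER): a per-gene, per-sample summary of the total
   miRNA pressure on that gene; genes whose expression does not respond
   negatively to their ER are excluded from the candidate set.

All bootstrap consensus filters in one stage share a single resampling
stream, so every record is judged against the same resamples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InteractionTable

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusConfig",
    "RegulationVectors",
    "bootstrap_counts",
    "row_correlations",
    "bootstrap_row_correlations",
    "interpolated_percentile",
    "expression_correlation_filter",
    "compute_interaction_regulation",
    "abundance_filter",
    "compute_effective_regulation",
    "filter_genes_by_effective_regulation",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ConsensusConfig:
    """Bootstrap-consensus settings for a filtering stage.

    A record passes consensus when its threshold condition holds in at
    least ``min_pass_frac`` of ``n_resamples`` resamples of the samples
    drawn with replacement. ``n_resamples = 0`` disables consensus
    entirely (the full-data condition alone decides).
    """

    n_resamples: int = 1000
    min_pass_frac: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 0:
            raise ValueError("n_resamples must be >= 0")
        if not 0 < self.min_pass_frac <= 1:
            raise ValueError("min_pass_frac must lie in (0, 1]")


@dataclass
class RegulationVectors:
    """Per-interaction IR vectors and per-gene ER vectors across samples.

    ``ir`` rows align with the interaction-table records (index =
    (regulator, target)); ``er`` rows are genes. Columns are sample ids in
    both frames. Either frame may be absent if not yet computed.
    """

    ir: pd.DataFrame | None = None
    er: pd.DataFrame | None = None
    sample_ids: list[str] = field(default_factory=list)

    def ir_for(self, regulator: str, target: str) -> np.ndarray:
        return self.ir.loc[(regulator, target)].to_numpy()

    def er_for(self, gene: str) -> np.ndarray:
        return self.er.loc[gene].to_numpy()


# ---------------------------------------------------------------------------
# bootstrap helpers
# ---------------------------------------------------------------------------

def bootstrap_counts(n_samples: int, consensus: ConsensusConfig) -> np.ndarray | None:
    """Shared resampling stream: one multiplicity matrix for a whole stage.

    Drawing ``n_samples`` indices with replacement is equivalent to a
    multinomial count vector over samples; returns an (n_samples,
    n_resamples) integer matrix, or None when consensus is disabled.
    """
    if consensus.n_resamples == 0:
        return None
    rng = np.random.default_rng(consensus.seed)
    counts = rng.multinomial(
        n_samples, np.full(n_samples, 1.0 / n_samples), size=consensus.n_resamples
    )
    return counts.T.astype(float)


def row_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation between corresponding rows of X and Y (k x n).

    Rows with zero variance yield NaN.
    """
    X = X - X.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    num = (X * Y).sum(axis=1)
    den = np.sqrt((X * X).sum(axis=1) * (Y * Y).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > _EPS, num / den, np.nan)
    return out


def bootstrap_row_correlations(
    X: np.ndarray, Y: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Correlation of each row pair under every resample: (k, B) matrix.

    ``counts`` is the (n, B) multiplicity matrix from
    :func:`bootstrap_counts`. Resamples where either vector is constant
    give NaN (treated as a consensus failure downstream).
    """
    n = X.shape[1]
    # center once for numerical stability; correlation is shift-invariant
    X = X - X.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    sx = X @ counts
    sy = Y @ counts
    sxx = (X * X) @ counts
    syy = (Y * Y) @ counts
    sxy = (X * Y) @ counts
    cov = sxy / n - (sx / n) * (sy / n)
    vx = sxx / n - (sx / n) ** 2
    vy = syy / n - (sy / n) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((vx > _EPS) & (vy > _EPS), cov / np.sqrt(vx * vy), np.nan)
    return out


def consensus_pass_fraction(corr_resamples: np.ndarray, condition) -> np.ndarray:
    """Fraction of resamples in which ``condition`` holds; NaN counts as fail."""
    ok = condition(corr_resamples)
    ok = np.where(np.isnan(corr_resamples), False, ok)
    return ok.mean(axis=1)


def interpolated_percentile(values: np.ndarray, p: float) -> float:
    """Percentile with linear interpolation between order statistics
    (rank h = (n-1)p + 1), tolerant of -inf entries."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty vector")
    h = (n - 1) * p
    lo = int(math.floor(h))
    hi = int(math.ceil(h))
    if lo == hi or v[lo] == v[hi]:
        return float(v[lo])
    if not np.isfinite(v[lo]):
        return float(v[lo])
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def _record_matrices(
    table: InteractionTable,
    mirnas: ExpressionMatrix,
    genes: ExpressionMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-record regulator/target expression row indices and value blocks."""
    mir_pos = {m: i for i, m in enumerate(mirnas.entity_ids)}
    gene_pos = {g: i for i, g in enumerate(genes.entity_ids)}
    regs = table.data["regulator"].to_numpy()
    tgts = table.data["target"].to_numpy()
    missing_r = [r for r in np.unique(regs) if r not in mir_pos]
    missing_t = [t for t in np.unique(tgts) if t not in gene_pos]
    if missing_r or missing_t:
        raise ValueError(
            f"interaction entities without expression rows: "
            f"{(missing_r + missing_t)[:5]}"
        )
    reg_idx = np.array([mir_pos[r] for r in regs])
    tgt_idx = np.array([gene_pos[t] for t in tgts])
    return reg_idx, tgt_idx, mirnas.values, genes.values


# ---------------------------------------------------------------------------
# stage 1: expression anticorrelation
# ---------------------------------------------------------------------------

def expression_correlation_filter(
    table: InteractionTable,
    mirnas: ExpressionMatrix,
    genes: ExpressionMatrix,
    threshold: float = -0.1,
    consensus: ConsensusConfig | None = None,
) -> InteractionTable:
    """Keep miRNA-target records with robustly negative expression correlation.

    A record survives when corr(Exp(r), Exp(t)) < ``threshold`` on the full
    data and, if consensus is enabled, in at least ``min_pass_frac`` of the
    shared bootstrap resamples. Records with a constant expression vector
    are dropped (correlation undefined). The returned table carries
    ``corr`` and ``consensus_frac`` diagnostic columns.
    """
    consensus = consensus or ConsensusConfig()
    reg_idx, tgt_idx, M, G = _record_matrices(table, mirnas, genes)
    X, Y = M[reg_idx], G[tgt_idx]

    corr = row_correlations(X, Y)
    constant = np.isnan(corr)
    if constant.any():
        for i in np.flatnonzero(constant)[:10]:
            logger.info(
                "dropping %s->%s: constant expression vector",
                table.data["regulator"].iat[i], table.data["target"].iat[i],
            )
    keep = ~constant & (corr < threshold)

    counts = bootstrap_counts(X.shape[1], consensus)
    if counts is not None:
        frac = consensus_pass_fraction(
            bootstrap_row_correlations(X, Y, counts), lambda c: c < threshold
        )
        keep &= frac >= consensus.min_pass_frac
    else:
        frac = np.where(keep, 1.0, 0.0)

    df = table.data.copy()
    df["corr"] = corr
    df["consensus_frac"] = frac
    return InteractionTable(df.loc[keep])


# ---------------------------------------------------------------------------
# stage 2: interaction regulation (abundance)
# ---------------------------------------------------------------------------

def compute_interaction_regulation(
    table: InteractionTable,
    mirnas: ExpressionMatrix,
    genes: ExpressionMatrix,
) -> RegulationVectors:
    """Per-sample IR for every record of the current table.

    For regulator r and target t at one sample,

        IR(r,t) = [Exp(r) Exp(t) s_rt / sum_{j in targets(r)} Exp(j) s_rj]
                * [Exp(t) Exp(r) s_rt / sum_{j in regulators(t)} Exp(j) s_jt]

    with both denominator sums taken over the current table only. A zero
    denominator (all of a regulator's targets silent in that sample) makes
    IR 0 for that sample.
    """
    if not table.has_weights:
        raise ValueError("norm_weight must be set and positive on every record")
    reg_idx, tgt_idx, M, G = _record_matrices(table, mirnas, genes)
    w = table.data["norm_weight"].to_numpy(dtype=float)

    num = M[reg_idx] * G[tgt_idx] * w[:, None]  # Exp(r) Exp(t) s_rt per sample

    d1 = np.zeros_like(M)  # per regulator: sum_j Exp(j) s_rj over its targets
    np.add.at(d1, reg_idx, G[tgt_idx] * w[:, None])
    d2 = np.zeros_like(G)  # per target: sum_j Exp(j) s_jt over its regulators
    np.add.at(d2, tgt_idx, M[reg_idx] * w[:, None])

    den1, den2 = d1[reg_idx], d2[tgt_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        ir = np.where(den1 > 0, num / den1, 0.0) * np.where(den2 > 0, num / den2, 0.0)
    n_zero = int(((den1 <= 0) | (den2 <= 0)).sum())
    if n_zero:
        logger.info("IR: %d record-sample cells had a zero denominator -> IR=0", n_zero)

    index = pd.MultiIndex.from_arrays(
        [table.data["regulator"], table.data["target"]], names=["regulator", "target"]
    )
    return RegulationVectors(
        ir=pd.DataFrame(ir, index=index, columns=genes.sample_ids),
        sample_ids=genes.sample_ids,
    )


def abundance_filter(
    table: InteractionTable,
    reg: RegulationVectors,
    log_ir_threshold: float | str = -4.89,
    percentile: float = 0.80,
) -> InteractionTable:
    """Keep records whose log-IR profile shows sufficient abundance.

    The natural log of each record's IR vector (zeros map to -inf) must
    have its ``percentile`` quantile (linear interpolation) strictly above
    ``log_ir_threshold``. The default threshold is the reference
    data-derived cut; pass ``"auto"`` to recompute it as the third
    quartile of all log-IR values in the current dataset.
    """
    if reg.ir is None:
        raise ValueError("IR vectors not computed")
    ir = reg.ir.to_numpy()
    with np.errstate(divide="ignore"):
        log_ir = np.log(ir)

    if log_ir_threshold == "auto":
        finite = log_ir[np.isfinite(log_ir)]
        log_ir_threshold = float(np.percentile(finite, 75))
        logger.info("abundance threshold (auto, Q3 of log IR): %.4f", log_ir_threshold)

    p80 = np.array([interpolated_percentile(row, percentile) for row in log_ir])
    df = table.data.copy()
    df["log_ir_p"] = p80
    return InteractionTable(df.loc[p80 > log_ir_threshold])


# ---------------------------------------------------------------------------
# stage 3: effective regulation
# ---------------------------------------------------------------------------

def compute_effective_regulation(
    table: InteractionTable,
    mirnas: ExpressionMatrix,
    genes: ExpressionMatrix | None = None,
) -> RegulationVectors:
    """Per-sample ER for every gene:

        ER(t) = sum_{r in regulators(t)} Exp(r) s_rt / sum_{j in targets(r)} s_rj

    The inner score sum runs over the current table, so a promiscuous
    regulator spreads its expression across its targets. Genes without
    regulators (when ``genes`` is given) get ER identically 0.
    """
    if not table.has_weights:
        raise ValueError("norm_weight must be set and positive on every record")
    gene_universe = genes if genes is not None else None
    mir_pos = {m: i for i, m in enumerate(mirnas.entity_ids)}
    regs = table.data["regulator"].to_numpy()
    tgts = table.data["target"].to_numpy()
    missing = [r for r in np.unique(regs) if r not in mir_pos]
    if missing:
        raise ValueError(f"regulator(s) without expression rows: {missing[:5]}")
    w = table.data["norm_weight"].to_numpy(dtype=float)

    # per-regulator score sums (sample independent)
    score_sum = pd.Series(w).groupby(pd.Series(regs)).sum()
    share = w / score_sum.loc[regs].to_numpy()

    if gene_universe is not None:
        out_genes = gene_universe.entity_ids
    else:
        out_genes = sorted(set(tgts))
    gene_pos = {g: i for i, g in enumerate(out_genes)}
    tgt_idx = np.array([gene_pos[t] for t in tgts])

    M = mirnas.values
    reg_idx = np.array([mir_pos[r] for r in regs])
    er = np.zeros((len(out_genes), M.shape[1]))
    np.add.at(er, tgt_idx, M[reg_idx] * share[:, None])

    return RegulationVectors(
        er=pd.DataFrame(er, index=out_genes, columns=mirnas.sample_ids),
        sample_ids=mirnas.sample_ids,
    )


def filter_genes_by_effective_regulation(
    genes: ExpressionMatrix,
    reg: RegulationVectors,
    threshold: float = -0.01,
    consensus: ConsensusConfig | None = None,
    return_stats: bool = False,
):
    """Candidate genes: expression anticorrelated with effective regulation.

    A gene is a candidate when corr(Exp(t), ER(t)) < ``threshold`` on the
    full data and in >= ``min_pass_frac`` of the shared resamples. Genes
    with constant ER (including regulator-less genes) or constant
    expression are excluded. Returns the candidate id set (plus a
    per-gene diagnostic frame when ``return_stats``).
    """
    if reg.er is None:
        raise ValueError("ER vectors not computed")
    consensus = consensus or ConsensusConfig()
    shared = [g for g in genes.entity_ids if g in reg.er.index]
    X = genes.data.loc[shared].to_numpy()
    Y = reg.er.loc[shared].to_numpy()

    corr = row_correlations(X, Y)
    keep = ~np.isnan(corr) & (corr < threshold)

    counts = bootstrap_counts(X.shape[1], consensus)
    if counts is not None:
        frac = consensus_pass_fraction(
            bootstrap_row_correlations(X, Y, counts), lambda c: c < threshold
        )
        keep &= frac >= consensus.min_pass_frac
    else:
        frac = np.where(keep, 1.0, 0.0)

    candidates = {g for g, k in zip(shared, keep) if k}
    if not candidates:
        raise ValueError(
            "no gene passed the effective-regulation filter; relax the threshold"
        )
    if return_stats:
        stats = pd.DataFrame(
            {"gene": shared, "corr": corr, "consensus_frac": frac, "candidate": keep}
        )
        return candidates, stats
    return candidates
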
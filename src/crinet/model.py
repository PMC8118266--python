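"""The `Crinet` model object: full ceRNA network inference from data.

Usage follows the model/results convention of statistical modelling
packages: construct the model from the four inputs, call :meth:`fit`, and
read estimates and diagnostics off the returned :class:`CrinetResults`::

    model = Crinet(genes, mirnas, cna, interactions)
    res = model.fit()
    print(res.summary())
    res.save("out/")

``fit`` executes the whole cascade: input preparation, miRNA-target
filtering (anticorrelation, interaction-regulation abundance, effective
regulation), pairwise ceRNA screening (common regulators, CNA-adjusted
partial correlation, collective regulation, bootstrap consensus),
network deconvolution with top-fraction retention, and group inference.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconvolution as deconv
from . import groups as groups_mod
from . import pairs as pairs_mod
from . import preprocess
from . import regulation
from .containers import CNAMatrix, ExpressionMatrix, InteractionTable, read_expression_matrix
from .network import CeRNANetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "Crinet",
    "CrinetResults",
    "run_pipeline",
    "degree_distribution_fit",
    "list_overlap_test",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the inference cascade, with reference defaults.

    The defaults are the thresholds of the reference breast-cancer
    analysis; the data-derived ones (``log_ir_threshold``,
    ``partial_corr_min``) can be recomputed from the current dataset by
    passing ``"auto"`` / enabling ``auto_partial_corr_min``.
    """

    # data preparation
    gene_expr_threshold: float = 1.0
    mirna_zero_value: float = 0.0
    low_expr_frac: float = 0.15
    top_fraction: float = 0.40
    weight_floor: float = 0.01
    # miRNA-target stage
    mirna_corr_threshold: float = -0.1
    log_ir_threshold: float | str = -4.89
    ir_percentile: float = 0.80
    er_corr_threshold: float = -0.01
    target_consensus_resamples: int = 1000
    # pair stage
    hypergeom_alpha: float = 0.01
    partial_corr_min: float = 0.55
    auto_partial_corr_min: bool = False
    partial_p_max: float = 0.01
    cr_max: float = -0.01
    pair_consensus_resamples: int = 100
    consensus_min_pass_frac: float = 0.99
    # deconvolution
    deconvolution_fraction: float = 1.0 / 3.0
    max_direct_eig: float = 0.9
    drop_nonpositive: bool = True
    # groups
    walk_length: int = 4
    member_frac: float = 0.90
    neighbor_frac: float = 0.90
    group_max_iter: int = 10000
    # randomness: one master seed derives independent per-stage streams
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(2)
        return {
            "target_consensus": int(children[0].generate_state(1)[0] % 2**31),
            "pair_consensus": int(children[1].generate_state(1)[0] % 2**31),
        }

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class CrinetResults:
    """Estimates and diagnostics of a fitted :class:`Crinet` model."""

    config: PipelineConfig
    network: CeRNANetwork
    grouped_network: "groups_mod.GroupedNetwork"
    groups: list
    pre_deconvolution_network: CeRNANetwork | None = None
    interactions: InteractionTable | None = None
    candidate_genes: set = field(default_factory=set)
    regulation: regulation.RegulationVectors | None = None
    pair_stats: pd.DataFrame | None = None
    stage_report: pd.DataFrame | None = None

    def degree_fit(self, grouped: bool = False) -> dict:
        net = self.grouped_network if grouped else self.network
        return degree_distribution_fit(net)

    def summary(self) -> str:
        lines = [
            "ceRNA network inference results",
            "=" * 46,
            f"{'final network nodes':<34}{self.network.n_nodes:>12}",
            f"{'final network edges':<34}{self.network.n_edges:>12}",
            f"{'ceRNA groups':<34}{len(self.groups):>12}",
            f"{'grouped-network nodes':<34}{self.grouped_network.n_nodes:>12}",
            f"{'grouped-network edges':<34}{self.grouped_network.n_edges:>12}",
            f"{'community-detection iterations':<34}"
            f"{self.grouped_network.walktrap_iterations:>12}",
            "-" * 46,
        ]
        if self.stage_report is not None:
            lines.append("stage report (entities surviving each step):")
            for _, row in self.stage_report.iterrows():
                lines.append(f"  {row['stage']:<30}{row['count']:>12}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write every output as TSV/YAML (byte-deterministic for a fixed
        config and seed)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        self.network.to_tsv(out / "network_edges.tsv")
        if self.pre_deconvolution_network is not None:
            self.pre_deconvolution_network.to_tsv(out / "pre_deconvolution_edges.tsv")
        self.grouped_network.edges_to_tsv(out / "grouped_network_edges.tsv")
        self.grouped_network.groups_to_tsv(out / "groups.tsv")
        if self.interactions is not None:
            self.interactions.to_tsv(out / "interactions_final.tsv")
        if self.pair_stats is not None:
            self.pair_stats.to_csv(out / "pair_stats.tsv", sep="\t", index=False)
        if self.stage_report is not None:
            self.stage_report.to_csv(out / "stage_report.tsv", sep="\t", index=False)
        (out / "candidate_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(self.candidate_genes))
        )


class Crinet:
    """ceRNA network model over expression, CNA and binding-score data.

    Parameters
    ----------
    genes, mirnas
        Gene (FPKM-like) and miRNA (RPM-like) expression matrices.
    cna
        Gene-centric copy-number matrix sharing the gene universe.
    interactions
        Candidate miRNA-target interactions with raw binding scores.
    config
        :class:`PipelineConfig`; defaults to the reference thresholds.
    """

    def __init__(
        self,
        genes: ExpressionMatrix,
        mirnas: ExpressionMatrix,
        cna: CNAMatrix,
        interactions: InteractionTable,
        config: PipelineConfig | None = None,
    ):
        self.config = config or PipelineConfig()
        self.genes, self.mirnas, self.cna = preprocess.align_samples(genes, mirnas, cna)
        self.interactions = interactions

    @classmethod
    def from_files(
        cls,
        gene_path: str | Path,
        mirna_path: str | Path,
        cna_path: str | Path,
        interaction_path: str | Path,
        config: PipelineConfig | None = None,
    ) -> "Crinet":
        return cls(
            read_expression_matrix(gene_path, "gene"),
            read_expression_matrix(mirna_path, "miRNA"),
            read_expression_matrix(cna_path, "cna"),
            InteractionTable.from_tsv(interaction_path),
            config,
        )

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None) -> CrinetResults:
        """Run the full inference cascade and return the results object."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        seeds = cfg.stage_seeds()
        report: list[dict] = []

        def log_stage(stage: str, count: int, **extra):
            report.append({"stage": stage, "count": count, **extra})
            logger.info("stage %-28s -> %d", stage, count)

        # ---- data preparation ----------------------------------------
        genes, mirnas = preprocess.filter_low_expression(
            self.genes, self.mirnas,
            gene_thresh=cfg.gene_expr_threshold,
            mirna_zero=cfg.mirna_zero_value,
            frac=cfg.low_expr_frac,
        )
        table = self.interactions
        log_stage("interactions/all", len(table),
                  n_mirnas=table.data["regulator"].nunique(),
                  n_genes=table.data["target"].nunique())

        table = preprocess.select_top_interactions(table, cfg.top_fraction)
        table = preprocess.normalize_binding_scores(
            table, weight_floor=cfg.weight_floor)
        table = table.restrict(regulators=mirnas.entity_ids,
                               targets=genes.entity_ids)
        if len(table) == 0:
            raise ValueError("stage interactions/top_fraction emptied the table "
                             f"(top_fraction={cfg.top_fraction})")
        log_stage("interactions/top_fraction", len(table),
                  n_mirnas=table.data["regulator"].nunique(),
                  n_genes=table.data["target"].nunique())

        # ---- miRNA-target filtering ----------------------------------
        target_consensus = regulation.ConsensusConfig(
            n_resamples=cfg.target_consensus_resamples,
            min_pass_frac=cfg.consensus_min_pass_frac,
            seed=seeds["target_consensus"],
        )
        table = regulation.expression_correlation_filter(
            table, mirnas, genes,
            threshold=cfg.mirna_corr_threshold, consensus=target_consensus)
        if len(table) == 0:
            raise ValueError("stage interactions/correlation emptied the table "
                             f"(threshold={cfg.mirna_corr_threshold})")
        log_stage("interactions/correlation", len(table),
                  n_mirnas=table.data["regulator"].nunique(),
                  n_genes=table.data["target"].nunique())

        reg = regulation.compute_interaction_regulation(table, mirnas, genes)
        table = regulation.abundance_filter(
            table, reg, log_ir_threshold=cfg.log_ir_threshold,
            percentile=cfg.ir_percentile)
        if len(table) == 0:
            raise ValueError("stage interactions/abundance emptied the table "
                             f"(log_ir_threshold={cfg.log_ir_threshold})")
        log_stage("interactions/abundance", len(table),
                  n_mirnas=table.data["regulator"].nunique(),
                  n_genes=table.data["target"].nunique())

        reg = regulation.compute_effective_regulation(table, mirnas, genes)
        candidates = regulation.filter_genes_by_effective_regulation(
            genes, reg, threshold=cfg.er_corr_threshold,
            consensus=target_consensus)
        log_stage("genes/candidates", len(candidates))

        # ---- pair inference ------------------------------------------
        pairs = pairs_mod.candidate_pair_screen(
            candidates, table, alpha=cfg.hypergeom_alpha)
        if len(pairs) == 0:
            raise ValueError("stage pairs/common_regulators emptied the pair set "
                             f"(alpha={cfg.hypergeom_alpha})")
        log_stage("pairs/common_regulators", len(pairs))

        partial_corr_min = cfg.partial_corr_min
        if cfg.auto_partial_corr_min:
            rho, _ = pairs_mod._pairwise_stats(
                *self._pair_arrays(pairs, genes, reg))
            pos = rho[~np.isnan(rho) & (rho > 0)]
            if len(pos):
                partial_corr_min = float(np.percentile(pos, 75))
                logger.info("partial_corr_min (auto, Q3 of positive partial "
                            "correlations): %.4f", partial_corr_min)

        pair_consensus = regulation.ConsensusConfig(
            n_resamples=cfg.pair_consensus_resamples,
            min_pass_frac=cfg.consensus_min_pass_frac,
            seed=seeds["pair_consensus"],
        )
        thresholds = pairs_mod.PairThresholds(
            partial_corr_min=partial_corr_min,
            partial_p_max=cfg.partial_p_max,
            cr_max=cfg.cr_max,
        )
        pre_net, pair_stats = pairs_mod.pair_filter(
            pairs, genes, self.cna, reg,
            thresholds=thresholds, consensus=pair_consensus,
            weight_floor=cfg.weight_floor, return_stats=True)
        log_stage("pairs/partial_correlation",
                  int(pair_stats["pass_partial_corr"].sum()))
        log_stage("pairs/collective_regulation",
                  int((pair_stats["pass_partial_corr"]
                       & pair_stats["pass_cr"]).sum()))
        log_stage("pairs/consensus", pre_net.n_edges)

        # ---- deconvolution -------------------------------------------
        dec = deconv.deconvolve_network(pre_net, max_direct_eig=cfg.max_direct_eig)
        net = deconv.rank_and_retain_edges(
            dec, pre_net, fraction=cfg.deconvolution_fraction,
            drop_nonpositive=cfg.drop_nonpositive)
        log_stage("pairs/deconvolution", net.n_edges)

        # ---- groups ---------------------------------------------------
        valid_groups, iterations = groups_mod.refine_groups(
            net, genes, reg, table,
            walk_length=cfg.walk_length,
            member_frac=cfg.member_frac,
            neighbor_frac=cfg.neighbor_frac,
            neighbor_corr_threshold=partial_corr_min,
            cr_max=cfg.cr_max,
            max_iter=cfg.group_max_iter,
        )
        grouped = groups_mod.integrate_groups(net, valid_groups, iterations)
        log_stage("groups/valid", len(valid_groups))
        log_stage("grouped_network/nodes", grouped.n_nodes)
        log_stage("grouped_network/edges", grouped.n_edges)

        return CrinetResults(
            config=cfg,
            network=net,
            grouped_network=grouped,
            groups=valid_groups,
            pre_deconvolution_network=pre_net,
            interactions=table,
            candidate_genes=candidates,
            regulation=reg,
            pair_stats=pair_stats,
            stage_report=pd.DataFrame(report),
        )

    @staticmethod
    def _pair_arrays(pairs: pd.DataFrame, genes: ExpressionMatrix, reg):
        gene_ids = sorted(set(pairs["gene_a"]) | set(pairs["gene_b"]))
        pos = {g: i for i, g in enumerate(gene_ids)}
        G = genes.data.loc[gene_ids].to_numpy()
        E = reg.er.loc[gene_ids].to_numpy()
        C = np.zeros_like(G)
        ia = pairs["gene_a"].map(pos).to_numpy()
        ib = pairs["gene_b"].map(pos).to_numpy()
        return G, C, E, ia, ib


# ---------------------------------------------------------------------------
# orchestration from a config file
# ---------------------------------------------------------------------------

def _input_digest(paths: list[Path], cfg: PipelineConfig) -> str:
    h = hashlib.sha256(cfg.digest().encode())
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    gene_path: str | Path,
    mirna_path: str | Path,
    cna_path: str | Path,
    interaction_path: str | Path,
    outdir: str | Path,
    use_cache: bool = True,
) -> CrinetResults:
    """Fit the model from files and write all outputs under ``outdir``.

    A digest of the inputs and config is stored in a manifest; when it
    matches an existing manifest and ``use_cache`` is set, the completed
    run is not repeated (the written outputs are authoritative).
    """
    outdir = Path(outdir)
    paths = [Path(p) for p in (gene_path, mirna_path, cna_path, interaction_path)]
    digest = _input_digest(paths, config)
    manifest = outdir / "manifest.json"
    if use_cache and manifest.exists():
        try:
            if json.loads(manifest.read_text()).get("digest") == digest:
                logger.info("outputs in %s are up to date (digest %s)", outdir, digest)
                return load_results(outdir)
        except (json.JSONDecodeError, OSError, ValueError):
            pass
    model = Crinet.from_files(*paths, config=config)
    results = model.fit()
    results.save(outdir)
    manifest.write_text(json.dumps({"digest": digest}, indent=0) + "\n")
    return results


def load_results(outdir: str | Path) -> CrinetResults:
    """Reload a completed run's outputs from ``outdir``.

    Only what was serialised comes back (no in-memory regulation
    vectors); sufficient for summaries, recovery scoring and plotting.
    """
    out = Path(outdir)
    config = PipelineConfig.from_yaml(out / "config.yaml")
    net = CeRNANetwork.from_tsv(out / "network_edges.tsv")
    pre = out / "pre_deconvolution_edges.tsv"
    pre_net = CeRNANetwork.from_tsv(pre) if pre.exists() else None

    gdf = pd.read_csv(out / "groups.tsv", sep="\t")
    loaded_groups = [
        groups_mod.CeRNAGroup(
            members=frozenset(str(row["members"]).split(",")),
            common_regulators=frozenset(str(row["common_regulators"]).split(","))
            if pd.notna(row["common_regulators"]) else frozenset(),
            group_cr=float(row["group_cr"]),
            common_regulator_ok=True, regulation_ok=True, compatibility_ok=True,
            group_id=str(row["group_id"]),
        )
        for _, row in gdf.iterrows()
    ]
    grouped_edges = pd.read_csv(out / "grouped_network_edges.tsv", sep="\t")
    member_genes = set().union(*(g.members for g in loaded_groups)) if loaded_groups else set()
    grouped = groups_mod.GroupedNetwork(
        individual_nodes=sorted(set(net.nodes) - member_genes),
        groups=loaded_groups,
        edges=grouped_edges,
    )
    report_path = out / "stage_report.tsv"
    stage_report = pd.read_csv(report_path, sep="\t") if report_path.exists() else None
    candidates_path = out / "candidate_genes.txt"
    candidates = (
        set(candidates_path.read_text().split()) if candidates_path.exists() else set()
    )
    pair_stats_path = out / "pair_stats.tsv"
    pair_stats = (
        pd.read_csv(pair_stats_path, sep="\t") if pair_stats_path.exists() else None
    )
    interactions_path = out / "interactions_final.tsv"
    interactions = (
        InteractionTable.from_tsv(interactions_path)
        if interactions_path.exists() else None
    )
    return CrinetResults(
        config=config,
        network=net,
        grouped_network=grouped,
        groups=loaded_groups,
        pre_deconvolution_network=pre_net,
        interactions=interactions,
        candidate_genes=candidates,
        pair_stats=pair_stats,
        stage_report=stage_report,
    )


# ---------------------------------------------------------------------------
# post-hoc network summaries
# ---------------------------------------------------------------------------

def degree_distribution_fit(net) -> dict:
    """Power-law check: OLS of log10 P(k) on log10 k over observed degrees.

    Accepts a pairwise or grouped network; degrees of zero are excluded
    (log undefined) and at least 3 distinct positive degrees are
    required. Returns the slope and R^2 of the fit; scale-free networks
    show a negative slope with high R^2.
    """
    degrees = net.degrees().to_numpy()
    degrees = degrees[degrees > 0]
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError("need at least 3 distinct degrees for a power-law fit")
    pk = counts / counts.sum()
    x, y = np.log10(ks), np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "r_squared": float(r2)}


def list_overlap_test(set_a, set_b, universe) -> float:
    """Hypergeometric upper-tail p for the overlap of two gene lists.

    Same kernel as the common-regulator screen, reused for enrichment
    audits of inferred gene sets against reference lists.
    """
    _, p = pairs_mod.common_regulator_pvalue(set(set_a), set(set_b), set(universe))
    return p
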
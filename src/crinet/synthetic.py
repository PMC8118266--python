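"""Synthetic miRNA/gene expression data with planted ceRNA structure.

The generator emulates the four pipeline inputs (gene expression, miRNA
expression, gene-centric CNA, miRNA-target binding scores) on a scale
where the full pipeline runs in seconds, with known ground truth:

* miRNA expression is i.i.d. log-normal (RPM-like);
* each *planted pair* (or group) of genes shares one small set of
  strongly binding miRNAs; both members carry identical binding weights,
  so in the noiseless limit their expression vectors are exactly affinely
  related;
* each *decoy pair* has the same shared-regulator construction but with
  weaker binding, emulating the weaker, partially indirect co-regulation
  that the deconvolution + top-fraction step is meant to down-rank;
* *background genes* receive many weak random regulators, providing the
  bulk of the interaction table (so the planted interactions sit inside
  the strongest-scoring fraction rather than being the whole table);
* gene expression = baseline - repression * sum(weight x regulator
  expression) + CNA + Gaussian noise, truncated at zero; the CNA matrix
  is ``cna_effect`` x standard normal per gene, so ``cna_effect = 0``
  yields a constant (zero) CNA matrix.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CNAMatrix, ExpressionMatrix, InteractionTable
from .network import CeRNANetwork

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "score_recovery"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults are the package's reference conditions."""

    n_genes: int = 200
    n_mirnas: int = 30
    n_samples: int = 300
    n_planted_pairs: int = 20
    n_decoy_pairs: int = 40
    planted_group_sizes: tuple[int, ...] = ()
    regulators_per_set: int = 4
    max_set_overlap: int = 2
    background_regulators: int = 9
    repression_strength: float = 0.8
    cna_effect: float = 3.0
    noise_sd: float = 3.0
    seed: int = 0
    # expression scales (miRNA RPM-like log-normal; gene FPKM-like baseline)
    mirna_log_mean: float = 3.0
    mirna_log_sd: float = 0.5
    baseline_range: tuple[float, float] = (150.0, 200.0)
    # raw binding-score ranges (weighted-context++ convention: negative,
    # more negative = stronger); planted < decoy < background
    planted_score_range: tuple[float, float] = (-0.62, -0.42)
    decoy_score_range: tuple[float, float] = (-0.40, -0.30)
    background_score_range: tuple[float, float] = (-0.25, -0.02)

    def __post_init__(self):
        if min(self.n_genes, self.n_mirnas, self.n_samples) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.regulators_per_set > self.n_mirnas:
            raise ValueError("more planted regulators per set than miRNAs")
        if self.noise_sd < 0 or self.cna_effect < 0:
            raise ValueError("noise_sd and cna_effect must be >= 0")
        if self.repression_strength <= 0:
            raise ValueError("repression_strength must be positive")
        n_planted_genes = (
            2 * self.n_planted_pairs
            + 2 * self.n_decoy_pairs
            + sum(self.planted_group_sizes)
        )
        if any(s < 2 for s in self.planted_group_sizes):
            raise ValueError("planted groups need >= 2 members")
        if n_planted_genes > self.n_genes:
            raise ValueError(
                f"planted structure needs {n_planted_genes} genes but "
                f"n_genes={self.n_genes}"
            )


@dataclass
class SyntheticDataset:
    genes: ExpressionMatrix
    mirnas: ExpressionMatrix
    cna: CNAMatrix
    table: InteractionTable
    truth: dict = field(default_factory=dict)


def _sample_regulator_sets(
    rng: np.random.Generator, n_sets: int, n_mirnas: int, set_size: int,
    max_overlap: int, max_tries: int = 20000,
) -> list[np.ndarray]:
    """Regulator sets with bounded pairwise overlap (rejection sampling).

    Bounding the overlap keeps distinct planted units from sharing enough
    miRNAs to pass the common-regulator screen against each other.
    """
    sets: list[np.ndarray] = []
    tries = 0
    while len(sets) < n_sets:
        cand = np.sort(rng.choice(n_mirnas, size=set_size, replace=False))
        if all(len(np.intersect1d(cand, s)) <= max_overlap for s in sets):
            sets.append(cand)
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "cannot place planted regulator sets with the requested "
                "overlap bound; reduce planted units or raise n_mirnas"
            )
    return sets


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the four pipeline inputs plus ground truth under ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n_g, n_m, n_s = spec.n_genes, spec.n_mirnas, spec.n_samples

    gene_ids = [f"gene{i:04d}" for i in range(n_g)]
    mirna_ids = [f"mir{i:03d}" for i in range(n_m)]
    sample_ids = [f"sample{i:04d}" for i in range(n_s)]

    M = rng.lognormal(spec.mirna_log_mean, spec.mirna_log_sd, size=(n_m, n_s))

    # --- planted unit layout (pairs, groups, decoys, then background) ----
    units: list[dict] = []
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = gene_ids[cursor:cursor + k]
        cursor += k
        return out

    for _ in range(spec.n_planted_pairs):
        units.append({"kind": "pair", "members": take(2)})
    for size in spec.planted_group_sizes:
        units.append({"kind": "group", "members": take(size)})
    for _ in range(spec.n_decoy_pairs):
        units.append({"kind": "decoy", "members": take(2)})
    background = gene_ids[cursor:]

    reg_sets = _sample_regulator_sets(
        rng, len(units), n_m, spec.regulators_per_set, spec.max_set_overlap
    )
    for unit, regs in zip(units, reg_sets):
        unit["regulators"] = regs

    # --- interaction table with raw binding scores -----------------------
    records: list[tuple[str, str, float]] = []
    # weight matrix used by the expression model (genes x miRNAs)
    W = np.zeros((n_g, n_m))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    for unit in units:
        lo, hi = (
            spec.decoy_score_range if unit["kind"] == "decoy"
            else spec.planted_score_range
        )
        # one score per (unit, miRNA), shared by every member: identical
        # binding makes members exactly affinely related at zero noise
        scores = rng.uniform(lo, hi, size=len(unit["regulators"]))
        for m_idx, s in zip(unit["regulators"], scores):
            for g in unit["members"]:
                records.append((mirna_ids[m_idx], g, float(s)))
                W[gene_pos[g], m_idx] = -s  # binding weight = |raw score|

    lo, hi = spec.background_score_range
    for g in background:
        regs = rng.choice(n_m, size=min(spec.background_regulators, n_m),
                         replace=False)
        scores = rng.uniform(lo, hi, size=len(regs))
        for m_idx, s in zip(regs, scores):
            records.append((mirna_ids[m_idx], g, float(s)))
            W[gene_pos[g], m_idx] = -s

    classes = rng.choice(
        ["mRNA", "lncRNA", "pseudogene"], size=n_g, p=[0.7, 0.2, 0.1]
    )
    class_of = dict(zip(gene_ids, classes))
    table = InteractionTable(pd.DataFrame(
        {
            "regulator": [r for r, _, _ in records],
            "target": [t for _, t, _ in records],
            "raw_score": [s for _, _, s in records],
            "rna_class": [class_of[t] for _, t, _ in records],
        }
    ))

    # --- expression model ------------------------------------------------
    baseline = rng.uniform(*spec.baseline_range, size=n_g)
    cna_raw = rng.standard_normal((n_g, n_s))
    CNA = spec.cna_effect * cna_raw  # cna_effect = 0 -> constant matrix
    noise = (
        rng.standard_normal((n_g, n_s)) * spec.noise_sd
        if spec.noise_sd > 0 else np.zeros((n_g, n_s))
    )
    G = baseline[:, None] - spec.repression_strength * (W @ M) + CNA + noise
    G = np.maximum(G, 0.0)

    truth = {
        "pairs": sorted(
            tuple(sorted(u["members"])) for u in units if u["kind"] == "pair"
        ),
        "groups": [sorted(u["members"]) for u in units if u["kind"] == "group"],
        "decoy_pairs": sorted(
            tuple(sorted(u["members"])) for u in units if u["kind"] == "decoy"
        ),
        "unit_regulators": {
            ",".join(sorted(u["members"])): [mirna_ids[i] for i in u["regulators"]]
            for u in units
        },
    }
    return SyntheticDataset(
        genes=ExpressionMatrix(
            pd.DataFrame(G, index=gene_ids, columns=sample_ids), "FPKM"),
        mirnas=ExpressionMatrix(
            pd.DataFrame(M, index=mirna_ids, columns=sample_ids), "RPM"),
        cna=CNAMatrix(
            pd.DataFrame(CNA, index=gene_ids, columns=sample_ids), "CNA"),
        table=table,
        truth=truth,
    )


def score_recovery(truth: dict, inferred) -> dict:
    """Precision/recall of the planted pairs in an inferred network.

    A planted pair counts as recovered when it is an edge of the inferred
    network or both genes sit in one inferred group. The inferred pair
    set is the gene-gene edge set plus all within-group pairs; precision
    is 1 by convention when nothing was inferred.
    """
    true_pairs = {tuple(p) for p in truth["pairs"]}
    from .groups import GroupedNetwork  # local import avoids a cycle

    if isinstance(inferred, GroupedNetwork):
        gene_edges = {
            tuple(sorted((a, b)))
            for a, ka, b, kb in zip(
                inferred.edges["node_a"], inferred.edges["kind_a"],
                inferred.edges["node_b"], inferred.edges["kind_b"])
            if ka == "gene" and kb == "gene"
        }
        inferred_pairs = gene_edges | inferred.member_pairs()
    elif isinstance(inferred, CeRNANetwork):
        inferred_pairs = inferred.edge_set()
    else:
        inferred_pairs = {tuple(sorted(p)) for p in inferred}

    hit = len(true_pairs & inferred_pairs)
    precision = 1.0 if not inferred_pairs else hit / len(inferred_pairs)
    recall = 1.0 if not true_pairs else hit / len(true_pairs)
    return {"precision": precision, "recall": recall,
            "n_inferred": len(inferred_pairs), "n_true": len(true_pairs)}
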
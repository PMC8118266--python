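"""Input preparation: sample alignment, low-expression filtering,
binding-score normalisation and top-fraction interaction selection."""

from __future__ import annotations

import math

import numpy as np

from .containers import CNAMatrix, ExpressionMatrix, GeneClassMap, InteractionTable

__all__ = [
    "align_samples",
    "filter_low_expression",
    "normalize_binding_scores",
    "select_top_interactions",
]

_EPS = 1e-12


def align_samples(
    genes: ExpressionMatrix,
    mirnas: ExpressionMatrix,
    cna: CNAMatrix | None = None,
):
    """Intersect the sample sets of all inputs and align column order.

    The shared samples keep the order they have in the gene-expression
    matrix. Raises if the intersection is empty.
    """
    shared = [s for s in genes.sample_ids if s in set(mirnas.sample_ids)]
    if cna is not None:
        cna_samples = set(cna.sample_ids)
        shared = [s for s in shared if s in cna_samples]
    if not shared:
        raise ValueError("no samples shared across the input matrices")
    out = (genes.align_samples(shared), mirnas.align_samples(shared))
    if cna is not None:
        out = out + (cna.align_samples(shared),)
    return out


def filter_low_expression(
    genes: ExpressionMatrix,
    mirnas: ExpressionMatrix,
    gene_thresh: float = 1.0,
    mirna_zero: float = 0.0,
    frac: float = 0.15,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Drop lowly expressed entities.

    A gene is removed when its expression is below ``gene_thresh`` (FPKM < 1
    by default) in at least ``frac`` of samples; a miRNA is removed when its
    expression equals ``mirna_zero`` (RPM = 0) in at least ``frac`` of
    samples. The two criteria are applied independently per data type.
    """
    if set(genes.sample_ids) != set(mirnas.sample_ids):
        raise ValueError("gene and miRNA matrices must share the sample set")
    n = len(genes.sample_ids)
    min_count = frac * n  # "at least frac" => count >= frac * n

    low_gene = (genes.values < gene_thresh).sum(axis=1) >= min_count
    low_mirna = (mirnas.values == mirna_zero).sum(axis=1) >= min_count

    if low_gene.all() or low_mirna.all():
        raise ValueError(
            "low-expression filter removed every entity; relax the threshold or frac"
        )
    kept_genes = genes.select_entities(
        [g for g, low in zip(genes.entity_ids, low_gene) if not low]
    )
    kept_mirnas = mirnas.select_entities(
        [m for m, low in zip(mirnas.entity_ids, low_mirna) if not low]
    )
    return kept_genes, kept_mirnas


def normalize_binding_scores(
    table: InteractionTable,
    classes: GeneClassMap | None = None,
    weight_floor: float = 0.01,
) -> InteractionTable:
    """Turn raw binding scores into positive interaction weights.

    Raw scores follow the weighted-context++ convention (more negative =
    stronger binding) and have class-specific distributions, so the steps
    are: (1) z-normalise within each RNA class (zero-variance class -> all
    z = 0); (2) rescale all z into [-1, 1] by dividing by the global max
    |z|; (3) flip orientation so stronger binding maps to larger values;
    (4) global min-max onto [0, 1]; (5) affine map onto [weight_floor, 1]
    so every weight is strictly positive (a zero weight would silently
    delete the interaction from the regulation statistics, which divide by
    weight sums).
    """
    if not 0 < weight_floor < 1:
        raise ValueError("weight_floor must lie in (0, 1)")
    df = table.data.copy()
    if classes is not None:
        missing = [g for g in df["target"].unique() if g not in classes]
        if missing:
            raise ValueError(f"gene(s) without RNA class: {missing[:5]}")
        cls_col = df["target"].map(lambda g: classes[g])
    else:
        cls_col = df["rna_class"]

    raw = df["raw_score"].to_numpy(dtype=float)
    z = np.zeros_like(raw)
    for c in cls_col.unique():
        m = (cls_col == c).to_numpy()
        mu, sd = raw[m].mean(), raw[m].std()  # population sd
        z[m] = 0.0 if sd < _EPS else (raw[m] - mu) / sd

    zmax = np.abs(z).max()
    if zmax < _EPS:
        # single distinct score (globally degenerate): everything binds equally
        df["norm_weight"] = 1.0
        return InteractionTable(df)
    v = -(z / zmax)  # orientation: most negative raw -> largest value
    vmin, vmax = v.min(), v.max()
    if vmax - vmin < _EPS:
        df["norm_weight"] = 1.0
        return InteractionTable(df)
    mm = (v - vmin) / (vmax - vmin)
    df["norm_weight"] = weight_floor + (1.0 - weight_floor) * mm
    return InteractionTable(df)


def select_top_interactions(
    table: InteractionTable, fraction: float = 0.40
) -> InteractionTable:
    """Keep the strongest ``fraction`` of interactions by raw binding score.

    Records are ranked most-negative-first; the top ``ceil(fraction * N)``
    are retained and records tying the boundary score are kept as well, so
    the result does not depend on input order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    raw = table.data["raw_score"].to_numpy(dtype=float)
    n_keep = math.ceil(fraction * len(raw))
    boundary = np.sort(raw)[n_keep - 1]
    return table.subset(raw <= boundary)
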
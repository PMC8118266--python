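"""Core data containers: expression/CNA matrices and miRNA-target tables.

All tabular I/O is plain TSV (UTF-8, ``.`` decimal): matrices carry entity
ids in the first column and sample ids in the header row; interaction tables
carry one (regulator, target) record per row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "pseudogene")

__all__ = [
    "ExpressionMatrix",
    "CNAMatrix",
    "InteractionTable",
    "GeneClassMap",
    "read_expression_matrix",
    "RNA_CLASSES",
]


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dupes[:5]}")


class ExpressionMatrix:
    """Non-negative expression matrix, entities (rows) x samples (columns).

    Parameters
    ----------
    data
        DataFrame indexed by entity id with sample ids as columns. Values
        must be finite and >= 0 (FPKM/RPM-like units).
    unit_label
        Free-text unit annotation ("FPKM", "RPM", ...).
    """

    _allow_negative = False

    def __init__(self, data: pd.DataFrame, unit_label: str = ""):
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValueError("expression matrix must have >0 entities and samples")
        _check_unique(data.index, "entity")
        _check_unique(data.columns, "sample")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            bad = data.index[~np.isfinite(values).all(axis=1)][0]
            raise ValueError(f"non-finite value in row {bad!r}")
        if not self._allow_negative and (values < 0).any():
            bad = data.index[(values < 0).any(axis=1)][0]
            raise ValueError(f"negative expression value in row {bad!r}")
        self.data = data.astype(float)
        self.unit_label = unit_label

    # -- basic views -----------------------------------------------------
    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, entity_id: str) -> np.ndarray:
        return self.data.loc[entity_id].to_numpy()

    def select_entities(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [i for i in ids if i in self.data.index]
        return type(self)(self.data.loc[ids], self.unit_label)

    def align_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.data.columns)
        if missing:
            raise ValueError(f"sample id(s) absent from matrix: {sorted(missing)[:5]}")
        return type(self)(self.data.loc[:, sample_ids], self.unit_label)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, unit_label: str = "") -> "ExpressionMatrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - message wrapper
            raise ValueError(f"malformed matrix file {path}: {exc}") from exc
        non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
        if len(non_numeric):
            raise ValueError(f"non-numeric cell(s) in column(s) {list(non_numeric)[:3]} of {path}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, unit_label)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="id")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        n, m = self.data.shape
        return f"<{type(self).__name__} {n} entities x {m} samples>"


class CNAMatrix(ExpressionMatrix):
    """Gene-centric copy-number matrix; values are finite reals (may be <0)."""

    _allow_negative = True

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


def read_expression_matrix(path: str | Path, kind: str = "gene") -> ExpressionMatrix:
    """Read a TSV matrix; ``kind`` selects validation and units.

    ``kind="cna"`` returns a :class:`CNAMatrix` (negative values allowed);
    ``"gene"``/``"miRNA"`` return :class:`ExpressionMatrix` with FPKM/RPM
    unit labels.
    """
    if kind == "cna":
        return CNAMatrix.from_tsv(path, unit_label="CNA")
    if kind not in ("gene", "miRNA"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    return ExpressionMatrix.from_tsv(path, unit_label="FPKM" if kind == "gene" else "RPM")


class GeneClassMap:
    """Mapping gene id -> RNA class (mRNA | lncRNA | pseudogene)."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = {g: c for g, c in mapping.items() if c not in RNA_CLASSES}
        if bad:
            raise ValueError(f"unknown RNA class(es): {dict(list(bad.items())[:3])}")
        self._map = dict(mapping)

    def __getitem__(self, gene_id: str) -> str:
        return self._map[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def from_table(cls, table: "InteractionTable") -> "GeneClassMap":
        df = table.data.drop_duplicates("target")
        return cls(dict(zip(df["target"], df["rna_class"])))


class InteractionTable:
    """miRNA-target interaction records with binding scores.

    Columns: ``regulator`` (miRNA id), ``target`` (gene id), ``raw_score``
    (weighted-context++-style; more negative = stronger binding),
    ``rna_class`` and, once normalised, ``norm_weight`` in (0, 1].
    Duplicate (regulator, target) pairs collapse to the strongest (most
    negative) raw score.
    """

    COLUMNS = ("regulator", "target", "raw_score", "rna_class")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"interaction table missing column(s) {sorted(missing)}")
        df = data.copy()
        bad_class = set(df["rna_class"]) - set(RNA_CLASSES)
        if bad_class:
            raise ValueError(f"unknown RNA class(es) {sorted(bad_class)[:3]}")
        if not np.isfinite(df["raw_score"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite raw binding score")
        # strongest score wins on (regulator, target) collision
        df = df.sort_values("raw_score", kind="mergesort")
        df = df.drop_duplicates(["regulator", "target"], keep="first")
        if "norm_weight" not in df.columns:
            df["norm_weight"] = np.nan
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def regulators(self) -> list[str]:
        return sorted(self.data["regulator"].unique())

    @property
    def targets(self) -> list[str]:
        return sorted(self.data["target"].unique())

    @property
    def has_weights(self) -> bool:
        w = self.data["norm_weight"].to_numpy(dtype=float)
        return bool(np.isfinite(w).all() and (w > 0).all())

    def regulator_sets(self) -> dict[str, frozenset[str]]:
        """gene id -> frozenset of its miRNA regulators."""
        return {
            g: frozenset(sub)
            for g, sub in self.data.groupby("target", sort=False)["regulator"]
        }

    def target_sets(self) -> dict[str, frozenset[str]]:
        return {
            r: frozenset(sub)
            for r, sub in self.data.groupby("regulator", sort=False)["target"]
        }

    def restrict(self, regulators: Iterable[str] | None = None,
                 targets: Iterable[str] | None = None) -> "InteractionTable":
        df = self.data
        if regulators is not None:
            df = df[df["regulator"].isin(set(regulators))]
        if targets is not None:
            df = df[df["target"].isin(set(targets))]
        return InteractionTable(df)

    def subset(self, mask: np.ndarray) -> "InteractionTable":
        return InteractionTable(self.data.loc[np.asarray(mask)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionTable":
        df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
        rename = {"score": "raw_score", "class": "rna_class"}
        df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:
        return (f"<InteractionTable {len(self)} records, "
                f"{self.data['regulator'].nunique()} miRNAs, "
                f"{self.data['target'].nunique()} genes>")
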
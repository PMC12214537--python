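"""Data model and readers/writers for the formats the pipeline touches.

In-memory containers are thin dataclasses around scipy sparse matrices and
pandas frames, oriented genes x cells throughout. On-disk formats are the
field's plain-text standards: Matrix Market triplets for UMI counts, GMT for
gene sets, TSV for bulk expression and sample metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger("flowsc")

__all__ = [
    "CountDataset",
    "ExpressionMatrix",
    "GeneSetCollection",
    "BulkDataset",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "collapse_probes",
    "read_bulk_tsv",
    "write_table",
]

MITO_PREFIXES = ("mt-",)


def _is_mito(symbol: str) -> bool:
    return symbol.lower().startswith(MITO_PREFIXES)


@dataclass
class CountDataset:
    """Sparse UMI count matrix (genes x cells) with per-cell/per-gene metadata.

    cell_meta is indexed by barcode and carries at least ``group`` and
    ``sample_id`` (and optionally ``cell_type``); gene_meta is indexed by gene
    symbol and carries a boolean ``mito`` flag (symbol prefix rule, mt-/MT-).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(
                {"mito": [_is_mito(g) for g in self.gene_ids]}, index=self.gene_ids
            )
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz:
            data = self.counts.data
            if np.any(data < 0):
                raise ValidationError("negative counts present")
            if not np.all(np.equal(np.mod(data, 1), 0)):
                raise ValidationError("non-integer counts present")
        dupes = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()]
        if len(dupes):
            raise ValidationError(f"duplicate gene symbols: {sorted(set(dupes))}")
        if pd.Index(self.cell_ids).has_duplicates:
            raise ValidationError("duplicate cell barcodes")
        if not self.cell_meta.index.equals(pd.Index(self.cell_ids)):
            raise ValidationError("cell_meta index does not match cell_ids")
        for col in ("group", "sample_id"):
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta missing required column {col!r}")
            if self.cell_meta[col].isna().any():
                raise ValidationError(f"cell_meta column {col!r} has missing values")
        if "mito" not in self.gene_meta.columns:
            raise ValidationError("gene_meta missing 'mito' column")

    # -- convenience --------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMI count per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with at least one UMI, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's UMIs on mitochondrial genes (0 for empty cells)."""
        totals = self.cell_totals().astype(float)
        mito_mask = self.gene_meta["mito"].to_numpy(dtype=bool)
        mito = np.asarray(self.counts[mito_mask].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        return frac

    def subset_cells(self, index: np.ndarray) -> "CountDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountDataset(
            counts=self.counts[:, index].tocsr(),
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[index],
            cell_meta=self.cell_meta.iloc[index],
            gene_meta=self.gene_meta,
        )

    def subset_genes(self, index: np.ndarray) -> "CountDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountDataset(
            counts=self.counts[index].tocsr(),
            gene_ids=self.gene_ids[index],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta,
            gene_meta=self.gene_meta.iloc[index],
        )

    def to_anndata(self):
        """Cells x genes AnnData view (copies data) for scanpy interop."""
        import anndata

        return anndata.AnnData(
            X=self.counts.T.tocsr().astype(np.float32),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )


@dataclass
class ExpressionMatrix:
    """Normalized expression (genes x cells) derived from a CountDataset."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    normalization: str = "logCP10K"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("values shape does not match gene/cell ids")
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValidationError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)


class GeneSetCollection:
    """Named, ordered gene lists (GMT semantics)."""

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]] | None = None,
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self.sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, genes in (sets or {}).items():
            self.add(name, genes, (descriptions or {}).get(name, ""))

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValidationError(f"duplicate gene set name {name!r}")
        genes = list(genes)
        if not genes:
            raise ValidationError(f"gene set {name!r} is empty")
        if any((not isinstance(g, str)) or g == "" for g in genes):
            raise ValidationError(f"gene set {name!r} contains empty symbols")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            logger.warning(
                "gene set %r: %d duplicate symbols removed", name, len(genes) - len(deduped)
            )
        self.sets[name] = deduped
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def union(self) -> list[str]:
        out: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                out[g] = None
        return list(out)


@dataclass
class BulkDataset:
    """Bulk expression on log2 scale, samples x genes, with group metadata.

    sample_meta carries ``group`` and, for paired cohorts, ``pair_id``; pair ids
    must partition samples into pairs when present.
    """

    expr: pd.DataFrame
    sample_meta: pd.DataFrame
    is_log2: bool = True

    def __post_init__(self) -> None:
        if self.expr.columns.has_duplicates:
            raise ValidationError("duplicate gene names in bulk matrix")
        if not self.sample_meta.index.equals(self.expr.index):
            raise ValidationError("sample_meta index does not match expression rows")
        if "group" not in self.sample_meta.columns:
            raise ValidationError("sample_meta missing 'group' column")
        if "pair_id" in self.sample_meta.columns:
            sizes = self.sample_meta.groupby("pair_id").size()
            if not (sizes == 2).all():
                raise ValidationError("pair_id does not partition samples into pairs")


# ---------------------------------------------------------------------------
# Matrix Market triplet I/O
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def _symbol_from_line(line: str) -> str:
    # 10x genes.tsv may be "gene_id<TAB>symbol[<TAB>type]"; one-column files
    # carry the symbol directly.
    fields = line.split("\t")
    return fields[1] if len(fields) >= 2 else fields[0]


def read_counts_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path | None = None,
) -> CountDataset:
    """Read a 10x-style MTX triplet (plus optional cell metadata TSV).

    Cells missing from the metadata file get ``group="unknown"`` and
    ``sample_id="unknown"``. The mito flag is set from the mt-/MT- prefix.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # malformed header/entries
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    genes = [_symbol_from_line(l) for l in _read_lines(genes_path)]
    barcodes = [l.split("\t")[0] for l in _read_lines(barcodes_path)]
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix declares {mat.shape[0]} x {mat.shape[1]} but gene/barcode "
            f"files list {len(genes)} genes and {len(barcodes)} barcodes"
        )
    dense_check = mat.tocoo()
    if np.any(dense_check.data < 0) or not np.all(np.mod(dense_check.data, 1) == 0):
        raise ValidationError("matrix contains negative or non-integer entries")
    meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    if meta_path is not None:
        user = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        meta = meta.join(user)
    for col, default in (("group", "unknown"), ("sample_id", "unknown")):
        if col not in meta.columns:
            meta[col] = default
        meta[col] = meta[col].fillna(default)
    return CountDataset(
        counts=mat.tocsr().astype(np.int64),
        gene_ids=np.array(genes, dtype=object),
        cell_ids=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )


def write_counts_mtx(ds: CountDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cell_meta.tsv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
        "meta": out / "cell_meta.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), ds.counts.tocoo(), field="integer")
    with open(paths["genes"], "w") as fh:
        fh.writelines(f"{g}\n" for g in ds.gene_ids)
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(f"{b}\n" for b in ds.cell_ids)
    ds.cell_meta.to_csv(paths["meta"], sep="\t", index_label="barcode")
    return paths


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Parse an MSigDB-dialect GMT file (name, description, genes...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.strip() == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g != ""]
            coll.add(name, genes, desc)
    return coll


def write_gene_sets_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in coll.names():
            genes = "\t".join(coll[name])
            fh.write(f"{name}\t{coll.descriptions.get(name, '')}\t{genes}\n")


# ---------------------------------------------------------------------------
# Bulk arrays
# ---------------------------------------------------------------------------

def _split_genes(target) -> list[str]:
    """Normalize a probe's gene annotation to a list of symbols.

    Accepts a string (with the array-annotation ``///`` multi-gene separator),
    an iterable of symbols, or None/NaN for unannotated probes.
    """
    if target is None or (isinstance(target, float) and np.isnan(target)):
        return []
    if isinstance(target, str):
        parts = [p.strip() for p in target.split("///")]
        return [p for p in parts if p]
    return [str(g) for g in target if str(g).strip()]


def collapse_probes(
    expr_by_probe: pd.DataFrame,
    probe_to_gene_map: Mapping[str, object],
    sample_meta: pd.DataFrame | None = None,
    is_log2: bool = True,
) -> BulkDataset:
    """Collapse a samples x probes matrix to samples x genes.

    Probes mapping to several genes or to none are excluded; remaining probes
    for the same gene are averaged (arithmetic mean).
    """
    gene_of: dict[str, str] = {}
    for probe in expr_by_probe.columns:
        genes = _split_genes(probe_to_gene_map.get(probe))
        if len(genes) == 1:
            gene_of[probe] = genes[0]
    if not gene_of:
        raise ValidationError("no probe in the matrix maps to exactly one gene")
    kept = expr_by_probe[list(gene_of)]
    collapsed = kept.T.groupby([gene_of[p] for p in kept.columns]).mean().T
    collapsed.columns.name = "gene"
    if sample_meta is None:
        sample_meta = pd.DataFrame({"group": "unknown"}, index=expr_by_probe.index)
    return BulkDataset(expr=collapsed, sample_meta=sample_meta, is_log2=is_log2)


def read_bulk_tsv(
    expr_path: str | Path, meta_path: str | Path, is_log2: bool = True
) -> BulkDataset:
    """Read a samples x genes TSV (first column sample ID) plus sample metadata."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    meta = meta.reindex(expr.index)
    return BulkDataset(expr=expr, sample_meta=meta, is_log2=is_log2)


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    params: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    """Write a CSV with a header comment recording version, seed and parameters."""
    from . import __version__

    parts = [f"flowsc v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    for key, val in (params or {}).items():
        parts.append(f"{key}={val}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# " + " | ".join(parts) + "\n")
        df.to_csv(fh, index=index)
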
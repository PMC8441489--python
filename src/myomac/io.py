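"""On-disk formats: Matrix-Market triplet + gene/barcode TSVs (10x-style),
GMT gene sets, and schema-checked CSV/TSV tables.

The Matrix-Market reader is deliberately strict: it rejects duplicate
coordinates, out-of-range indices and negative counts with file/line
context, guarantees the pipeline never starts from a malformed matrix.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .containers import CountMatrix, EcarTrace, GeneSetCollection, MetaboliteTable

_MM_HEADER = "%%MatrixMarket matrix coordinate integer general"


class FormatError(ValueError):
    """A file violated its declared format."""


def _fail(path: Path, lineno: int | None, msg: str) -> None:
    loc = f"{path}" if lineno is None else f"{path}:{lineno}"
    raise FormatError(f"{loc}: {msg}")


# ---------------------------------------------------------------------------
# Matrix-Market triplet + label files
# ---------------------------------------------------------------------------

def write_mtx_triplet(cm: CountMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write ``matrix.mtx`` / ``genes.tsv`` / ``barcodes.tsv`` under ``outdir``.

    Triplet indices are 1-based on disk (Matrix-Market convention); genes
    are rows. Label files are header-less single-column TSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "barcodes": outdir / "barcodes.tsv",
    }
    coo = cm.values.tocoo()
    order = np.lexsort((coo.row, coo.col))  # column-major, the 10x layout
    with open(paths["matrix"], "w") as fh:
        fh.write(_MM_HEADER + "\n")
        fh.write(f"{cm.n_genes} {cm.n_cells} {coo.nnz}\n")
        for i in order:
            fh.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {coo.data[i]}\n")
    paths["genes"].write_text("".join(g + "\n" for g in cm.gene_ids))
    paths["barcodes"].write_text("".join(b + "\n" for b in cm.barcodes))
    return paths


def read_mtx_triplet(
    matrix: str | Path,
    genes: str | Path | None = None,
    barcodes: str | Path | None = None,
) -> CountMatrix:
    """Read a 10x-style triplet directory or explicit file paths.

    ``matrix`` may be a directory containing matrix.mtx/genes.tsv/barcodes.tsv.
    Indices on disk are 1-based; the returned matrix is 0-based CSR.
    """
    matrix = Path(matrix)
    if matrix.is_dir():
        genes = matrix / "genes.tsv"
        barcodes = matrix / "barcodes.tsv"
        matrix = matrix / "matrix.mtx"
    if genes is None or barcodes is None:
        raise ValueError("genes and barcodes paths required when matrix is a file")
    gene_ids = [ln.split("\t")[0] for ln in Path(genes).read_text().splitlines() if ln]
    bc = [ln.split("\t")[0] for ln in Path(barcodes).read_text().splitlines() if ln]

    with open(matrix) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("%%MatrixMarket"):
            _fail(matrix, 1, "missing MatrixMarket header")
        tokens = header.lower().split()
        if tokens[1:4] != ["matrix", "coordinate", "integer"]:
            _fail(matrix, 1, f"unsupported MatrixMarket dialect: {header!r}")
        lineno = 1
        line = fh.readline()
        lineno += 1
        while line.startswith("%"):
            line = fh.readline()
            lineno += 1
        try:
            n_rows, n_cols, nnz = (int(t) for t in line.split())
        except ValueError:
            _fail(matrix, lineno, f"malformed size line: {line.rstrip()!r}")
        if n_rows != len(gene_ids):
            _fail(matrix, lineno, f"{n_rows} rows declared but {len(gene_ids)} gene IDs")
        if n_cols != len(bc):
            _fail(matrix, lineno, f"{n_cols} cols declared but {len(bc)} barcodes")
        rows = np.empty(nnz, dtype=np.int64)
        cols = np.empty(nnz, dtype=np.int64)
        vals = np.empty(nnz, dtype=np.int64)
        k = 0
        for line in fh:
            lineno += 1
            if not line.strip():
                continue
            if k >= nnz:
                _fail(matrix, lineno, f"more than {nnz} declared entries")
            parts = line.split()
            if len(parts) != 3:
                _fail(matrix, lineno, f"expected 3 fields, got {len(parts)}")
            try:
                i, j, v = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError:
                _fail(matrix, lineno, f"non-integer triplet: {line.rstrip()!r}")
            if not (1 <= i <= n_rows and 1 <= j <= n_cols):
                _fail(matrix, lineno, f"index ({i},{j}) outside declared {n_rows}x{n_cols}")
            if v < 0:
                _fail(matrix, lineno, f"negative count {v}")
            rows[k], cols[k], vals[k] = i - 1, j - 1, v
            k += 1
        if k != nnz:
            _fail(matrix, None, f"declared {nnz} entries but found {k}")
    flat = rows * n_cols + cols
    if len(np.unique(flat)) != nnz:
        dup = np.flatnonzero(np.bincount(flat, minlength=0) > 1) if nnz else []
        i, j = divmod(int(dup[0]), n_cols) if len(dup) else (0, 0)
        _fail(matrix, None, f"duplicate coordinate ({i + 1},{j + 1})")
    values = sp.csr_matrix((vals, (rows, cols)), shape=(n_rows, n_cols), dtype=np.int64)
    return CountMatrix(values, gene_ids, bc)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            _fail(path, lineno, f"GMT line has {len(fields)} fields, needs >=3")
        name, desc, members = fields[0], fields[1], fields[2:]
        if name in sets:
            _fail(path, lineno, f"duplicate gene-set name {name!r}")
        members = [m for m in members if m]
        if not members:
            _fail(path, lineno, f"gene set {name!r} has no members")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Schema-dispatched tables
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "cell_metadata": {
        "columns": {"barcode": str, "sample_id": str, "age": str, "timepoint": str},
        "sep": "\t",
    },
    "ecar": {
        "columns": {"well": str, "time_index": int, "phase": str, "ecar": float},
        "sep": ",",
    },
    "beads": {
        "columns": {"group": str, "well": str, "cell": int, "beads": int},
        "sep": ",",
    },
    "protein": {
        "columns": {"well": str, "protein_ug": float},
        "sep": ",",
    },
    "groups": {
        "columns": {"sample_id": str, "group": str},
        "sep": ",",
    },
}


def _read_schema_frame(path: Path, schema: str) -> pd.DataFrame:
    spec = _SCHEMAS[schema]
    df = pd.read_csv(path, sep=spec["sep"])
    unknown = set(df.columns) - set(spec["columns"])
    if unknown:
        _fail(path, None, f"unknown column(s) {sorted(unknown)} for schema {schema!r}")
    missing = set(spec["columns"]) - set(df.columns)
    if missing:
        _fail(path, None, f"missing column(s) {sorted(missing)} for schema {schema!r}")
    for col, typ in spec["columns"].items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                _fail(path, None, f"non-numeric value in column {col!r} at row {int(bad.idxmax())}")
            df[col] = coerced.astype(typ)
        else:
            df[col] = df[col].astype(str)
    return df


def read_table(path: str | Path, schema: str, **kwargs):
    """Read a CSV/TSV into the container the schema dispatches to.

    Schemas: ``metabolites`` (needs ``groups_path``), ``ecar`` (optional
    ``protein_path``), ``beads``, ``protein``, ``cell_metadata``.
    """
    path = Path(path)
    if schema == "metabolites":
        groups_path = kwargs.pop("groups_path", None)
        if groups_path is None:
            raise ValueError("schema 'metabolites' requires groups_path=")
        df = pd.read_csv(path, index_col=0)
        arr = df.apply(pd.to_numeric, errors="coerce")
        if arr.isna().any().any():
            r, c = np.argwhere(arr.isna().to_numpy())[0]
            _fail(path, None, f"non-numeric abundance at row {df.index[r]!r}, sample {df.columns[c]!r}")
        gdf = _read_schema_frame(Path(groups_path), "groups")
        groups = pd.Series(gdf["group"].to_numpy(), index=gdf["sample_id"])
        return MetaboliteTable(arr, groups)
    if schema == "ecar":
        df = _read_schema_frame(path, "ecar")
        protein_path = kwargs.pop("protein_path", None)
        protein = None
        if protein_path is not None:
            pdf = _read_schema_frame(Path(protein_path), "protein")
            protein = pd.Series(pdf["protein_ug"].to_numpy(), index=pdf["well"])
        return EcarTrace(df, protein)
    if schema in _SCHEMAS:
        return _read_schema_frame(path, schema)
    raise ValueError(f"unknown schema {schema!r}")


def write_metabolite_table(table: MetaboliteTable, path: str | Path,
                           groups_path: str | Path) -> None:
    pd.DataFrame(table.values).to_csv(path)
    pd.DataFrame({"sample_id": table.samples,
                  "group": table.groups.loc[table.samples].to_numpy()}).to_csv(
        groups_path, index=False)


def write_ecar_trace(trace: EcarTrace, path: str | Path,
                     protein_path: str | Path | None = None) -> None:
    trace.measurements.to_csv(path, index=False)
    if protein_path is not None and trace.protein_ug is not None:
        pd.DataFrame({"well": trace.protein_ug.index,
                      "protein_ug": trace.protein_ug.to_numpy()}).to_csv(
            protein_path, index=False)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
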
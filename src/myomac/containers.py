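"""In-memory containers shared across the pipeline.

These are thin, validated wrappers around numpy/scipy/pandas objects: a
gene x cell UMI count matrix, a reference expression panel (ImmGen-like),
gene-set collections, metabolite abundance tables and extracellular
acidification (ECAR) traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Injection order of the glycolysis stress test.
ECAR_PHASES = ("baseline", "glucose", "oligomycin", "2DG")


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return labels


@dataclass
class CountMatrix:
    """Gene x cell non-negative integer UMI counts.

    ``values`` is a scipy CSR matrix with genes as rows (10x convention);
    ``gene_ids`` and ``barcodes`` label rows and columns respectively.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix has negative entries")
        if not np.issubdtype(self.values.dtype, np.integer):
            data = self.values.data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValueError("count matrix entries must be integers")
            self.values = self.values.astype(np.int64)
        self.gene_ids = _check_unique(self.gene_ids, "gene IDs")
        self.barcodes = _check_unique(self.barcodes, "barcodes")
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene IDs: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            self.values[:, idx].tocsr(),
            list(self.gene_ids),
            [self.barcodes[i] for i in idx],
        )


@dataclass
class ExpressionMatrix:
    """Normalized gene x cell expression with its normalization descriptor."""

    values: np.ndarray  # genes x cells, float
    gene_ids: list[str]
    barcodes: list[str]
    scale_factor: float = 1e4
    log_base: str = "e"  # natural-log of (1 + scaled counts)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene IDs")
        self.barcodes = _check_unique(self.barcodes, "barcodes")
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("expression shape does not match labels")
        if self.values.size and self.values.min() < 0:
            raise ValueError("log-normalized expression must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene IDs: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class ReferencePanel:
    """Reference cell types x genes positive signal matrix (ImmGen-like)."""

    values: pd.DataFrame  # index = cell types, columns = genes

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        _check_unique(list(self.values.index), "reference cell types")
        _check_unique(list(self.values.columns), "reference genes")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("reference panel signals must be strictly positive")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            # preserve order, drop duplicate members
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class MetaboliteTable:
    """Metabolites x samples abundance table with per-sample group labels.

    ``provenance`` records normalization steps already applied, in order;
    a raw table (empty provenance) must be strictly positive.
    """

    values: pd.DataFrame  # index = metabolites, columns = sample IDs
    groups: pd.Series  # sample ID -> group label
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        _check_unique(list(self.values.index), "metabolites")
        _check_unique(list(self.values.columns), "samples")
        self.groups = pd.Series(self.groups).astype(str)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[list(self.values.columns)]
        if self.groups.nunique() < 2:
            raise ValueError("metabolite table needs >=2 groups for contrasts")
        if not self.provenance and (self.values.to_numpy() <= 0).any():
            bad = np.argwhere(self.values.to_numpy() <= 0)[0]
            raise ValueError(
                "raw abundances must be strictly positive; offending entry "
                f"({self.values.index[bad[0]]}, {self.values.columns[bad[1]]})"
            )
        self.provenance = tuple(self.provenance)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class EcarTrace:
    """Ordered ECAR measurements from a glycolysis stress test.

    One row per (well, time index): columns ``well``, ``time_index``,
    ``phase`` and ``ecar``. Phases must follow the injection order
    baseline -> glucose -> oligomycin -> 2DG within each well.
    ``protein_ug`` optionally maps well -> total protein (Bradford), in ug.
    """

    measurements: pd.DataFrame
    protein_ug: pd.Series | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.measurements)
        required = {"well", "time_index", "phase", "ecar"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ECAR trace missing columns: {sorted(missing)}")
        unknown = set(df["phase"]) - set(ECAR_PHASES)
        if unknown:
            raise ValueError(f"unknown ECAR phase labels: {sorted(unknown)}")
        if (df["ecar"].to_numpy() < 0).any():
            raise ValueError("ECAR values must be non-negative")
        order = {p: i for i, p in enumerate(ECAR_PHASES)}
        for well, sub in df.groupby("well"):
            sub = sub.sort_values("time_index")
            codes = sub["phase"].map(order).to_numpy()
            if (np.diff(codes) < 0).any():
                raise ValueError(f"well {well!r}: phases out of injection order")
            if len(set(codes)) < len(ECAR_PHASES):
                present = {ECAR_PHASES[c] for c in codes}
                absent = [p for p in ECAR_PHASES if p not in present]
                raise ValueError(f"well {well!r}: missing phase {absent[0]!r}")
        self.measurements = df.reset_index(drop=True)
        if self.protein_ug is not None:
            self.protein_ug = pd.Series(self.protein_ug).astype(float)
            if (self.protein_ug <= 0).any():
                raise ValueError("protein mass must be positive")

    @property
    def wells(self) -> list[str]:
        return list(dict.fromkeys(self.measurements["well"]))

    def well_trace(self, well: str) -> pd.DataFrame:
        sub = self.measurements[self.measurements["well"] == well]
        if sub.empty:
            raise KeyError(f"unknown well {well!r}")
        return sub.sort_values("time_index").reset_index(drop=True)
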
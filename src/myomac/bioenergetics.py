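"""Glycolysis stress-test metrics and phagocytosis index.

From an ECAR trace with the four injection phases (baseline, glucose,
oligomycin, 2-deoxy-D-glucose):

    non-glycolytic acidification = min ECAR of the 2DG phase
    glycolysis                   = max ECAR after glucose - last baseline ECAR
    glycolytic capacity          = max ECAR after oligomycin - last baseline ECAR
    glycolytic reserve           = capacity - glycolysis (exact identity)

"max" aggregation after each injection with the last pre-injection baseline
is the stress-test kinetics convention; a "mean"-of-phase mode is provided
since the underlying reports do not pin the variant down. Metrics can be
normalized to total protein per well (Bradford). Phagocytosis is summarized
per well (the experimental unit), then averaged within treatment groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ECAR_PHASES, EcarTrace


@dataclass
class GlycolysisMetrics:
    glycolysis: float
    glycolytic_capacity: float
    glycolytic_reserve: float
    non_glycolytic: float
    aggregation: str = "max"
    normalized: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "glycolysis": self.glycolysis,
            "glycolytic_capacity": self.glycolytic_capacity,
            "glycolytic_reserve": self.glycolytic_reserve,
            "non_glycolytic": self.non_glycolytic,
        }


def _phase_values(df: pd.DataFrame) -> dict[str, np.ndarray]:
    df = df.sort_values("time_index")
    out = {}
    for phase in ECAR_PHASES:
        vals = df.loc[df["phase"] == phase, "ecar"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"missing ECAR phase {phase!r}")
        out[phase] = vals
    return out


def glycolysis_metrics(trace, aggregation: str = "max") -> GlycolysisMetrics:
    """Stress-test metrics from a single well's trace.

    ``trace`` is a DataFrame with time_index/phase/ecar columns (or an
    EcarTrace with exactly one well). Raises naming the phase if one of the
    four injection phases is absent.
    """
    if isinstance(trace, EcarTrace):
        wells = trace.wells
        if len(wells) != 1:
            raise ValueError("pass a single-well trace (use per_well_metrics for many)")
        df = trace.well_trace(wells[0])
    else:
        df = pd.DataFrame(trace)
    if aggregation not in {"max", "mean"}:
        raise ValueError("aggregation must be 'max' or 'mean'")
    phases = _phase_values(df)
    if aggregation == "max":
        base = float(phases["baseline"][-1])  # last pre-injection measurement
        glucose = float(phases["glucose"].max())
        oligo = float(phases["oligomycin"].max())
        nong = float(phases["2DG"].min())
    else:
        base = float(phases["baseline"].mean())
        glucose = float(phases["glucose"].mean())
        oligo = float(phases["oligomycin"].mean())
        nong = float(phases["2DG"].mean())
    glycolysis = glucose - base
    capacity = oligo - base
    reserve = capacity - glycolysis
    return GlycolysisMetrics(glycolysis, capacity, reserve, nong, aggregation)


def normalize_by_protein(metrics: GlycolysisMetrics, protein_ug: float) -> GlycolysisMetrics:
    """Divide all metrics by the well's protein mass (ug); must be positive."""
    if protein_ug <= 0:
        raise ValueError("protein mass must be > 0")
    return GlycolysisMetrics(
        metrics.glycolysis / protein_ug,
        metrics.glycolytic_capacity / protein_ug,
        metrics.glycolytic_reserve / protein_ug,
        metrics.non_glycolytic / protein_ug,
        metrics.aggregation,
        normalized=True,
    )


def per_well_metrics(trace: EcarTrace, aggregation: str = "max",
                     normalize: bool = False) -> pd.DataFrame:
    """Metrics per well, optionally protein-normalized, as a tidy frame."""
    rows = []
    for well in trace.wells:
        m = glycolysis_metrics(trace.well_trace(well), aggregation)
        if normalize:
            if trace.protein_ug is None or well not in trace.protein_ug.index:
                raise ValueError(f"no protein mass recorded for well {well!r}")
            m = normalize_by_protein(m, float(trace.protein_ug[well]))
        rows.append({"well": well, **m.as_dict()})
    return pd.DataFrame(rows)


@dataclass
class PhagocytosisResult:
    group_means: pd.Series   # group -> mean of well means
    well_means: pd.DataFrame  # group, well, mean beads/cell, n cells
    n_cells: pd.Series       # group -> total cells counted


def phagocytosis_index(bead_counts: pd.DataFrame) -> PhagocytosisResult:
    """Average beads per cell with the well as the experimental unit.

    ``bead_counts`` needs columns group/well/beads (one row per cell).
    Group mean = mean of its well means.
    """
    df = pd.DataFrame(bead_counts)
    for col in ("group", "well", "beads"):
        if col not in df.columns:
            raise ValueError(f"bead table missing column {col!r}")
    if df.empty:
        raise ValueError("empty bead table")
    if (df["beads"] < 0).any():
        raise ValueError("bead counts must be >= 0")
    wm = (df.groupby(["group", "well"])["beads"]
            .agg(mean_beads="mean", n_cells="size").reset_index())
    gm = wm.groupby("group")["mean_beads"].mean()
    n = df.groupby("group")["beads"].size()
    return PhagocytosisResult(gm, wm, n)
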
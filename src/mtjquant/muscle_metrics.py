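"""Structural scoring of zebrafish muscle phenotypes.

Three assays, all on tabular inputs (manual scores or synthetic ground
truth):

* myotendinous-junction (MTJ) vertex angles from three landmark points —
  chevron-shaped MTJs widen toward a U shape when laminin adhesion fails;
* per-embryo fiber-detachment incidence (percent of muscle segments per
  embryo containing detached fibers), summarized as group mean ± SEM;
* mosaic transplanted-cell attachment rates (detached / total scored cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .stats import sem

__all__ = [
    "MtjBoundaryTrace",
    "MosaicCellCounts",
    "MosaicRate",
    "mtj_vertex_angle",
    "detachment_incidence",
    "mosaic_detachment_rate",
    "mtj_failure_fraction",
    "half_up_round",
]


@dataclass
class MtjBoundaryTrace:
    """Three MTJ landmarks in µm image coordinates (x, y)."""

    dorsal_end: tuple[float, float]
    vertex: tuple[float, float]
    ventral_end: tuple[float, float]
    embryo_id: str = ""
    somite_index: int = 0


@dataclass
class MosaicCellCounts:
    """Counts of transplanted donor cells scored in host embryos."""

    condition: str  # "stressed" | "unstressed"
    n_total: int
    n_detached: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_detached <= self.n_total:
            raise ValueError("need 0 <= n_detached <= n_total")


@dataclass
class MosaicRate:
    condition: str
    percent: float          # unrounded
    percent_rounded: float  # half-up, one decimal (reporting convention)


def half_up_round(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.45 -> 2.5), as used for printed percents."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def mtj_vertex_angle(trace: MtjBoundaryTrace) -> float:
    """Interior angle at the MTJ vertex, in degrees in (0, 180].

    The angle between the two arm vectors (vertex -> dorsal end and
    vertex -> ventral end), via the arccosine of their normalized dot
    product. Invariant to rigid motions and to swapping the arms.
    """
    v = np.asarray(trace.vertex, dtype=float)
    u1 = np.asarray(trace.dorsal_end, dtype=float) - v
    u2 = np.asarray(trace.ventral_end, dtype=float) - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("coincident landmark points: arm of zero length")
    c = float(np.dot(u1, u2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _incidence(table: pd.DataFrame, total_col: str, count_col: str):
    required = {"embryo_id", "group", total_col, count_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty table")
    totals = table[total_col].to_numpy()
    counts = table[count_col].to_numpy()
    if (totals < 1).any():
        raise ValueError(f"{total_col} must be >= 1")
    if (counts < 0).any() or (counts > totals).any():
        raise ValueError(f"need 0 <= {count_col} <= {total_col}")

    per_embryo = table[["embryo_id", "group"]].copy()
    per_embryo["percent"] = 100.0 * counts / totals

    rows = []
    for group, sub in per_embryo.groupby("group", sort=True):
        vals = sub["percent"].to_numpy()
        rows.append({
            "group": group,
            "n_embryos": len(vals),
            "mean_percent": float(np.mean(vals)),
            "sem_percent": sem(vals) if len(vals) >= 2 else np.nan,
        })
    return per_embryo, pd.DataFrame(rows)


def detachment_incidence(table: pd.DataFrame):
    """Fiber-detachment incidence from a per-embryo segment-score table.

    ``table`` columns: embryo_id, group, n_segments, n_detached_segments.
    Returns ``(per_embryo, per_group)``: per-embryo percent of muscle
    segments with detached fibers, and group mean ± SEM over embryos.
    """
    return _incidence(table, "n_segments", "n_detached_segments")


def mtj_failure_fraction(table: pd.DataFrame):
    """Per-embryo percent of MTJs that failed, plus group mean ± SEM.

    Same contract as :func:`detachment_incidence` with columns
    embryo_id, group, n_mtjs, n_failed.
    """
    return _incidence(table, "n_mtjs", "n_failed")


def mosaic_detachment_rate(counts: MosaicCellCounts) -> MosaicRate:
    """Percent of transplanted cells detached, with one-decimal reporting."""
    if counts.n_total < 1:
        raise ValueError("n_total must be >= 1")
    pct = 100.0 * counts.n_detached / counts.n_total
    return MosaicRate(counts.condition, pct, half_up_round(pct, 1))
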
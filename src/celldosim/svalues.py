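"""Cellular S-values: self, cross, and branching-weighted chain totals.

The S-value S(r_T ← r_S) is the mean absorbed dose to the target region per
decay in the source region, in Gy·Bq⁻¹·s⁻¹ (numerically Gy per decay).
Self-dose S-values come directly from single-cell runs (total nucleus dose
divided by the number of simulated decays).  Cross-dose S-values — dose to a
*nearest neighbour's* nucleus per decay, the MIRD per-neighbour convention —
are derived from 13-cell cluster runs: with decays uniform over the 13
cells the per-decay central-nucleus dose obeys

    D/N = (S_self + 12·S_cross) / 13    ⇒    S_cross = (13·D/N − S_self)/12.

Chain totals weight each member by its expected decays per ²²⁵Ac decay
(1 for all members except ²¹³Po at 0.978 and ²⁰⁹Tl at 0.022) with
uncertainties combined in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nuclides import AC225_CHAIN, chain_weights
from .scoring import RegionDose

__all__ = [
    "SValueRecord",
    "SValueTable",
    "CrossDoseInconsistencyError",
    "self_svalue",
    "cross_svalue_from_cluster",
    "cumulative_chain_svalue",
    "percent_difference",
    "AbsorbedDoseResult",
    "absorbed_dose_from_activity",
]

TOTAL_KEY = "Total"


@dataclass(frozen=True)
class SValueRecord:
    """One S-value: Gy per decay in a source compartment, with its SE."""

    nuclide: str
    compartment: str
    target: str  # "self" | "cross"
    s_gy_per_decay: float
    u_s: float = 0.0
    n_histories: int = 0

    def __post_init__(self) -> None:
        if self.s_gy_per_decay < 0 or self.u_s < 0:
            raise ValueError("S-values and uncertainties must be >= 0")


class CrossDoseInconsistencyError(ValueError):
    """Cluster dose significantly below the pure self-dose expectation."""


@dataclass
class SValueTable:
    """S-value records keyed by (nuclide, compartment, target) + provenance."""

    records: dict[tuple[str, str, str], SValueRecord] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, rec: SValueRecord) -> None:
        key = (rec.nuclide, rec.compartment, rec.target)
        self.records[key] = rec

    def get(self, nuclide: str, compartment: str, target: str = "self") -> SValueRecord:
        try:
            return self.records[(nuclide, compartment, target)]
        except KeyError:
            raise KeyError(
                f"no record for ({nuclide}, {compartment}, {target})") from None

    def is_complete(self, compartments, target: str = "self") -> bool:
        return all((n, c, target) in self.records
                   for n in AC225_CHAIN for c in compartments)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"nuclide": r.nuclide, "compartment": r.compartment,
             "target": r.target, "S": r.s_gy_per_decay, "u_S": r.u_s,
             "n_histories": r.n_histories}
            for r in self.records.values()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "SValueTable":
        table = cls(meta=dict(meta or {}))
        for row in df.itertuples(index=False):
            table.add(SValueRecord(row.nuclide, row.compartment, row.target,
                                   float(row.S), float(getattr(row, "u_S", 0.0)),
                                   int(getattr(row, "n_histories", 0))))
        return table


def self_svalue(dose: RegionDose, n_histories: int, nuclide: str,
                compartment: str) -> SValueRecord:
    """S = D_nuc / N for a single-cell run (dose summed over N decays)."""
    if n_histories <= 0:
        raise ValueError("n_histories must be positive")
    return SValueRecord(nuclide, compartment, "self",
                        dose.dose_gy / n_histories,
                        dose.uncertainty_gy / n_histories, n_histories)


def cross_svalue_from_cluster(
    cluster_dose: RegionDose,
    s_self: SValueRecord,
    n_histories: int,
    n_cells: int = 13,
    n_neighbors: int = 12,
    sigma_gate: float = 3.0,
) -> SValueRecord:
    """Per-neighbour cross S-value from the central-nucleus cluster dose.

    Raises :class:`CrossDoseInconsistencyError` if the derived value is
    negative by more than ``sigma_gate`` combined standard errors.
    """
    if s_self.target != "self":
        raise ValueError("s_self must be a self-dose record")
    d_per_decay = cluster_dose.dose_gy / n_histories
    u_d = cluster_dose.uncertainty_gy / n_histories
    s_cross = (n_cells * d_per_decay - s_self.s_gy_per_decay) / n_neighbors
    u_cross = np.hypot(n_cells * u_d, s_self.u_s) / n_neighbors
    if s_cross < -sigma_gate * u_cross:
        raise CrossDoseInconsistencyError(
            f"{s_self.nuclide}/{s_self.compartment}: derived cross S-value "
            f"{s_cross:.3e} < 0 beyond {sigma_gate} sigma ({u_cross:.3e})")
    return SValueRecord(s_self.nuclide, s_self.compartment, "cross",
                        max(s_cross, 0.0), u_cross, n_histories)


def cumulative_chain_svalue(
    table: SValueTable,
    weights: dict[str, float] | None = None,
    compartment: str = "nucleus",
    target: str = "self",
) -> SValueRecord:
    """Branching-weighted chain total S_total = Σᵢ wᵢ·Sᵢ (quadrature u)."""
    weights = weights or chain_weights("Ac-225")
    s_total = 0.0
    var = 0.0
    n_min = None
    for nuc in AC225_CHAIN:
        w = weights.get(nuc, 0.0)
        if w == 0.0:
            continue
        rec = table.get(nuc, compartment, target)
        s_total += w * rec.s_gy_per_decay
        var += (w * rec.u_s) ** 2
        n_min = rec.n_histories if n_min is None else min(n_min, rec.n_histories)
    return SValueRecord(TOTAL_KEY, compartment, target, s_total,
                        float(np.sqrt(var)), n_min or 0)


def percent_difference(s_ours: float, s_reference: float) -> float:
    """100 × (ours − reference)/reference."""
    if s_reference <= 0:
        raise ValueError("reference S-value must be positive")
    return 100.0 * (s_ours - s_reference) / s_reference


@dataclass(frozen=True)
class AbsorbedDoseResult:
    """D = A_C × S: absorbed dose from cumulated activity (MIRD schema)."""

    cumulated_activity_bq_s: float
    s_gy_per_decay: float

    @property
    def dose_gy(self) -> float:
        return self.cumulated_activity_bq_s * self.s_gy_per_decay


def absorbed_dose_from_activity(a_c: float, s: SValueRecord | float) -> AbsorbedDoseResult:
    """Absorbed dose for ``a_c`` decays (Bq·s) in the source region."""
    if a_c < 0:
        raise ValueError("cumulated activity must be >= 0")
    s_val = s.s_gy_per_decay if isinstance(s, SValueRecord) else float(s)
    return AbsorbedDoseResult(a_c, s_val)
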
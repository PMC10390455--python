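"""Daughter-retention and internalization scenario curves.

Alpha-decay recoil strips the daughter from the targeting vector, so
daughters with appreciable half-lives (²²¹Fr, 4.8 min; ²¹³Bi, 45.6 min) can
migrate before decaying.  Retention is modelled as static bookkeeping: a
fraction f of the branch nuclide *and everything downstream of it* decays at
the target site, the rest contributes zero dose anywhere:

    S(f) = S_upstream + f · S_downstream

Internalization mixes the cell-surface and whole-cell source distributions:

    S(i) = (1 − i) · S(cell_surface) + i · S(whole_cell)

Both families are affine in the fraction, so endpoints reproduce table
entries exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nuclides import AC225_CHAIN, chain_weights
from .svalues import SValueTable, cumulative_chain_svalue

__all__ = [
    "ScenarioCurve",
    "DEFAULT_FRACTIONS",
    "downstream_weights",
    "retention_curve",
    "internalization_curve",
    "max_decrease_at_zero_retention",
]

DEFAULT_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

COMPARTMENTS = ("cell_surface", "cytoplasm", "nucleus", "whole_cell")


@dataclass(frozen=True)
class ScenarioCurve:
    """Chain-total S-value versus a retention/internalization fraction."""

    scenario_kind: str  # "retention_Fr-221" | "retention_Bi-213" | "internalization"
    compartment: str | None
    fractions: tuple[float, ...]
    s_values: tuple[float, ...]
    u_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if len(self.fractions) != len(self.s_values):
            raise ValueError("fractions and S-values differ in length")

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.fractions, self.s_values, self.u_s])

    def plot(self, ax=None, **kwargs):
        """Simple line plot of S versus fraction."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", self.compartment or self.scenario_kind)
        ax.plot(self.fractions, self.s_values, marker="o", label=label, **kwargs)
        ax.set_xlabel(self.scenario_kind.replace("_", " ") + " fraction")
        ax.set_ylabel("S-value (Gy Bq$^{-1}$ s$^{-1}$)")
        return ax


def downstream_weights(branch_nuclide: str) -> dict[str, float]:
    """Chain weights of the branch nuclide and everything below it."""
    full = chain_weights("Ac-225")
    sub = chain_weights(branch_nuclide)
    # scale the sub-chain by the branch nuclide's own weight in the full chain
    w0 = full[branch_nuclide]
    return {n: w0 * w for n, w in sub.items()}


def retention_curve(
    table: SValueTable,
    branch_nuclide: str,
    compartment: str,
    fractions=DEFAULT_FRACTIONS,
    target: str = "self",
) -> ScenarioCurve:
    """Chain-total S versus retention fraction of ``branch_nuclide``+progeny."""
    if branch_nuclide not in ("Fr-221", "Bi-213"):
        raise ValueError("retention is modelled for Fr-221 or Bi-213")
    full = chain_weights("Ac-225")
    down = downstream_weights(branch_nuclide)
    up = {n: full[n] - down.get(n, 0.0) for n in full}
    s_up = cumulative_chain_svalue(table, up, compartment, target)
    s_down = cumulative_chain_svalue(table, down, compartment, target)
    fr = tuple(float(f) for f in fractions)
    s = tuple(s_up.s_gy_per_decay + f * s_down.s_gy_per_decay for f in fr)
    u = tuple(float(np.hypot(s_up.u_s, f * s_down.u_s)) for f in fr)
    return ScenarioCurve(f"retention_{branch_nuclide}", compartment, fr, s, u)


def internalization_curve(
    table: SValueTable,
    fractions=DEFAULT_FRACTIONS,
    nuclide: str | None = None,
    target: str = "self",
) -> ScenarioCurve:
    """S versus internalized fraction (surface → whole-cell mixing).

    ``nuclide=None`` mixes the chain totals; a specific nuclide mixes its
    own records.
    """
    if nuclide is None:
        lo = cumulative_chain_svalue(table, None, "cell_surface", target)
        hi = cumulative_chain_svalue(table, None, "whole_cell", target)
    else:
        lo = table.get(nuclide, "cell_surface", target)
        hi = table.get(nuclide, "whole_cell", target)
    fr = tuple(float(f) for f in fractions)
    s = tuple((1.0 - f) * lo.s_gy_per_decay + f * hi.s_gy_per_decay for f in fr)
    u = tuple(float(np.hypot((1.0 - f) * lo.u_s, f * hi.u_s)) for f in fr)
    return ScenarioCurve("internalization", nuclide, fr, s, u)


def max_decrease_at_zero_retention(
    table: SValueTable,
    branch_nuclide: str,
    compartments=COMPARTMENTS,
    target: str = "self",
) -> float:
    """Largest % decrease of the chain total at zero retention, over compartments."""
    worst = 0.0
    for comp in compartments:
        curve = retention_curve(table, branch_nuclide, comp, (0.0, 1.0), target)
        s0, s1 = curve.s_values
        worst = max(worst, 100.0 * (1.0 - s0 / s1))
    return worst
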
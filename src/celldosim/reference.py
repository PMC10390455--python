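"""Published reference S-values and regression comparison.

The packaged fixture carries the published Geant4-DNA nuclear S-values for
the ²²⁵Ac chain (single cell and 13-cell cluster) together with the per cent
difference each value has with respect to MIRDcell v3.10.  The MIRDcell
values themselves were not printed and are reconstructed by inverting the
per cent-difference definition:

    pct = 100·(S − S_mirdcell)/S_mirdcell   ⇒   S_mirdcell = S/(1 + pct/100)

Reconstruction is exact up to the 3-significant-figure rounding of the
printed values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .svalues import SValueTable, percent_difference

__all__ = ["ReferenceTable", "load_reference_table", "compare_to_reference"]


@dataclass
class ReferenceTable:
    """Published S-values plus reconstructed MIRDcell comparison values."""

    frame: pd.DataFrame  # columns: target, nuclide, compartment, S, pct, S_mirdcell

    def value(self, nuclide: str, compartment: str, target: str = "self",
              source: str = "published") -> float:
        sel = self.frame[
            (self.frame.nuclide == nuclide)
            & (self.frame.compartment == compartment)
            & (self.frame.target == target)
        ]
        if len(sel) != 1:
            raise KeyError(f"no reference for ({nuclide}, {compartment}, {target})")
        col = {"published": "S", "mirdcell": "S_mirdcell"}[source]
        return float(sel[col].iloc[0])

    def roundtrip_pct(self, nuclide: str, compartment: str,
                      target: str = "self") -> float:
        """Per cent difference recomputed from the reconstructed MIRDcell value."""
        return percent_difference(
            self.value(nuclide, compartment, target, "published"),
            self.value(nuclide, compartment, target, "mirdcell"),
        )


def load_reference_table() -> ReferenceTable:
    """Load the packaged published-values fixture."""
    path = resources.files("celldosim") / "data" / "reference_svalues.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    df = df.rename(columns={"pct_diff_vs_mirdcell": "pct"})
    df["S_mirdcell"] = df["S"] / (1.0 + df["pct"] / 100.0)
    return ReferenceTable(df)


def compare_to_reference(
    table: SValueTable,
    reference: ReferenceTable | None = None,
    tolerance_pct: float | None = None,
) -> pd.DataFrame:
    """Per-record per cent differences versus published and MIRDcell values.

    Returns a tidy frame with ``pct_vs_published`` and ``pct_vs_mirdcell``;
    if ``tolerance_pct`` is given, adds a boolean ``flagged`` column marking
    records outside that band versus the published values.
    """
    reference = reference or load_reference_table()
    rows = []
    for rec in table.records.values():
        try:
            pub = reference.value(rec.nuclide, rec.compartment, rec.target)
            mird = reference.value(rec.nuclide, rec.compartment, rec.target,
                                   "mirdcell")
        except KeyError:
            continue
        rows.append({
            "nuclide": rec.nuclide,
            "compartment": rec.compartment,
            "target": rec.target,
            "S": rec.s_gy_per_decay,
            "u_S": rec.u_s,
            "S_published": pub,
            "S_mirdcell": mird,
            "pct_vs_published": percent_difference(rec.s_gy_per_decay, pub),
            "pct_vs_mirdcell": percent_difference(rec.s_gy_per_decay, mird),
        })
    out = pd.DataFrame(rows)
    if tolerance_pct is not None and not out.empty:
        out["flagged"] = out["pct_vs_published"].abs() > tolerance_pct
    return out
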
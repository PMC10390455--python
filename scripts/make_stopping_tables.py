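"""Regenerate the packaged stopping-power/range fixtures.

Writes the synthetic liquid-water tables for alphas and electrons under
src/celldosim/data/.  Run from the repository root:

    python scripts/make_stopping_tables.py
"""

from pathlib import Path

from celldosim.stopping import build_table

HEADERS = {
    "alpha": """\
# Synthetic stopping-power / CSDA-range table: alpha particles in liquid water
# (density 1.0 g/cm^3).  Computed from the Bethe formula with a Barkas-type
# effective charge (I = 75 eV); the sub-Bragg-peak region (< ~0.75 MeV) is an
# empirical power law calibrated so the integrated CSDA range reproduces the
# published alpha ranges in unit-density tissue (47 um at 5.8 MeV, 85 um at
# 8.4 MeV).  Stand-in for ICRU/ASTAR reference tabulations; not measured data.
# columns: E_MeV  S_MeV_cm2_per_g  S_MeV_per_um  R_um
""",
    "beta": """\
# Synthetic stopping-power / CSDA-range table: electrons in liquid water
# (density 1.0 g/cm^3).  Berger-Seltzer collision stopping power (Moller),
# I = 75 eV; radiative losses neglected (<2% below 2 MeV in water).
# Stand-in for ICRU/ESTAR reference tabulations; not measured data.
# columns: E_MeV  S_MeV_cm2_per_g  S_MeV_per_um  R_um
""",
}
NAMES = {"alpha": "alpha_water_stopping_synthetic.tsv",
         "beta": "electron_water_stopping_synthetic.tsv"}


def main() -> None:
    out_dir = Path(__file__).resolve().parents[1] / "src" / "celldosim" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    for kind in ("alpha", "beta"):
        E, S, R = build_table(kind)
        lines = [HEADERS[kind]]
        for e, s, r in zip(E, S, R):
            lines.append(f"{e:.6e}\t{s:.6e}\t{s * 1e-4:.6e}\t{r:.6e}\n")
        (out_dir / NAMES[kind]).write_text("".join(lines))
        print(f"wrote {out_dir / NAMES[kind]} ({len(E)} rows)")


if __name__ == "__main__":
    main()
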
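# celldosim

Cellular Monte Carlo microdosimetry for the ²²⁵Ac decay chain.

Targeted alpha therapy with ²²⁵Ac delivers four high-LET alpha particles
(5.8–8.4 MeV, tissue ranges 47–85 µm) through a cascade of short-lived
daughters (²²¹Fr, ²¹⁷At, ²¹³Bi, ²¹³Po, ²⁰⁹Tl, ²⁰⁹Pb).  Because the alpha
range is only a few cell diameters, dosimetry for single cancer cells and
micrometastases has to be done at the cellular scale, and because alpha
recoil breaks the daughters free of the targeting vector, the dose actually
delivered depends on how well each daughter is retained at the target and on
how deeply the radiopharmaceutical is internalized.  This package computes
the quantities that capture all of that: **cellular S-values** — the mean
absorbed dose to the cell nucleus per radioactive decay in a source region,
in Gy·Bq⁻¹·s⁻¹ — in the MIRD schema `D(r_T ← r_S) = Ã · S(r_T ← r_S)`.

It is aimed at researchers developing preclinical alpha-emitter
radiopharmaceuticals who need per-nuclide, per-compartment dose coefficients
and what-if curves for daughter migration and internalization.

## What it does

* **Per-decay Monte Carlo** of each chain member individually: decays are
  sampled uniformly in one of four source compartments of a MIRD-style cell
  (10 µm cell, 8 µm concentric nucleus, liquid water) — cell surface,
  cytoplasm, nucleus, or whole cell — with isotropic single-emission
  branches (²¹³Bi splits 97.8% β⁻ / 2.2% α).
* **Straight-track CSDA transport** on packaged stopping-power/range tables
  for alphas and electrons in unit-density water, scoring energy into a
  100×100×100 grid of 0.8 µm voxels (with per-history statistics for
  history-by-history uncertainty estimation) or into exact analytic chords
  of the nucleus sphere.
* **Self- and cross-dose S-values**: self-dose from single-cell runs
  (S = D_nuc/N); cross-dose to a nearest neighbour's nucleus from a 13-cell
  hexagonal-close-packed micrometastasis via
  `S_cross = (13·D/N − S_self)/12`.
* **Chain totals** weighted by branching (1 for every member except
  ²¹³Po at 0.978 and ²⁰⁹Tl at 0.022), and **scenario curves**:
  S versus retention fraction of ²²¹Fr or ²¹³Bi (+ progeny), and S versus
  the internalized fraction mixing surface and whole-cell distributions.
* **Regression against published values** from a packaged reference table
  (including reconstructed MIRDcell v3.10 comparison values).

## Worked example

```python
from celldosim import (CellModel, TransportConfig, get_decay_scheme,
                       simulate_decays)

res = simulate_decays(get_decay_scheme("Ac-225"), CellModel(), "nucleus",
                      TransportConfig(n_histories=100_000, seed=1))
dose = res.region_dose("history")
print(f"S = {dose.dose_gy / res.n_histories:.4f} Gy/decay "
      f"(rel. SE {dose.relative_uncertainty:.2%})")
```

prints

```
S = 0.1430 Gy/decay (rel. SE 0.20%)
```

i.e. each ²²⁵Ac decay inside the nucleus deposits on average 0.143 Gy in
that nucleus — within ~2% of the published value 1.40×10⁻¹ Gy·Bq⁻¹·s⁻¹ for
this geometry.  The full study (all seven nuclides, four compartments,
single cell + cluster, scenario curves, comparison report) runs from one
config:

```sh
celldosim run --seed 1 --out results/study
celldosim compare --table results/study/svalues.csv --tolerance 15 --out cmp.csv
```

## Scope and limitations

Transport is continuous-slowing-down on straight tracks: no delta-ray
transport, no energy-loss straggling, no photon/Auger emissions.  For the
alpha emitters this is the same model class as the MIRD convolution codes
and agrees with them to a few per cent; for the low-energy beta emitters
(²⁰⁹Tl, ²⁰⁹Pb, the ²¹³Bi beta branch) the approximation is coarse — their
S-values are order-of-magnitude only, and they contribute <2% of any chain
total.  See `docs/methods.md` for the full model description and numerical
choices.
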
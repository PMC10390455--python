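# Methods

## Model overview

The package computes cellular S-values — mean absorbed dose to the cell
nucleus per decay in a source region, Gy·Bq⁻¹·s⁻¹ — for the members of the
²²⁵Ac decay chain by per-decay Monte Carlo in two geometries:

* a single MIRD-style cell: two concentric spheres of unit-density liquid
  water, cell radius 5 µm, nucleus radius 4 µm;
* a micrometastasis: 13 identical cells, a central cell plus the 12
  nearest-neighbour sites of a hexagonal close-packed lattice at 10 µm
  spacing (touching cells).  The HCP shell orientation is the canonical one
  (hexagon in the z = 0 plane, staggered triangles at z = ±d·√(2/3)); for
  the symmetric sources simulated here all scored quantities are invariant
  under rotations of the shell.

Each history is one radioactive decay of one nuclide: a host cell (cluster:
uniform over the 13 cells), a source position uniform in the chosen
compartment (cell surface — a zero-thickness sphere at r = 5 µm, the MIRD
"cell surface" convention; cytoplasm; nucleus; whole cell), a decay branch
drawn by branching ratio, and a single charged emission launched
isotropically.  Daughters are *not* followed; chain quantities are assembled
afterwards as branching-weighted sums, which is what makes the retention
bookkeeping possible.  Decay data (line energies, mean beta energies,
half-lives, the 97.8%/2.2% ²¹³Bi split) are hard-coded from the published
chain description; half-lives are metadata only — no Bateman evolution is
ever computed because S-values are per-decay quantities.  (Note: the chain's
second daughter is At-217; the occasional "²¹⁸At" in the source literature
is a typo.)

Alphas are mono-energetic at the per-nuclide line energy (5.8, 6.3, 7.1,
5.9, 8.4 MeV); betas default to their printed mean energy (0.435, 0.660,
0.198 MeV), with an opt-in allowed-shape spectrum whose endpoint is solved
so the spectrum mean equals the printed mean.  Gamma, X-ray, Auger and
conversion-electron emissions are not transported: on an 80 µm water domain
their energy deposition is negligible against 5.8–8.4 MeV alphas.  The
~0.1 MeV alpha-decay recoil is not scored by default (MIRD-class
comparators exclude it; it is ~2% of one alpha's energy); a flag deposits
it at the emission point.

## Transport and stopping-power data

Transport is the continuous slowing-down approximation (CSDA) on straight
tracks: a particle of energy E₀ and CSDA range R₀ = R(E₀) deposits, across
any segment [s₁, s₂] of its path, the residual-energy difference
E(R₀−s₁) − E(R₀−s₂).  Straight tracks are physically justified for alphas
(negligible angular scattering); for electrons they are an approximation —
electron ranges far exceed the cell, so chord-segment deposition dominates,
but delta rays and detours are ignored.  Consequently beta-only S-values
are order-of-magnitude estimates and are excluded from quantitative
regression (they contribute <2% of every chain total).

Stopping-power/range tables for liquid water ship as plain-text package
data and are interpolated log–log.  They are *synthetic* (computed, not
copied from a reference tabulation):

* **alphas** — Bethe formula with I = 75 eV and a Barkas-type effective
  charge Z_eff = 2·(1−exp(−125β/2^(2/3))).  Two calibration constants (a
  scale on the Bethe region, absorbing the shell/Barkas/Bloch corrections
  the bare formula lacks, and the amplitude of a low-energy enhancement
  term) are solved once so the integrated range reproduces *both* published
  alpha ranges in unit-density tissue: 47 µm at 5.8 MeV and 85 µm at
  8.4 MeV.  Below the Bragg peak (~0.75 MeV), where the Bethe expansion
  fails, an E^0.35 power law is grafted on; on this problem's scale all
  scoring happens within the first ~20 µm of a 47–85 µm track, so that
  region only fixes the (unscored) end of track.
* **electrons** — Berger–Seltzer collision stopping power (Møller),
  I = 75 eV; radiative losses (<2% below 2 MeV in water) neglected.
  Spot checks against standard water tabulations agree to ~1–3%
  (e.g. R(0.2 MeV) ≈ 449 µm, S(0.1 MeV) ≈ 4.12 MeV·cm²/g).

`scripts/make_stopping_tables.py` regenerates both fixtures.

## Scoring and uncertainties

Voxel mode mirrors the dose-actor approach: a 100×100×100 grid of 0.8 µm
voxels spanning ±40 µm, the cell centre on the corner shared by the eight
central voxels.  Tracks are walked with Amanatides–Woo traversal (numba);
per-voxel deposits telescope, so each history conserves energy within the
grid to machine precision.  The nucleus region is the set of voxels whose
*centre* lies inside the nucleus sphere; membership is binary.  On the
reference grid that mask holds 552 voxels, over-covering the 4 µm sphere by
5.4% in volume — the price of the binary convention at r/edge = 5.  The
region dose is the mean of per-voxel doses, D_nuc = ΣD_vox/n.

Two uncertainty estimators are provided:

* the **history-by-history voxel estimator**
  u[D_vox] = √( (ΣD²/N − (ΣD/N)²)/(N−1) ), aggregated over the region as
  the plain mean u[D_nuc] = Σu[D_vox]/n.  This is the published
  convention, implemented verbatim; note it describes the *typical voxel*,
  not the region mean — it ignores inter-voxel correlation and comes out
  near the single-voxel relative error (~3% at 10⁵ alpha histories).
* the **history-level region estimator**: the variance of the per-history
  nucleus dose.  This is the honest standard error of the region dose and
  is what the S-value uncertainties report.  At 10⁵ alpha histories it is
  ~0.2% for nucleus/whole-cell sources and 0.5–0.9% for cytoplasm/surface
  sources (where half the emissions miss the nucleus entirely).

Analytic-chord mode skips the grid and scores the exact chord of the
nucleus sphere per track; it is the discretisation-free oracle used in
tests, and agrees with voxel scoring to ~1% on mask-commensurate regions.
For the 8 µm nucleus the binary mask shifts the mean dose by −3% (nucleus
sources) to +3% (cytoplasm sources) relative to the chord oracle; this
offset is part of the published scoring convention, not a transport error.

## S-values, cross-dose, scenarios

Self-dose: S = D_nuc/N from the single-cell run.  Cross-dose uses the
cluster symmetry: with decays uniform over 13 cells the per-decay central
nucleus dose obeys D/N = (S_self + 12·S_cross)/13, giving the per-nearest-
neighbour (MIRD convention) value S_cross = (13·D/N − S_self)/12; the
magnitudes of the published cluster table (~¼ of self-dose for alphas) are
consistent with this per-neighbour convention, not with an all-neighbours
sum.  A derived cross value negative beyond 3 combined SE raises an
inconsistency error.  History allocation over cluster cells is stochastic
(uniform), identical in expectation to a deterministic equal split;
per-cell counts are recorded.

Chain totals are Σᵢ wᵢSᵢ with w = 1 for Ac/Fr/At/Bi/Pb, 0.978 for Po and
0.022 for Tl; uncertainties combine in quadrature.

Retention treats a fraction (1−f) of a branch nuclide *and all its progeny*
as migrated and contributing zero dose anywhere (total loss, no
redistribution): S(f) = S_upstream + f·S_downstream.  Internalization mixes
the two bounding distributions: S(i) = (1−i)·S(surface) + i·S(whole cell).
Both curve families are affine by construction with endpoints equal to
table entries.  The default fraction grid is 0 to 1 in steps of 0.2.

## Reproducibility and run protocol

Default history counts follow the published protocol: 10⁵ per alpha
emitter, 2×10⁶ per beta emitter, each split into 10 sub-jobs whose seeds
derive as seed + job index; merging sub-job accumulators is arithmetically
identical to averaging equally sized per-job dose images.  The default
generator is numpy's PCG64; Mersenne Twister is available as a config
option.  Fixed seeds give bit-identical grids and byte-identical CSV
outputs.  Cluster runs default to 2×10⁵ alpha histories (derived cross
S-value SE ≲ 1%).  The shared test fixture scales beta emitters to 2×10⁵
histories to keep the suite fast; since betas carry <2% of any chain
total, the induced noise is far below every comparison tolerance.  The
acceptance script uses the full protocol.

## Known limitations

* No delta-ray transport or energy-loss straggling: versus the published
  track-structure results this overestimates distal-source alpha self-dose
  (up to ~+15% for ²¹³Po on the cell surface, where the published
  CSDA-class comparator itself sits +13.8% above the track-structure
  value); versus the CSDA-class comparator this implementation agrees to
  ±4% everywhere.
* Beta S-values are order-of-magnitude (mono-energetic mean-energy CSDA
  electrons); the published track-structure values themselves deviate from
  CSDA comparators by −71% to +9% for these emitters at this cell size.
* Spherical concentric geometry only; no cell-size distributions,
  eccentric nuclei, or irregular shapes.
* Retention is static bookkeeping, not a kinetic (half-life/diffusion)
  migration model, and migrated progeny deposit nothing anywhere.
* The synthetic stopping tables are calibrated reproductions, not ICRU
  tabulations; their Bethe-region shape is accurate to a few per cent.
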
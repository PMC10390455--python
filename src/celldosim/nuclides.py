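"""Decay schemes of the ²²⁵Ac chain.

²²⁵Ac reaches stable ²⁰⁹Bi through six short-lived daughters.  Each decay
branch carries a single charged emission: alphas are mono-energetic at the
per-nuclide line energy, betas are represented by their mean energy (an
allowed-shape spectrum sampler is available as an opt-in, see
:func:`sample_beta_energy`).  Gammas, X-rays, Auger and conversion electrons
deposit negligible energy on an 80 µm water domain and are not modelled.

Half-lives are metadata only: S-values are per-decay quantities, so no
activity (Bateman) evolution is ever computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

__all__ = [
    "EmissionLine",
    "DecayBranch",
    "DecayScheme",
    "UnknownNuclideError",
    "AC225_CHAIN",
    "get_decay_scheme",
    "chain_weights",
    "sample_beta_energy",
    "beta_endpoint_for_mean",
]

#: electron rest energy [MeV]
_ME_C2 = 0.51099895


@dataclass(frozen=True)
class EmissionLine:
    """One charged emission of a decay branch.

    ``energy`` is the alpha line energy, or the beta *mean* energy, in MeV.
    ``intensity`` is emissions per branch decay (1 for every line here).
    """

    particle_kind: str  # "alpha" | "beta"
    energy: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.particle_kind not in ("alpha", "beta"):
            raise ValueError(f"unknown particle kind {self.particle_kind!r}")
        if not self.energy > 0:
            raise ValueError("emission energy must be positive")
        if not 0 < self.intensity <= 1:
            raise ValueError("intensity must be in (0, 1]")


@dataclass(frozen=True)
class DecayBranch:
    probability: float
    daughter: str | None
    lines: tuple[EmissionLine, ...]


@dataclass(frozen=True)
class DecayScheme:
    """Decay scheme of a single nuclide: half-life and weighted branches."""

    nuclide: str
    half_life_s: float
    branches: tuple[DecayBranch, ...]

    def __post_init__(self) -> None:
        if not self.half_life_s > 0:
            raise ValueError("half-life must be positive")
        total = sum(b.probability for b in self.branches)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"branch probabilities sum to {total}, not 1")

    @property
    def is_alpha_emitter(self) -> bool:
        """True if the dominant branch emits an alpha particle."""
        major = max(self.branches, key=lambda b: b.probability)
        return major.lines[0].particle_kind == "alpha"


class UnknownNuclideError(KeyError):
    """Raised for nuclides outside the supported ²²⁵Ac chain."""


_DAY = 86400.0
_HOUR = 3600.0
_MIN = 60.0

# Line energies, half-lives and branching ratios of the 225Ac series.
# Note: one occasionally sees the second daughter typeset as "218At"; the
# chain member is astatine-217.
_SCHEMES: dict[str, DecayScheme] = {
    "Ac-225": DecayScheme(
        "Ac-225", 9.92 * _DAY,
        (DecayBranch(1.0, "Fr-221", (EmissionLine("alpha", 5.8),)),),
    ),
    "Fr-221": DecayScheme(
        "Fr-221", 4.80 * _MIN,
        (DecayBranch(1.0, "At-217", (EmissionLine("alpha", 6.3),)),),
    ),
    "At-217": DecayScheme(
        "At-217", 32.6e-3,
        (DecayBranch(1.0, "Bi-213", (EmissionLine("alpha", 7.1),)),),
    ),
    "Bi-213": DecayScheme(
        "Bi-213", 45.6 * _MIN,
        (
            DecayBranch(0.978, "Po-213", (EmissionLine("beta", 0.435),)),
            DecayBranch(0.022, "Tl-209", (EmissionLine("alpha", 5.9),)),
        ),
    ),
    "Po-213": DecayScheme(
        "Po-213", 3.72e-6,
        (DecayBranch(1.0, "Pb-209", (EmissionLine("alpha", 8.4),)),),
    ),
    "Tl-209": DecayScheme(
        "Tl-209", 2.16 * _MIN,
        (DecayBranch(1.0, "Pb-209", (EmissionLine("beta", 0.660),)),),
    ),
    "Pb-209": DecayScheme(
        "Pb-209", 3.23 * _HOUR,
        (DecayBranch(1.0, None, (EmissionLine("beta", 0.198),)),),
    ),
}

#: chain members in decay order (terminating at stable 209Bi)
AC225_CHAIN: tuple[str, ...] = (
    "Ac-225", "Fr-221", "At-217", "Bi-213", "Po-213", "Tl-209", "Pb-209",
)


def get_decay_scheme(nuclide: str) -> DecayScheme:
    """Return the decay scheme of a ²²⁵Ac-chain member."""
    try:
        return _SCHEMES[nuclide]
    except KeyError:
        raise UnknownNuclideError(
            f"{nuclide!r} is not in the supported 225Ac chain "
            f"{sorted(_SCHEMES)}"
        ) from None


def chain_weights(head: str = "Ac-225") -> dict[str, float]:
    """Expected decays of each chain member per decay of ``head``.

    Branch probabilities propagate down the chain: starting from ``head``
    with weight 1, each daughter accumulates parent weight x branch
    probability.  For the full chain this yields 1 for every nuclide except
    Po-213 (0.978) and Tl-209 (0.022), the two sides of the ²¹³Bi split.
    """
    get_decay_scheme(head)  # validate membership
    weights: dict[str, float] = {head: 1.0}
    # chain is a tree with merges (Po-213 and Tl-209 both feed Pb-209):
    # process nuclides in decay order so parent weights are final.
    for nuc in AC225_CHAIN:
        w = weights.get(nuc)
        if w is None:
            continue
        for branch in _SCHEMES[nuc].branches:
            if branch.daughter is not None:
                weights[branch.daughter] = (
                    weights.get(branch.daughter, 0.0) + w * branch.probability
                )
    return weights


# ---------------------------------------------------------------------------
# beta energy sampling

def _allowed_spectrum(E: np.ndarray, endpoint: float) -> np.ndarray:
    """Unnormalised allowed beta shape p·W·(W0−W)² (no Coulomb correction)."""
    W = E / _ME_C2 + 1.0
    W0 = endpoint / _ME_C2 + 1.0
    p = np.sqrt(np.clip(W**2 - 1.0, 0.0, None))
    return p * W * np.clip(W0 - W, 0.0, None) ** 2


def _spectrum_mean(endpoint: float) -> float:
    E = np.linspace(1e-6, endpoint, 2000)
    w = _allowed_spectrum(E, endpoint)
    return float(np.trapezoid(w * E, E) / np.trapezoid(w, E))


def beta_endpoint_for_mean(mean_energy: float) -> float:
    """Endpoint energy of an allowed spectrum with the given mean energy."""
    return float(
        brentq(lambda e0: _spectrum_mean(e0) - mean_energy,
               1.2 * mean_energy, 6.0 * mean_energy, xtol=1e-8)
    )


def sample_beta_energy(
    scheme: DecayScheme,
    branch: DecayBranch | int = 0,
    rng: np.random.Generator | None = None,
    size: int | None = None,
    mode: str = "mean_energy",
) -> float | np.ndarray:
    """Draw beta energies [MeV] for a beta branch of ``scheme``.

    ``mode="mean_energy"`` (default) returns the printed mean energy
    deterministically — only mean energies are tabulated for this chain, and
    betas contribute <2% of the chain totals.  ``mode="spectrum"`` samples an
    allowed-shape spectrum whose endpoint is solved so the spectrum mean
    equals the printed mean.
    """
    if isinstance(branch, int):
        branch = scheme.branches[branch]
    line = branch.lines[0]
    if line.particle_kind != "beta":
        raise ValueError(f"branch of {scheme.nuclide} has no beta line")
    if mode == "mean_energy":
        if size is None:
            return line.energy
        return np.full(size, line.energy)
    if mode != "spectrum":
        raise ValueError(f"unknown beta mode {mode!r}")
    if rng is None:
        raise ValueError("spectrum mode requires an rng")
    endpoint = beta_endpoint_for_mean(line.energy)
    grid = np.linspace(1e-6, endpoint, 4000)
    pdf = _allowed_spectrum(grid, endpoint)
    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    u = rng.random(size if size is not None else 1)
    out = np.interp(u, cdf, grid)
    return out if size is not None else float(out[0])
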
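"""Analytically solvable harmonic alchemical system.

A single particle sits in a harmonic well whose spring constant is switched
linearly with the coupling parameter, k(λ) = (1−λ)·k0 + λ·k1, i.e.
U(x; λ) = ½ k(λ) x².  The alchemical free energy change has the closed form

    ΔG = (kT/2) · ln(k1/k0)

and ∂U/∂λ = ½ (k1−k0) x² with ⟨∂U/∂λ⟩_λ = ½ (k1−k0) · kT/k(λ), which makes
this model an exactness oracle for the thermodynamic-integration machinery:
samples drawn here, pushed through window averaging and quadrature, must
reproduce the closed form within quadrature and sampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["HarmonicAlchemyModel", "analytic_harmonic_dg", "sample_harmonic_dudl"]


@dataclass(frozen=True)
class HarmonicAlchemyModel:
    """Harmonic well morphed from spring constant ``k0`` to ``k1`` at thermal energy ``kT``.

    Energies are in kcal/mol; spring constants in kcal/mol/Å² (any consistent
    energy/length² unit works — only ratios and kT enter the free energy).
    """

    k0: float
    k1: float
    kT: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "kT"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and positive, got {value!r}")

    def spring_constant(self, lam: float) -> float:
        """k(λ) = (1−λ)·k0 + λ·k1."""
        return (1.0 - lam) * self.k0 + lam * self.k1


def analytic_harmonic_dg(model: HarmonicAlchemyModel) -> float:
    """Exact alchemical free energy (kT/2)·ln(k1/k0) in kcal/mol."""
    return 0.5 * model.kT * math.log(model.k1 / model.k0)


def sample_harmonic_dudl(
    model: HarmonicAlchemyModel,
    lam: float,
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Draw ``n`` equilibrium ∂U/∂λ samples at coupling ``lam``.

    Positions are drawn from the Boltzmann distribution of the λ-state,
    x ~ Normal(0, kT/k(λ)), and each sample is ½(k1−k0)x².  The sample mean
    therefore converges to ½(k1−k0)·kT/k(λ).  With ``seed`` omitted the
    model's own seed is used; either way the vector is reproducible.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if n < 1:
        raise ValueError(f"need at least one sample, got n={n}")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    k_lam = model.spring_constant(lam)
    x = rng.normal(0.0, math.sqrt(model.kT / k_lam), size=n)
    return 0.5 * (model.k1 - model.k0) * x**2
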
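"""Single-locus dominant architectures for a common complex disease.

Each susceptibility gene is summarised by the aggregate frequency ``q`` of its
risk alleles, the sporadic (non-carrier) disease rate ``f0`` and a genotype
relative risk ``grr`` so that carriers have penetrance ``f1 = grr * f0``.
Under a multiplicative model across loci, the number of such genes consistent
with a target aggregate first-degree familial relative risk (default 1.33) is

    N = log(FRR_total) / log(lambda_R)

where ``lambda_R`` is the locus-specific familial relative risk to first-degree
relatives, computed here by exact enumeration of the joint genotype
distribution of a parent-offspring pair under Hardy-Weinberg equilibrium and
Mendelian transmission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticModel",
    "MODELS",
    "genotype_frequencies",
    "penetrance_vector",
    "prevalence",
    "locus_frr",
    "num_loci",
]


@dataclass(frozen=True)
class GeneticModel:
    """One disease architecture (per-gene aggregate allele frequency).

    Parameters
    ----------
    name
        Short label ("I" .. "V" for the shipped presets).
    q
        Combined frequency of risk alleles in the gene (probability).
    f0
        Sporadic rate: disease probability for non-carriers.
    grr
        Genotype relative risk for carriers of at least one risk allele
        (dominant model; homozygotes have the same penetrance as
        heterozygotes).
    frr_total_target
        Aggregate first-degree familial relative risk the full set of loci
        should explain (dimensionless).
    """

    name: str
    q: float
    f0: float
    grr: float
    frr_total_target: float = 1.33

    def __post_init__(self) -> None:
        if not 0.0 <= self.q < 1.0:
            raise ValueError(f"allele frequency q={self.q} outside [0, 1)")
        if not 0.0 < self.f0 < 1.0:
            raise ValueError(f"sporadic rate f0={self.f0} outside (0, 1)")
        if self.grr < 1.0:
            raise ValueError(f"genotype relative risk {self.grr} < 1")
        if self.f1 > 1.0:
            raise ValueError(
                f"carrier penetrance grr*f0={self.f1:.3f} exceeds 1"
            )

    @property
    def f1(self) -> float:
        """Carrier penetrance grr * f0."""
        return self.grr * self.f0


#: The five architectures examined in the simulations: GRR 20, 15, 10, 7.5, 5
#: with q = 1e-4 and sporadic rate 0.02 throughout.
MODELS: dict[str, GeneticModel] = {
    name: GeneticModel(name=name, q=1e-4, f0=0.02, grr=grr)
    for name, grr in [("I", 20.0), ("II", 15.0), ("III", 10.0), ("IV", 7.5), ("V", 5.0)]
}


def genotype_frequencies(q: float) -> np.ndarray:
    """Hardy-Weinberg frequencies for genotypes (0, 1, 2 risk alleles)."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def penetrance_vector(model: GeneticModel) -> np.ndarray:
    """Penetrance by genotype (dominant: one copy is enough)."""
    return np.array([model.f0, model.f1, model.f1])


def prevalence(model: GeneticModel) -> float:
    """Population disease prevalence K = sum_g P(g) f(g)."""
    return float(genotype_frequencies(model.q) @ penetrance_vector(model))


def _transmission_matrix(q: float) -> np.ndarray:
    """T[gp, gc] = P(child genotype gc | parent genotype gp), mate from HW.

    The parent transmits a risk allele with probability 0, 1/2 or 1 depending
    on its genotype; the untyped mate contributes one with probability q.
    """
    t_parent = np.array([0.0, 0.5, 1.0])
    out = np.empty((3, 3))
    for gp in range(3):
        a = t_parent[gp]
        out[gp, 0] = (1 - a) * (1 - q)
        out[gp, 1] = a * (1 - q) + (1 - a) * q
        out[gp, 2] = a * q
    return out


def locus_frr(model: GeneticModel) -> float:
    """Locus-specific familial relative risk to first-degree relatives.

    lambda_R = P(offspring affected | parent affected) / K, computed exactly
    from the joint parent-offspring genotype distribution. For rare dominant
    alleles this agrees with the sibling recurrence ratio and with the
    variance-components approximation lambda ~ 1 + V_A / (2 K^2) to printed
    precision.
    """
    hw = genotype_frequencies(model.q)
    f = penetrance_vector(model)
    trans = _transmission_matrix(model.q)
    joint = hw[:, None] * trans  # P(gp, gc)
    k = prevalence(model)
    both_affected = float(f @ joint @ f)
    return both_affected / (k * k)


def num_loci(model: GeneticModel) -> int:
    """Number of loci so the aggregate familial relative risk hits the target.

    Uses the unrounded exact ``locus_frr``; the ratio is rounded to the
    nearest integer.
    """
    lam = locus_frr(model)
    if lam <= 1.0:
        raise ValueError(
            f"model {model.name!r} has no familial effect (lambda={lam!r})"
        )
    return round(math.log(model.frr_total_target) / math.log(lam))
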
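"""Stage-I exome simulation: background variants, true-gene segregation and
the gene-selection filters.

Each sequenced exome carries a fixed load of rare non-disease variants (by
default 400 rare missense, of which a bioinformatics filter passes 30%, and
20 truncating/splice-junction variants, which are not filtered), scattered
uniformly over the genome's genes.  When several relatives are sequenced in
a pedigree, a variant present in one is present in another only through
identity by descent; the joint carrier-set distribution is computed exactly
from the pedigree (see :func:`mpsdesign.pedigree.ibd_carrier_set_distribution`)
and variants are allocated sequentially so that every sequenced individual
keeps its nominal per-exome total.

A true susceptibility gene segregates in a pedigree with the conditional
probability that the index case carries a mutation in that particular gene
given the family's phenotypes; a segregating variant is truncating with
probability ``p_tsj_true``, is detected with the platform sensitivity, and
(if missense) passes the bioinformatics filter with its own pass rate.
Concordance of a true variant among all sequenced members occurs with the
joint carrier probability conditional on the index carrying.

Filters (one or two+ cases per pedigree):

========  =====================================================================
N1RV      all genes with a (concordant, if >=2 sequenced) rare variant
N1TS      all genes with a (concordant) truncating/splice variant
N2RV      genes with RVs in 2+ pedigrees; >=1 pedigree concordant
N2TS      as N2RV, and at least one of the RVs is truncating/splice
N3RV      genes with RVs in 3+ pedigrees; >=1 pedigree concordant
========  =====================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic_models import GeneticModel, num_loci
from .pedigree import (
    Pedigree,
    carrier_probability,
    ibd_carrier_set_distribution,
    joint_carrier_probability,
)

__all__ = [
    "VariantProfile",
    "FilterSpec",
    "FILTERS",
    "FamilyDesign",
    "ModelContext",
    "StageIResult",
    "simulate_background",
    "simulate_true_genes",
    "apply_filter",
    "simulate_replicate",
    "expected_distinct_genes",
]


@dataclass(frozen=True)
class VariantProfile:
    """Genome-wide variant load and filter pass rates per sequenced exome."""

    n_genes: int = 25_000
    n_rms: int = 400
    n_tsj: int = 20
    bioinf_pass_background: float = 0.30
    bioinf_pass_true_missense: float = 0.90
    sensitivity: float = 0.90
    p_tsj_true: float = 0.50
    #: if True, detection failures are drawn independently for each sequenced
    #: relative (affects concordance of true variants); by default the shared
    #: familial variant is detected once per pedigree.
    per_individual_detection: bool = False

    def __post_init__(self) -> None:
        for name in (
            "bioinf_pass_background",
            "bioinf_pass_true_missense",
            "sensitivity",
            "p_tsj_true",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if min(self.n_genes, self.n_rms, self.n_tsj) < 0 or self.n_genes == 0:
            raise ValueError("variant/gene counts must be non-negative (genes > 0)")


@dataclass(frozen=True)
class FilterSpec:
    """One gene-selection filter (see module docstring)."""

    name: str
    min_pedigrees: int
    require_tsj: bool


FILTERS: dict[str, FilterSpec] = {
    "N1RV": FilterSpec("N1RV", 1, False),
    "N1TS": FilterSpec("N1TS", 1, True),
    "N2RV": FilterSpec("N2RV", 2, False),
    "N2TS": FilterSpec("N2TS", 2, True),
    "N3RV": FilterSpec("N3RV", 3, False),
}


class FamilyDesign:
    """Stage-I sampling design: how many pedigrees, who is sequenced.

    Carries the exact IBD carrier-set distributions among the sequenced
    members, pre-processed for sequential variant allocation: the j-th
    sequenced member's novel variants (those carried by no earlier member)
    are shared with later members according to the conditional carrier-set
    distribution given the variant is absent from all earlier members.
    """

    def __init__(self, pedigree: Pedigree, members: Sequence[int], n_pedigrees: int):
        if n_pedigrees < 0:
            raise ValueError("n_pedigrees must be >= 0")
        self.pedigree = pedigree
        self.members = tuple(members)
        self.n_pedigrees = int(n_pedigrees)
        ns = len(self.members)
        self._alloc: list[tuple[np.ndarray, np.ndarray]] = []
        if ns > 1:
            dist = ibd_carrier_set_distribution(pedigree, self.members)
            for j, iid in enumerate(self.members):
                nu = dist[iid]
                masks = np.arange(1 << ns)
                sel = ((masks >> j) & 1 == 1) & (masks & ((1 << j) - 1) == 0)
                masks, probs = masks[sel], nu[sel]
                total = probs.sum()
                if total <= 0:
                    raise ValueError("degenerate carrier-set distribution")
                self._alloc.append((masks, probs / total))

    @property
    def n_sequenced(self) -> int:
        return len(self.members)

    def with_pedigrees(self, n_pedigrees: int) -> "FamilyDesign":
        out = FamilyDesign.__new__(FamilyDesign)
        out.pedigree = self.pedigree
        out.members = self.members
        out.n_pedigrees = int(n_pedigrees)
        out._alloc = self._alloc
        return out

    def allocate_carrier_sets(self, total: int, rng: np.random.Generator) -> np.ndarray:
        """Distinct-variant counts per carrier-set mask for one pedigree.

        Every sequenced member ends up carrying ``total`` variants (up to the
        negligible event that IBD sharing alone overshoots the total).
        Returns an array of length ``2**n_sequenced``.
        """
        ns = self.n_sequenced
        counts = np.zeros(1 << ns, dtype=np.int64)
        if ns == 1:
            counts[1] = total
            return counts
        carried = np.zeros(ns, dtype=np.int64)
        for j in range(ns):
            need = total - carried[j]
            if need <= 0:
                continue
            masks, probs = self._alloc[j]
            draw = rng.multinomial(need, probs)
            for mask, c in zip(masks, draw):
                if not c:
                    continue
                counts[mask] += c
                for i in range(ns):
                    if (mask >> i) & 1:
                        carried[i] += c
        return counts


@dataclass(frozen=True)
class ModelContext:
    """Per-architecture quantities derived from the stage-I pedigree.

    ``p_segregate`` is the per-gene probability that the index case carries a
    mutation in one given susceptibility gene (conditional on the family's
    phenotypes); genes segregate independently across the ``n_loci`` genes.
    ``p_concordant`` is the probability that every other sequenced member
    shares the index's variant, given the index carries it.
    """

    model: GeneticModel
    n_loci: int
    p_segregate: float
    p_concordant: float

    @classmethod
    def from_pedigree(
        cls, model: GeneticModel, pedigree: Pedigree, members: Sequence[int]
    ) -> "ModelContext":
        members = tuple(members)
        index = members[0]
        p_seg = carrier_probability(pedigree, model, index)
        if len(members) > 1:
            p_conc = joint_carrier_probability(
                pedigree, model, list(members[1:]), condition_on=index
            )
        else:
            p_conc = 1.0
        return cls(model, num_loci(model), p_seg, p_conc)


@dataclass(frozen=True)
class VariantTable:
    """Flat per-variant bookkeeping for one replicate.

    One row per (pedigree, variant): the gene it falls in, whether it is
    truncating/splice, and whether it is concordant (carried by every
    sequenced member; vacuously true with one sequenced member).
    """

    ped: np.ndarray
    gene: np.ndarray
    tsj: np.ndarray
    concordant: np.ndarray

    @classmethod
    def empty(cls) -> "VariantTable":
        z = np.empty(0, dtype=np.int64)
        b = np.empty(0, dtype=bool)
        return cls(z, z.copy(), b, b.copy())

    @classmethod
    def from_rows(cls, rows: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]):
        if not rows:
            return cls.empty()
        ped, gene, tsj, conc = (np.concatenate(cols) for cols in zip(*rows))
        return cls(ped, gene, tsj.astype(bool), conc.astype(bool))

    def __len__(self) -> int:
        return self.ped.size


@dataclass(frozen=True)
class StageIResult:
    """Genes passed to stage II by one filter in one replicate."""

    filter_name: str
    true_genes_passed: np.ndarray  # sorted indices among the true loci
    n_false_genes: int

    @property
    def n_true_genes(self) -> int:
        return int(self.true_genes_passed.size)


def simulate_background(
    profile: VariantProfile, design: FamilyDesign, rng: np.random.Generator
) -> VariantTable:
    """Simulate non-disease variants for every pedigree of the design.

    Rare missense variants are thinned by the bioinformatics filter at the
    variant level (a shared variant passes or fails for all carriers);
    truncating/splice variants all pass.
    """
    ns = design.n_sequenced
    full_mask = (1 << ns) - 1
    rows = []
    for p in range(design.n_pedigrees):
        for total, pass_rate, is_tsj in (
            (profile.n_rms, profile.bioinf_pass_background, False),
            (profile.n_tsj, 1.0, True),
        ):
            if total == 0:
                continue
            counts = design.allocate_carrier_sets(total, rng)
            for mask in np.flatnonzero(counts):
                kept = (
                    rng.binomial(counts[mask], pass_rate)
                    if pass_rate < 1.0
                    else int(counts[mask])
                )
                if not kept:
                    continue
                genes = rng.integers(0, profile.n_genes, size=kept)
                rows.append(
                    (
                        np.full(kept, p),
                        genes,
                        np.full(kept, is_tsj),
                        np.full(kept, mask == full_mask),
                    )
                )
    return VariantTable.from_rows(rows)


def simulate_true_genes(
    ctx: ModelContext,
    profile: VariantProfile,
    design: FamilyDesign,
    rng: np.random.Generator,
) -> VariantTable:
    """Simulate detected, filter-passing true-gene variants per pedigree.

    Gene indices run over ``0 .. ctx.n_loci - 1`` (the true susceptibility
    genes); a variant row appears only if the familial variant was detected
    and survived the bioinformatics filter in the index case.
    """
    ns = design.n_sequenced
    rows = []
    for p in range(design.n_pedigrees):
        k = rng.binomial(ctx.n_loci, ctx.p_segregate)
        if not k:
            continue
        genes = rng.choice(ctx.n_loci, size=k, replace=False)
        tsj = rng.random(k) < profile.p_tsj_true
        detected = rng.random(k) < profile.sensitivity
        passed = tsj | (rng.random(k) < profile.bioinf_pass_true_missense)
        qualifying = detected & passed
        if ns > 1:
            conc = rng.random(k) < ctx.p_concordant
            if profile.per_individual_detection:
                conc &= rng.random(k) < profile.sensitivity ** (ns - 1)
        else:
            conc = np.ones(k, dtype=bool)
        if qualifying.any():
            rows.append(
                (
                    np.full(int(qualifying.sum()), p),
                    genes[qualifying],
                    tsj[qualifying],
                    conc[qualifying],
                )
            )
    return VariantTable.from_rows(rows)


def _passing_genes(table: VariantTable, spec: FilterSpec, n_sequenced: int) -> np.ndarray:
    """Sorted gene indices passing one filter, from a variant table."""
    if len(table) == 0:
        return np.empty(0, dtype=np.int64)
    if spec.min_pedigrees == 1:
        ok = table.concordant.copy()
        if spec.require_tsj:
            ok &= table.tsj
        return np.unique(table.gene[ok])
    # per-gene pedigree counts over distinct (gene, pedigree) pairs
    n_ped = int(table.ped.max()) + 1
    key = table.gene * n_ped + table.ped
    uniq_pairs = np.unique(key)
    gene_of_pair = uniq_pairs // n_ped
    genes, ped_counts = np.unique(gene_of_pair, return_counts=True)
    order = np.searchsorted(genes, table.gene)
    conc_any = np.zeros(genes.size, dtype=bool)
    np.logical_or.at(conc_any, order, table.concordant)
    keep = ped_counts >= spec.min_pedigrees
    keep &= conc_any  # vacuous for one sequenced member (all concordant)
    if spec.require_tsj:
        tsj_any = np.zeros(genes.size, dtype=bool)
        np.logical_or.at(tsj_any, order, table.tsj)
        keep &= tsj_any
    return genes[keep]


def apply_filter(
    spec: FilterSpec,
    background: VariantTable,
    true_genes: VariantTable,
    n_sequenced: int,
) -> StageIResult:
    """Apply one gene-selection filter to a replicate's variant tables.

    True and false genes are counted separately: a true gene passes on the
    strength of its own segregating variants, and every passing background
    gene counts as false (cross-talk between the two — a background variant
    landing in a true gene — is ignored, as its probability per gene and
    pedigree is of order 1e-4).
    """
    false_passed = _passing_genes(background, spec, n_sequenced)
    true_passed = _passing_genes(true_genes, spec, n_sequenced)
    return StageIResult(spec.name, true_passed, int(false_passed.size))


def simulate_replicate(
    ctx: ModelContext,
    profile: VariantProfile,
    design: FamilyDesign,
    rng: np.random.Generator,
    filters: Iterable[FilterSpec | str] = tuple(FILTERS),
) -> dict[str, StageIResult]:
    """One full stage-I replicate evaluated under several filters at once."""
    specs = [FILTERS[f] if isinstance(f, str) else f for f in filters]
    background = simulate_background(profile, design, rng)
    true_table = simulate_true_genes(ctx, profile, design, rng)
    return {
        s.name: apply_filter(s, background, true_table, design.n_sequenced)
        for s in specs
    }


def expected_distinct_genes(n_variants: float, n_genes: int = 25_000) -> float:
    """Expected number of distinct genes hit by M variants thrown uniformly
    at ``n_genes`` genes: G (1 - (1 - 1/G)**M)."""
    return n_genes * (1.0 - (1.0 - 1.0 / n_genes) ** n_variants)
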
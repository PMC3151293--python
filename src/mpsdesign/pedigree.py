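"""Pedigrees and exact single-locus probability computations.

This module supplies the machinery that family-based sequencing designs need
from a pedigree: the conditional probability that a member carries a rare risk
allele given everyone's affection status (computed exactly by peeling /
variable elimination over the three-genotype single-locus model), joint
carrier probabilities for concordance arguments, kinship-based IBD sharing of
neutral rare variants between relatives, and the closed-form fraction of
irrelevant variants removed by requiring concordance between two relatives of
degree D:

    excluded = (2**(D+1) - 2) / (2**(D+1) - 1)

Pedigree files use the whitespace-delimited LINKAGE pre-makeped layout
(family, id, father, mother, sex, affection) with ``0`` for a missing parent
and affection coded 2 = affected, 1 = unaffected, 0 = unknown.  An optional
seventh column flags the members analysed by sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic_models import GeneticModel, genotype_frequencies

__all__ = [
    "AFFECTED",
    "UNAFFECTED",
    "UNKNOWN",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "read_ped",
    "write_ped",
    "kinship",
    "pairwise_sharing_probability",
    "background_retention",
    "genotype_posterior",
    "carrier_probability",
    "joint_carrier_probability",
    "ibd_carrier_set_distribution",
    "concordance_exclusion",
]

UNKNOWN = 0
UNAFFECTED = 1
AFFECTED = 2


class PedigreeError(ValueError):
    """Raised for malformed pedigree structures or files."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member (LINKAGE conventions: 0 = missing parent)."""

    id: int
    father_id: int = 0
    mother_id: int = 0
    sex: int = 1
    affection: int = UNKNOWN
    sequenced: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id == 0 and self.mother_id == 0


class Pedigree:
    """An ordered collection of individuals forming one family.

    Invariants (checked on construction): ids are unique and positive, each
    member has either both parents in the pedigree or none, no individual is
    its own ancestor.
    """

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = str(family_id)
        self.members: list[Individual] = list(members)
        self._by_id: dict[int, Individual] = {}
        for ind in self.members:
            if ind.id <= 0:
                raise PedigreeError(f"non-positive individual id {ind.id}")
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id}")
            self._by_id[ind.id] = ind
        self._validate()

    # -- basic structure ---------------------------------------------------

    def _validate(self) -> None:
        for ind in self.members:
            if (ind.father_id == 0) != (ind.mother_id == 0):
                raise PedigreeError(
                    f"individual {ind.id}: one parent missing "
                    f"(father={ind.father_id}, mother={ind.mother_id})"
                )
            for pid, label in ((ind.father_id, "father"), (ind.mother_id, "mother")):
                if pid and pid not in self._by_id:
                    raise PedigreeError(
                        f"individual {ind.id}: {label} {pid} not in pedigree"
                    )
            if ind.father_id and self[ind.father_id].sex != 1:
                raise PedigreeError(f"father {ind.father_id} of {ind.id} is not male")
            if ind.mother_id and self[ind.mother_id].sex != 2:
                raise PedigreeError(f"mother {ind.mother_id} of {ind.id} is not female")
        # acyclicity via depth computation
        self._depth: dict[int, int] = {}
        for ind in self.members:
            self._compute_depth(ind.id, visiting=set())

    def _compute_depth(self, iid: int, visiting: set[int]) -> int:
        if iid in self._depth:
            return self._depth[iid]
        if iid in visiting:
            raise PedigreeError(f"individual {iid} is its own ancestor")
        visiting.add(iid)
        ind = self[iid]
        if ind.is_founder:
            d = 0
        else:
            d = 1 + max(
                self._compute_depth(ind.father_id, visiting),
                self._compute_depth(ind.mother_id, visiting),
            )
        visiting.discard(iid)
        self._depth[iid] = d
        return d

    def __getitem__(self, iid: int) -> Individual:
        return self._by_id[iid]

    def __contains__(self, iid: int) -> bool:
        return iid in self._by_id

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Pedigree)
            and self.family_id == other.family_id
            and self.members == other.members
        )

    @property
    def ids(self) -> list[int]:
        return [ind.id for ind in self.members]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.members if ind.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.members if not ind.is_founder]

    @property
    def sequenced_ids(self) -> list[int]:
        return [ind.id for ind in self.members if ind.sequenced]

    def depth(self, iid: int) -> int:
        """Generation depth (founders have depth 0)."""
        return self._depth[iid]

    def topological_order(self) -> list[int]:
        """Member ids ordered so parents always precede children."""
        return sorted(self.ids, key=lambda i: (self._depth[i], i))

    def with_affections(self, affection: Mapping[int, int]) -> "Pedigree":
        """Copy of the pedigree with some affection statuses replaced."""
        members = [
            replace(ind, affection=affection.get(ind.id, ind.affection))
            for ind in self.members
        ]
        return Pedigree(self.family_id, members)


# -- LINKAGE pre-makeped file I/O -----------------------------------------


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read pedigrees from a LINKAGE pre-makeped file.

    Columns: family id father mother sex affection [sequenced].  Errors are
    reported with their line number.
    """
    path = Path(path)
    rows: dict[str, list[Individual]] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (6, 7):
            raise PedigreeError(
                f"{path.name}:{lineno}: expected 6 or 7 columns, got {len(fields)}"
            )
        try:
            fam = fields[0]
            iid, father, mother, sex, aff = (int(x) for x in fields[1:6])
            seq = bool(int(fields[6])) if len(fields) == 7 else False
        except ValueError as exc:
            raise PedigreeError(f"{path.name}:{lineno}: {exc}") from None
        if sex not in (1, 2):
            raise PedigreeError(f"{path.name}:{lineno}: unknown sex code {sex}")
        if aff not in (UNKNOWN, UNAFFECTED, AFFECTED):
            raise PedigreeError(f"{path.name}:{lineno}: unknown affection code {aff}")
        if fam not in rows:
            rows[fam] = []
            order.append(fam)
        rows[fam].append(
            Individual(iid, father, mother, sex, aff, sequenced=seq)
        )
    pedigrees = []
    for fam in order:
        try:
            pedigrees.append(Pedigree(fam, rows[fam]))
        except PedigreeError as exc:
            raise PedigreeError(f"{path.name}: family {fam}: {exc}") from None
    return pedigrees


def write_ped(pedigrees: Sequence[Pedigree], path: str | Path) -> None:
    """Write pedigrees in pre-makeped layout (round-trips with read_ped)."""
    lines = []
    for ped in pedigrees:
        for ind in ped.members:
            lines.append(
                f"{ped.family_id} {ind.id} {ind.father_id} {ind.mother_id} "
                f"{ind.sex} {ind.affection} {int(ind.sequenced)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# -- kinship and IBD sharing ----------------------------------------------


def kinship(ped: Pedigree, a: int, b: int) -> float:
    """Kinship coefficient between members a and b (standard recursion)."""
    cache: dict[tuple[int, int], float] = {}

    def phi(x: int, y: int) -> float:
        if ped.depth(x) < ped.depth(y):
            x, y = y, x
        key = (x, y) if x >= y else (y, x)
        if key in cache:
            return cache[key]
        ix = ped[x]
        if x == y:
            val = 0.5 * (1.0 + (phi(ix.father_id, ix.mother_id) if not ix.is_founder else 0.0))
        elif ix.is_founder:
            # after the depth swap both are founders here: unrelated
            val = 0.0
        else:
            # x is at least as deep as y, so x cannot be y's ancestor
            val = 0.5 * (phi(ix.father_id, y) + phi(ix.mother_id, y))
        cache[key] = val
        return val

    return phi(a, b)


def pairwise_sharing_probability(ped: Pedigree, a: int, b: int) -> float:
    """P(a rare variant carried by ``a`` is carried identical-by-descent
    by ``b``); equals twice the kinship coefficient for outbred pairs."""
    if a == b:
        raise ValueError("a and b must differ")
    return 2.0 * kinship(ped, a, b)


def background_retention(degree: int) -> float:
    """Fraction of the union of two relatives' neutral variants that is
    concordant: 1 / (2**(D+1) - 1) for relationship degree D >= 1."""
    if degree < 1:
        raise ValueError("degree of relationship must be >= 1")
    return 1.0 / (2 ** (degree + 1) - 1)


# -- exact genotype posteriors (Elston-Stewart peeling as variable
#    elimination over the pedigree's genotype network) ---------------------


def _mendel_table() -> np.ndarray:
    """M[gf, gm, gc]: child genotype distribution given parents'."""
    a = np.array([0.0, 0.5, 1.0])  # P(transmit risk allele | genotype)
    m = np.empty((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf, pm = a[gf], a[gm]
            m[gf, gm, 0] = (1 - pf) * (1 - pm)
            m[gf, gm, 1] = pf * (1 - pm) + (1 - pf) * pm
            m[gf, gm, 2] = pf * pm
    return m


_MENDEL = _mendel_table()


def evidence_vector(affection: int, model: GeneticModel) -> np.ndarray:
    """Phenotype likelihood by genotype; unknown phenotypes contribute 1."""
    if affection == AFFECTED:
        return np.array([model.f0, model.f1, model.f1])
    if affection == UNAFFECTED:
        return np.array([1 - model.f0, 1 - model.f1, 1 - model.f1])
    return np.ones(3)


def _factors(ped: Pedigree, model: GeneticModel) -> list[tuple[tuple[int, ...], np.ndarray]]:
    hw = genotype_frequencies(model.q)
    fs = []
    for ind in ped.members:
        ev = evidence_vector(ind.affection, model)
        if ind.is_founder:
            fs.append(((ind.id,), hw * ev))
        else:
            fs.append(
                ((ind.father_id, ind.mother_id, ind.id), _MENDEL * ev[None, None, :])
            )
    return fs


def _product(factors: list[tuple[tuple[int, ...], np.ndarray]]) -> tuple[tuple[int, ...], np.ndarray]:
    """Multiply factors over the union of their (genotype) variables."""
    vars_out: list[int] = []
    for fv, _ in factors:
        for v in fv:
            if v not in vars_out:
                vars_out.append(v)
    arr = np.ones((3,) * len(vars_out))
    for fv, fa in factors:
        idx = np.array([vars_out.index(v) for v in fv])
        # order factor axes by their position in the union, then broadcast
        expand = np.transpose(fa, axes=np.argsort(idx)) if len(fv) > 1 else fa
        shape = [1] * len(vars_out)
        for pos in idx:
            shape[pos] = 3
        arr = arr * expand.reshape(shape)
    return tuple(vars_out), arr


def _joint_distribution(
    ped: Pedigree, model: GeneticModel, keep: Sequence[int]
) -> tuple[tuple[int, ...], np.ndarray]:
    """Unnormalised joint genotype distribution over ``keep`` given all
    phenotypes, by greedy variable elimination (exact for any pedigree)."""
    for iid in keep:
        if iid not in ped:
            raise KeyError(f"individual {iid} not in pedigree {ped.family_id}")
    factors = _factors(ped, model)
    to_eliminate = [i for i in ped.ids if i not in set(keep)]
    while to_eliminate:
        # greedy: eliminate the variable whose combined factor is smallest
        best_v, best_scope = None, None
        for v in to_eliminate:
            scope: set[int] = set()
            for fv, _ in factors:
                if v in fv:
                    scope |= set(fv)
            if best_scope is None or len(scope) < len(best_scope):
                best_v, best_scope = v, scope
        v = best_v
        involved = [f for f in factors if v in f[0]]
        rest = [f for f in factors if v not in f[0]]
        pv, pa = _product(involved)
        pa = pa.sum(axis=pv.index(v))
        pv = tuple(x for x in pv if x != v)
        rest.append((pv, pa))
        factors = rest
        to_eliminate.remove(v)
    pv, pa = _product(factors)
    # reorder axes to match `keep`
    order = [pv.index(k) for k in keep]
    return tuple(keep), np.transpose(pa, axes=order) if len(pv) > 1 else pa


def genotype_posterior(ped: Pedigree, model: GeneticModel, person: int) -> np.ndarray:
    """P(genotype of ``person`` | all affection statuses); sums to 1."""
    _, arr = _joint_distribution(ped, model, [person])
    total = arr.sum()
    if total <= 0:
        raise ValueError("pedigree phenotypes have zero likelihood under model")
    return arr / total


def carrier_probability(ped: Pedigree, model: GeneticModel, person: int) -> float:
    """P(``person`` carries >= 1 risk allele | all affection statuses)."""
    post = genotype_posterior(ped, model, person)
    return float(post[1] + post[2])


def joint_carrier_probability(
    ped: Pedigree,
    model: GeneticModel,
    persons: Sequence[int],
    condition_on: int | None = None,
) -> float:
    """P(every listed person carries | phenotypes).

    With ``condition_on`` set, returns the probability that all ``persons``
    carry given that the designated individual carries (the "allele
    segregating in the family" sense used for concordance of true variants).
    """
    persons = list(dict.fromkeys(persons))
    keep = persons + ([condition_on] if condition_on is not None and condition_on not in persons else [])
    _, arr = _joint_distribution(ped, model, keep)
    carrier_mass = np.zeros((3,) * len(keep))
    carrier = np.array([0.0, 1.0, 1.0])
    mask = np.ones((3,) * len(keep))
    for axis, iid in enumerate(keep):
        if iid in persons or iid == condition_on:
            shape = [1] * len(keep)
            shape[axis] = 3
            mask = mask * carrier.reshape(shape)
    numerator = float((arr * mask).sum())
    if condition_on is None:
        denom = float(arr.sum())
    else:
        axis = keep.index(condition_on)
        cond_mask = np.ones((3,) * len(keep))
        shape = [1] * len(keep)
        shape[axis] = 3
        cond_mask = cond_mask * carrier.reshape(shape)
        denom = float((arr * cond_mask).sum())
    if denom <= 0:
        raise ValueError("conditioning event has zero probability")
    return numerator / denom


# -- IBD carrier-set distributions via inheritance-vector enumeration ------


def _founder_allele_labels(
    ped: Pedigree, max_meioses: int = 11
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Founder-allele origin labels for every member under all inheritance
    vectors.

    Returns, for each member id, a pair of integer arrays (paternal allele
    origin, maternal allele origin) of length 2**(2*M) where M is the number
    of non-founders; entry k gives the founder-allele label inherited under
    the k-th equally likely inheritance vector.
    """
    nonfounders = [ind.id for ind in ped.nonfounders]
    m = len(nonfounders)
    if m > max_meioses:
        raise PedigreeError(
            f"pedigree too large for exact IBD enumeration ({m} non-founders)"
        )
    n_vec = 1 << (2 * m)
    bit = {iid: 2 * j for j, iid in enumerate(nonfounders)}
    k = np.arange(n_vec)
    labels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    next_label = 0
    for iid in ped.topological_order():
        ind = ped[iid]
        if ind.is_founder:
            pat = np.full(n_vec, next_label)
            mat = np.full(n_vec, next_label + 1)
            next_label += 2
        else:
            fpat, fmat = labels[ind.father_id]
            mpat, mmat = labels[ind.mother_id]
            bsel_f = (k >> bit[iid]) & 1
            bsel_m = (k >> (bit[iid] + 1)) & 1
            pat = np.where(bsel_f == 0, fpat, fmat)
            mat = np.where(bsel_m == 0, mpat, mmat)
        labels[iid] = (pat, mat)
    return labels


def ibd_carrier_set_distribution(
    ped: Pedigree, members: Sequence[int] | None = None
) -> dict[int, np.ndarray]:
    """Distribution of the IBD carrier set of a rare variant among selected
    members, given the variant is carried by one of them.

    For each id ``i`` in ``members`` (default: the sequenced members), the
    returned array ``p`` has length ``2**len(members)`` and ``p[mask]`` is the
    probability that a rare variant carried by ``i`` is carried exactly by the
    members flagged in ``mask`` (bit j = members[j]); masks always include
    ``i``'s own bit.  Exact, by enumeration of all inheritance vectors; rare
    variants are assumed to recur only by descent.
    """
    ids = list(members) if members is not None else ped.sequenced_ids
    if not ids:
        raise ValueError("no members given and none flagged as sequenced")
    labels = _founder_allele_labels(ped)
    n_vec = len(labels[ids[0]][0])
    out: dict[int, np.ndarray] = {}
    for i, iid in enumerate(ids):
        acc = np.zeros(1 << len(ids))
        for allele in labels[iid]:
            mask = np.zeros(n_vec, dtype=np.int64)
            for j, jid in enumerate(ids):
                pat, mat = labels[jid]
                mask |= ((pat == allele) | (mat == allele)).astype(np.int64) << j
            acc += np.bincount(mask, minlength=1 << len(ids)) / n_vec
        out[iid] = acc / 2.0
    return out


def concordance_exclusion(ped: Pedigree, members: Sequence[int]) -> float:
    """Fraction of the union of the members' neutral variants eliminated by
    requiring every member to carry the variant.

    Each member carries the same expected number of background variants; the
    expected union is accumulated member by member (counting only variants
    carried by no earlier member) and compared with the expected fully
    concordant count.  For two relatives of degree D this reduces to the
    closed form (2**(D+1) - 2) / (2**(D+1) - 1).
    """
    ids = list(members)
    if len(ids) < 2:
        raise ValueError("need at least two members")
    dist = ibd_carrier_set_distribution(ped, ids)
    union = 0.0
    for j, iid in enumerate(ids):
        nu = dist[iid]
        masks = np.arange(nu.size)
        union += nu[(masks & ((1 << j) - 1)) == 0].sum()
    concordant = dist[ids[0]][(1 << len(ids)) - 1]
    return 1.0 - concordant / union
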
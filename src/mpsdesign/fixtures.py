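"""Shipped pedigree fixtures and random-pedigree generation.

Two reference families drive the simulations:

* :func:`fig1a` — the stage-I "very high-risk" pedigree. Three generations,
  eleven members; the sequenced affected members are the index case (ID 8),
  his first cousin (ID 11) and their aunt (ID 5, a sibling of both cousins'
  blood parents). One individual is sequenced per family when the design
  sequences one (ID 8), two (IDs 8 and 11), or three (IDs 8, 5 and 11).
* :func:`fig1b` — the stage-II pedigree with a more modest family history
  (index case plus an affected parent and an affected cousin); only ID 8 is
  analysed.

The affection-status readings were calibrated against the published anchor
probabilities (cousin sharing of a segregating allele ~0.73 and three-way
sharing ~0.67 under the GRR-15 architecture; stage-II index carrier
probabilities ~0.061/0.040/0.019/0.011/0.005 across the five architectures),
since the pedigrees themselves are available only as a drawing.  If the
drawing is read differently the fixture files — not the algorithms — are
what should change.

Both pedigrees are also installed as ``data/fig1a.ped`` / ``data/fig1b.ped``
in LINKAGE pre-makeped format (regenerate with ``python -m
mpsdesign.fixtures``).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .pedigree import AFFECTED, UNAFFECTED, UNKNOWN, Individual, Pedigree

__all__ = ["fig1a", "fig1b", "fixture_path", "make_random_pedigree"]

# (id, father, mother, sex, affection, sequenced)
_FIG1A_ROWS = [
    (1, 0, 0, 1, AFFECTED, False),
    (2, 0, 0, 2, UNKNOWN, False),
    (3, 1, 2, 1, UNKNOWN, False),
    (4, 0, 0, 2, AFFECTED, False),
    (5, 1, 2, 2, AFFECTED, True),
    (6, 1, 2, 2, UNAFFECTED, False),
    (7, 0, 0, 1, AFFECTED, False),
    (8, 3, 4, 1, AFFECTED, True),
    (9, 3, 4, 2, UNAFFECTED, False),
    (10, 7, 6, 1, UNAFFECTED, False),
    (11, 7, 6, 2, AFFECTED, True),
]

_FIG1B_ROWS = [
    (1, 0, 0, 1, UNKNOWN, False),
    (2, 0, 0, 2, UNAFFECTED, False),
    (3, 1, 2, 1, AFFECTED, False),
    (4, 0, 0, 2, UNAFFECTED, False),
    (5, 1, 2, 2, UNAFFECTED, False),
    (6, 1, 2, 2, UNAFFECTED, False),
    (7, 0, 0, 1, UNAFFECTED, False),
    (8, 3, 4, 1, AFFECTED, True),
    (9, 3, 4, 2, UNAFFECTED, False),
    (10, 7, 6, 1, UNAFFECTED, False),
    (11, 7, 6, 2, AFFECTED, False),
]


def _build(family_id: str, rows) -> Pedigree:
    return Pedigree(
        family_id,
        [Individual(i, f, m, s, a, sequenced=q) for i, f, m, s, a, q in rows],
    )


def fig1a() -> Pedigree:
    """The stage-I high-risk pedigree (sequenced members 8, 5, 11)."""
    return _build("FIG1A", _FIG1A_ROWS)


def fig1b() -> Pedigree:
    """The stage-II pedigree (index case 8 analysed)."""
    return _build("FIG1B", _FIG1B_ROWS)


def fixture_path(name: str) -> Path:
    """Filesystem path of an installed fixture file, e.g. ``"fig1a.ped"``."""
    return Path(resources.files("mpsdesign").joinpath("data", name))


def make_random_pedigree(
    n_members: int, rng: np.random.Generator, family_id: str = "RAND"
) -> Pedigree:
    """Random valid pedigree for property tests (peeling vs enumeration).

    Grows the family one member at a time: each new member is either a
    founder or, when a potential couple exists, a child of a random
    male/female pair among existing members.  Parent ids always precede
    child ids, so the result is acyclic by construction.  Affection statuses
    are uniform over affected / unaffected / unknown.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    members: list[Individual] = []
    males: list[int] = []
    females: list[int] = []
    for iid in range(1, n_members + 1):
        sex = int(rng.integers(1, 3))
        affection = int(rng.integers(0, 3))
        father = mother = 0
        if males and females and rng.random() < 0.6:
            father = int(rng.choice(males))
            mother = int(rng.choice(females))
        members.append(Individual(iid, father, mother, sex, affection))
        (males if sex == 1 else females).append(iid)
    return Pedigree(family_id, members)


def _regenerate() -> None:
    from .pedigree import write_ped

    out = Path(__file__).parent / "data"
    out.mkdir(exist_ok=True)
    write_ped([fig1a()], out / "fig1a.ped")
    write_ped([fig1b()], out / "fig1b.ped")


if __name__ == "__main__":
    _regenerate()
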
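"""Replicate driver: evaluate (model, filter, N_p, N_s) design cells.

Each cell is simulated for ``n_replicates`` independent stage-I replicates;
the numbers of true and false genes passed to stage II and the total study
cost are averaged across replicates.  Results are bit-identical for a given
seed and do not depend on the order in which cells are evaluated: every
(model, N_p, N_s, replicate) combination derives its generator from the seed
and its own coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cost import CostModel, study_cost
from .fixtures import fig1a
from .genetic_models import MODELS, GeneticModel
from .pedigree import Pedigree
from .stage1 import (
    FILTERS,
    FamilyDesign,
    ModelContext,
    VariantProfile,
    simulate_replicate,
)

__all__ = [
    "SEQUENCED_BY_DESIGN",
    "DesignCell",
    "default_grid",
    "make_design",
    "run_grid",
    "false_genes_by_filter",
]

#: Which members of the stage-I pedigree are sequenced for each design size
#: (index case first; then the first cousin; then the aunt).
SEQUENCED_BY_DESIGN: dict[int, tuple[int, ...]] = {1: (8,), 2: (8, 11), 3: (8, 5, 11)}


@dataclass(frozen=True)
class DesignCell:
    model: str
    filter: str
    n_pedigrees: int
    n_sequenced: int

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r} (have {sorted(MODELS)})")
        if self.filter not in FILTERS:
            raise ValueError(f"unknown filter {self.filter!r} (have {sorted(FILTERS)})")
        if self.n_sequenced not in SEQUENCED_BY_DESIGN:
            raise ValueError("n_sequenced must be 1, 2 or 3")
        if self.n_pedigrees < 0:
            raise ValueError("n_pedigrees must be >= 0")


def default_grid(
    models: tuple[str, ...] = tuple(MODELS),
    filters: tuple[str, ...] = tuple(FILTERS),
    n_pedigrees: tuple[int, ...] = (10, 20, 30, 40, 60, 80),
    n_sequenced: tuple[int, ...] = (1, 2, 3),
) -> list[DesignCell]:
    """The full factorial design grid (overridable per axis)."""
    return [
        DesignCell(m, f, np_, ns)
        for m, f, np_, ns in itertools.product(models, filters, n_pedigrees, n_sequenced)
    ]


def make_design(
    n_pedigrees: int, n_sequenced: int, pedigree: Pedigree | None = None
) -> FamilyDesign:
    """Stage-I family design on the shipped high-risk pedigree (or a custom
    one with the same member ids)."""
    ped = pedigree if pedigree is not None else fig1a()
    return FamilyDesign(ped, SEQUENCED_BY_DESIGN[n_sequenced], n_pedigrees)


def _replicate_rng(seed: int, model_idx: int, n_ped: int, ns: int, rep: int):
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(model_idx, n_ped, ns, rep))
    return np.random.default_rng(ss)


def run_grid(
    cells: list[DesignCell],
    seed: int,
    n_replicates: int = 100,
    profile: VariantProfile | None = None,
    cost_model: CostModel | None = None,
    pedigree: Pedigree | None = None,
) -> pd.DataFrame:
    """Evaluate design cells; one row per cell.

    Columns: mean/sd of true and false gene counts, mean study cost, and the
    proportion of the architecture's true genes recovered.
    """
    profile = profile if profile is not None else VariantProfile()
    cost_model = cost_model if cost_model is not None else CostModel()
    model_order = {name: i for i, name in enumerate(MODELS)}

    # group cells sharing the same simulations (model, N_p, N_s)
    groups: dict[tuple[str, int, int], list[DesignCell]] = {}
    for cell in cells:
        groups.setdefault((cell.model, cell.n_pedigrees, cell.n_sequenced), []).append(cell)

    records = []
    ctx_cache: dict[tuple[str, int], ModelContext] = {}
    design_cache: dict[tuple[int, int], FamilyDesign] = {}
    for (model_name, n_ped, ns), members in sorted(
        groups.items(), key=lambda kv: (model_order[kv[0][0]], kv[0][1], kv[0][2])
    ):
        if (ns, n_ped) not in design_cache:
            base = design_cache.get((ns, -1))
            if base is None:
                base = make_design(n_ped, ns, pedigree)
                design_cache[(ns, -1)] = base
            design_cache[(ns, n_ped)] = base.with_pedigrees(n_ped)
        design = design_cache[(ns, n_ped)]
        if (model_name, ns) not in ctx_cache:
            ctx_cache[(model_name, ns)] = ModelContext.from_pedigree(
                MODELS[model_name], design.pedigree, design.members
            )
        ctx = ctx_cache[(model_name, ns)]
        filter_names = sorted({c.filter for c in members})
        tallies = {f: [] for f in filter_names}
        for rep in range(n_replicates):
            rng = _replicate_rng(seed, model_order[model_name], n_ped, ns, rep)
            results = simulate_replicate(ctx, profile, design, rng, filter_names)
            for f in filter_names:
                r = results[f]
                tallies[f].append((r.n_true_genes, r.n_false_genes))
        for cell in members:
            arr = np.array(tallies[cell.filter], dtype=float).reshape(-1, 2)
            n_true, n_false = arr[:, 0], arr[:, 1]
            costs = [
                study_cost(n_ped, ns, t + fgenes, cost_model)
                for t, fgenes in zip(n_true, n_false)
            ]
            records.append(
                {
                    "model": cell.model,
                    "filter": cell.filter,
                    "n_pedigrees": n_ped,
                    "n_sequenced": ns,
                    "n_replicates": n_replicates,
                    "mean_true": n_true.mean() if len(arr) else 0.0,
                    "sd_true": n_true.std(ddof=1) if len(arr) > 1 else 0.0,
                    "mean_false": n_false.mean() if len(arr) else 0.0,
                    "sd_false": n_false.std(ddof=1) if len(arr) > 1 else 0.0,
                    "mean_cost": float(np.mean(costs)) if costs else 0.0,
                    "proportion_true": (n_true.mean() / ctx.n_loci) if len(arr) else 0.0,
                }
            )
    return pd.DataFrame(records)


def false_genes_by_filter(grid: pd.DataFrame) -> pd.DataFrame:
    """False-gene means averaged across disease models (they share the same
    background-variant process), pivoted filter x (N_s, N_p)."""
    return (
        grid.groupby(["filter", "n_sequenced", "n_pedigrees"])["mean_false"]
        .mean()
        .unstack("n_pedigrees")
        .reset_index()
    )
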
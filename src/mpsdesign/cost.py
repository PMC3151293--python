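"""Study cost: stage-I exome sequencing plus stage-II per-gene screening.

total = exome_cost * N_p * N_s + gene_screen_cost * n_stage2_samples * n_genes

with N_p stage-I pedigrees, N_s sequenced individuals per pedigree, and
``n_genes`` genes (true + false) carried into stage II.  At the defaults
($4000 per exome, $10 per gene per screened sample, 250 stage-II samples)
one exome costs 400 times one candidate-gene screen.  Fractional gene counts
(replicate averages) are costed as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CostModel", "study_cost"]


@dataclass(frozen=True)
class CostModel:
    exome_cost: float = 4000.0
    gene_screen_cost: float = 10.0
    n_stage2_samples: int = 250

    def __post_init__(self) -> None:
        if min(self.exome_cost, self.gene_screen_cost, self.n_stage2_samples) <= 0:
            raise ValueError("all cost constants must be positive")


def study_cost(
    n_pedigrees: int,
    n_sequenced_per_ped: int,
    n_genes_stage2: float,
    cost_model: CostModel | None = None,
) -> float:
    """Total study cost in currency units (USD at the default constants)."""
    cm = cost_model if cost_model is not None else CostModel()
    if n_pedigrees < 0 or n_sequenced_per_ped < 0 or n_genes_stage2 < 0:
        raise ValueError("cost inputs must be non-negative")
    stage1 = cm.exome_cost * n_pedigrees * n_sequenced_per_ped
    stage2 = cm.gene_screen_cost * cm.n_stage2_samples * n_genes_stage2
    return stage1 + stage2
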
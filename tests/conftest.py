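import itertools

import numpy as np
import pytest

from mpsdesign import pedigree as ped_mod
from mpsdesign.genetic_models import genotype_frequencies


def brute_force_joint(ped, model, keep):
    """Exhaustive-enumeration oracle for conditional genotype distributions.

    Sums the full likelihood over all 3**n genotype vectors and marginalises
    onto ``keep``; independent of the peeling/elimination code path.
    """
    hw = genotype_frequencies(model.q)
    idx = {iid: k for k, iid in enumerate(ped.ids)}
    out = np.zeros((3,) * len(keep))
    for g in itertools.product(range(3), repeat=len(ped)):
        p = 1.0
        for ind in ped.members:
            gi = g[idx[ind.id]]
            p *= ped_mod.evidence_vector(ind.affection, model)[gi]
            if ind.is_founder:
                p *= hw[gi]
            else:
                p *= ped_mod._MENDEL[
                    g[idx[ind.father_id]], g[idx[ind.mother_id]], gi
                ]
        out[tuple(g[idx[k]] for k in keep)] += p
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
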
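"""Headline quantities recomputed end to end from the package itself.

Used by ``scripts/acceptance.py`` and the ``persistlin reproduce`` CLI verb.
Every number is produced by running the pipeline at call time: the printed-
counts fixture is summarized with :func:`summary_counts`, and the M3
variance-to-mean ratio comes from fresh Luria-Delbrück simulations.
"""

from __future__ import annotations

import json

from .lineage import summary_counts
from .linstats import binomial_null_vmr, ld_test
from .synth import hct116_config, table_one_fixture

__all__ = ["run_targets"]


def run_targets(seed: int = 0, ld_reps: int = 100) -> dict:
    """Recompute the headline quantities; returns {name: {value, n}}.

    t1  percent of drug-time cells in the printed-counts fixture whose
        sub-lineage fully dies (deaths plus both-died daughter pairs).
    t2  binomial-null VMR, 1 - p, at that fixture's persister fraction.
    t3  the persister fraction p itself.
    t4  mean VMR of per-lineage persister counts over ``ld_reps``
        independent M3 simulations of the HCT116-like recipe
        (symmetric 9e-3/h state transitions, state-conditioned fate matrix,
        49 founders, one-random-daughter end fates).
    """
    fixture = table_one_fixture()
    counts = summary_counts(fixture)
    death_frac = counts.death_fraction
    persister_frac = counts.persister_fraction

    cfg = hct116_config()
    ld = ld_test(cfg, n_reps=ld_reps, seed=seed)

    return {
        "t1": {"value": round(100.0 * death_frac, 2), "n": counts.n_at_drug},
        "t2": {
            "value": round(binomial_null_vmr(persister_frac), 4),
            "n": counts.n_at_drug,
        },
        "t3": {"value": round(persister_frac, 4), "n": counts.n_at_drug},
        "t4": {"value": round(ld.mean_vmr, 4), "n": ld_reps},
    }


def write_targets(path, seed: int = 0, ld_reps: int = 100) -> dict:
    out = run_targets(seed=seed, ld_reps=ld_reps)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
    return out
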
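"""Synthetic time-lapse datasets with known ground truth.

Two recipes emulate the structure of the published colon-cancer (HCT116)
and osteosarcoma (U2OS) cisplatin experiments:

``hct116_like``  full-tree tracking, ~49 founder lineages, 48 h drug-free
    growth followed by 72 h of drug, two heritable states switching
    symmetrically at 9e-3 / h before drug, state-conditioned fate matrix at
    drug addition, 0.5 h snapshot rounding, an admixture of never-divider
    founders and no pre-drug deaths.  The population curve is biphasic:
    steep first decay then a persister plateau.

``u2os_like``  forward-lineage tracking (one random daughter kept per
    division), three drug-concentration labels (Low / Medium / High) that
    share identical post-drug IMT and AT distributions and differ only in
    the fate probabilities (higher death probability at higher dose),
    giving a monotone single-phase decay; a small pre-drug death fraction.

Every generated table is exactly reproducible from its manifest (the
generating function name, all parameters, and the seed).
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .emg import EMGParams
from .lineage import (CellRecord, ExperimentConfig, ExperimentTable,
                      write_cell_table)
from .simulate import FateMatrix, SimConfig, TransitionMatrix, simulate

__all__ = [
    "DEFAULT_PRE_IMT",
    "DEFAULT_POST_IMT",
    "DEFAULT_POST_AT",
    "DEFAULT_TRANSITIONS",
    "DEFAULT_FATES",
    "U2OS_FATES",
    "hct116_config",
    "barcode_config",
    "hct116_like",
    "u2os_like",
    "fixture_suite",
    "table_one_fixture",
]

# Pre-drug IMT: mean ~19.7 h, reproducing ~2.5 doublings over the 48 h
# drug-free window (49 founders -> a few hundred cells).
DEFAULT_PRE_IMT = EMGParams(13.0, 2.5, 0.15)
# Post-drug divisions are slower than drug-free cycling (mean 30 h); the
# death-time distribution (mean ~18 h) is calibrated so that the M3 recipe
# with the published transition and fate matrices reproduces the published
# first-phase decay rate of drug-treated HCT116 populations (~ -0.029/h).
DEFAULT_POST_IMT = EMGParams(20.0, 5.0, 0.10)
DEFAULT_POST_AT = EMGParams(10.0, 4.0, 0.12)
# Symmetric state switching, 9e-3 per hour.
DEFAULT_TRANSITIONS = TransitionMatrix(9e-3, 9e-3)
# State-conditioned fate probabilities (die, divide, stay).
DEFAULT_FATES = FateMatrix((0.9125, 0.05, 0.0375), (0.35, 0.10, 0.55))

# Per-concentration i.i.d. fate triples (die, divide, stay): death
# probability increases with dose, division and survival decrease.
U2OS_FATES = {
    "Low": (0.13, 0.43, 0.44),
    "Medium": (0.28, 0.31, 0.41),
    "High": (0.60, 0.23, 0.17),
}
U2OS_FOUNDERS = {"Low": 247, "Medium": 262, "High": 316}
U2OS_NEVER_DIVIDERS = {"Low": 9, "Medium": 13, "High": 9}


def hct116_config(**overrides) -> SimConfig:
    """The HCT116-like M3 simulation configuration (no never-dividers)."""
    base = dict(
        model="M3",
        n_founders=49,
        t_drug=48.0,
        t_end=120.0,
        pre_imt=DEFAULT_PRE_IMT,
        post_imt=DEFAULT_POST_IMT,
        post_at=DEFAULT_POST_AT,
        transitions=DEFAULT_TRANSITIONS,
        fates=DEFAULT_FATES,
        initial_ages="stationary",
        tracking_mode="full_tree",
    )
    base.update(overrides)
    return SimConfig(**base)


def barcode_config(condition: str = "simexpt", n_founders: int = 30,
                   **overrides) -> SimConfig:
    """M3 configuration emulating a lineage-barcoding experiment.

    Barcodes are introduced ~7 generations (144 h) before drug so that,
    with switching at 9e-3/h, cell states have decorrelated from founder
    states by treatment time — the regime barcoding studies operate in.
    Conditions: ``simexpt`` (published T and F), ``no_trans`` (frozen
    states, T = 0), ``control`` (state-independent fates with the same
    overall death probability).
    """
    cfg = hct116_config(
        n_founders=n_founders, t_drug=144.0, t_end=216.0, **overrides
    )
    if condition == "simexpt":
        return cfg
    if condition == "no_trans":
        return replace(
            cfg, transitions=TransitionMatrix(0.0, 0.0), initial_p_fraction=0.5
        )
    if condition == "control":
        row = (0.64, 0.10, 0.26)
        return replace(cfg, fates=FateMatrix(row, row))
    raise ValueError(f"unknown condition {condition!r}")


def _never_divider_records(n: int, p_die_post: float, cfg: ExperimentConfig,
                           at: EMGParams, rng, id_prefix: str = "nd"):
    """Founders that never divide; most die post-drug, the rest survive."""
    recs = []
    for i in range(n):
        dies = rng.random() < p_die_post
        t_death = cfg.t_drug + max(
            rng.normal(at.mu, at.sigma) + rng.exponential(1.0 / at.lam), 1e-6
        )
        if dies and t_death < cfg.t_end:
            end, ev = t_death, "death"
        else:
            end, ev = cfg.t_end, "censored"
        cid = f"{id_prefix}{i:04d}"
        recs.append(
            CellRecord(
                cell_id=cid,
                parent_id=None,
                lineage_id=f"L{id_prefix}{i:04d}",
                birth_time=0.0,
                end_time=float(
                    np.floor(end / cfg.snapshot_interval + 1e-9)
                    * cfg.snapshot_interval
                )
                if ev == "death"
                else end,
                end_event=ev,
                tracked=True,
            )
        )
    return recs


def hct116_like(seed=0, n_founders: int = 49, n_never_dividers: int = 13,
                snapshot_round: bool = True, **overrides):
    """Generate an HCT116-like full-tree experiment.

    Returns ``(ExperimentTable, manifest)``; the manifest suffices to
    regenerate the dataset exactly.
    """
    cfg = hct116_config(
        n_founders=n_founders, snapshot_round=snapshot_round, **overrides
    )
    ss = np.random.SeedSequence(seed)
    sim_seed, nd_seed = ss.spawn(2)
    res = simulate(cfg, seed=sim_seed)
    rng = np.random.default_rng(nd_seed)
    nd = _never_divider_records(
        n_never_dividers, 10.0 / 13.0, cfg.experiment_config(), cfg.post_at, rng
    )
    table = ExperimentTable(
        list(res.table.records) + nd, cfg.experiment_config()
    )
    manifest = {
        "recipe": "hct116_like",
        "seed": int(seed),
        "n_founders": n_founders,
        "n_never_dividers": n_never_dividers,
        "snapshot_round": snapshot_round,
        "pre_imt": list(cfg.pre_imt.as_array()),
        "post_imt": list(cfg.post_imt.as_array()),
        "post_at": list(cfg.post_at.as_array()),
        "transitions": [cfg.transitions.k_sp, cfg.transitions.k_ps],
        "fates": {"s_prime": list(cfg.fates.s_prime),
                  "p_prime": list(cfg.fates.p_prime)},
        "model": cfg.model,
        "t_drug": cfg.t_drug,
        "t_end": cfg.t_end,
        "dt": cfg.dt,
    }
    return table, manifest


def u2os_like(concentration: str = "Medium", seed=0, n_founders: int | None = None,
              pre_drug_death_fraction: float = 0.025,
              n_never_dividers: int | None = None,
              snapshot_round: bool = True, **overrides):
    """Generate a U2OS-like forward-lineage experiment at one dose label.

    Identical post-drug IMT/AT distributions across concentrations; the
    dose label sets only the i.i.d. fate triple.  Returns
    ``(ExperimentTable, manifest)``.
    """
    if concentration not in U2OS_FATES:
        raise ValueError(f"concentration must be one of {sorted(U2OS_FATES)}")
    if n_founders is None:
        n_founders = U2OS_FOUNDERS[concentration]
    if n_never_dividers is None:
        n_never_dividers = U2OS_NEVER_DIVIDERS[concentration]
    cfg = SimConfig(
        model="M2",
        n_founders=n_founders,
        t_drug=48.0,
        t_end=120.0,
        pre_imt=DEFAULT_PRE_IMT,
        post_imt=DEFAULT_POST_IMT,
        post_at=DEFAULT_POST_AT,
        m2_fates=U2OS_FATES[concentration],
        initial_ages="stationary",
        tracking_mode="forward_lineage",
        snapshot_round=snapshot_round,
        concentration_label=concentration,
        **overrides,
    )
    ss = np.random.SeedSequence(seed)
    sim_seed, nd_seed, death_seed = ss.spawn(3)
    res = simulate(cfg, seed=sim_seed)
    records = list(res.table.records)

    # overlay a small pre-drug death fraction on founder lineages: a
    # founder destined to die pre-drug is replaced by a single record dying
    # at a uniform time before its first division
    rng = np.random.default_rng(death_seed)
    founders = [r for r in records if r.parent_id is None and r.tracked]
    doomed = [
        f for f in founders if rng.random() < pre_drug_death_fraction
    ]
    snap = cfg.snapshot_interval
    for f in doomed:
        sub = _subtree_ids(records, f.cell_id)
        records = [r for r in records if r.cell_id not in sub]
        t_die = float(
            np.floor(rng.uniform(2.0, cfg.t_drug - 1.0) / snap) * snap
        )
        records.append(replace(f, end_time=t_die, end_event="death"))

    rng_nd = np.random.default_rng(nd_seed)
    frac_die = {"Low": 2 / 9, "Medium": 8 / 13, "High": 3 / 9}[concentration]
    records += _never_divider_records(
        n_never_dividers, frac_die, cfg.experiment_config(), cfg.post_at, rng_nd
    )
    table = ExperimentTable(records, cfg.experiment_config())
    manifest = {
        "recipe": "u2os_like",
        "concentration": concentration,
        "seed": int(seed),
        "n_founders": n_founders,
        "pre_drug_death_fraction": pre_drug_death_fraction,
        "n_never_dividers": n_never_dividers,
        "snapshot_round": snapshot_round,
        "fates": list(U2OS_FATES[concentration]),
        "pre_imt": list(cfg.pre_imt.as_array()),
        "post_imt": list(cfg.post_imt.as_array()),
        "post_at": list(cfg.post_at.as_array()),
        "t_drug": cfg.t_drug,
        "t_end": cfg.t_end,
        "dt": cfg.dt,
    }
    return table, manifest


def _subtree_ids(records, root_id: str) -> set[str]:
    kids: dict[str, list[str]] = {}
    for r in records:
        if r.parent_id is not None:
            kids.setdefault(r.parent_id, []).append(r.cell_id)
    out, stack = set(), [root_id]
    while stack:
        c = stack.pop()
        out.add(c)
        stack.extend(kids.get(c, ()))
    return out


# --------------------------------------------------------------------------
# hand-checkable fixtures


def _mk(cell_id, parent, lineage, birth, end, event, tracked=True):
    return CellRecord(cell_id, parent, lineage, birth, end, event, tracked)


def fixture_suite(seed=0, outdir=None) -> dict[str, ExperimentTable]:
    """Minimal hand-checkable tables for unit and oracle tests.

    Keys: ``three_cell``, ``never_divider``, ``straddler``, ``iid_fates``,
    ``ld_toy``.  If ``outdir`` is given the tables are also written as CSVs.
    """
    cfg = ExperimentConfig()
    rng = np.random.default_rng(seed)
    tables: dict[str, ExperimentTable] = {}

    tables["three_cell"] = ExperimentTable(
        [
            _mk("a", None, "L0", 0.0, 10.0, "division"),
            _mk("a1", "a", "L0", 10.0, 120.0, "censored"),
            _mk("a2", "a", "L0", 10.0, 120.0, "censored"),
        ],
        cfg,
    )

    tables["never_divider"] = ExperimentTable(
        [
            _mk("a", None, "L0", 0.0, 20.0, "division"),
            _mk("a1", "a", "L0", 20.0, 120.0, "censored"),
            _mk("a2", "a", "L0", 20.0, 120.0, "censored"),
            _mk("b", None, "L1", 0.0, 120.0, "censored"),
        ],
        cfg,
    )

    tables["straddler"] = ExperimentTable(
        [
            _mk("a", None, "L0", 0.0, 40.0, "division"),
            _mk("a1", "a", "L0", 40.0, 60.0, "death"),
            _mk("a2", "a", "L0", 40.0, 120.0, "censored"),
        ],
        cfg,
    )

    # 20 founders divide at t=24; the 40 daughters get i.i.d. coin-flip
    # fates — a null table for correlation statistics
    recs = []
    for i in range(20):
        recs.append(_mk(f"f{i}", None, f"L{i}", 0.0, 24.0, "division"))
        for d in (1, 2):
            if rng.random() < 0.5:
                recs.append(_mk(f"f{i}d{d}", f"f{i}", f"L{i}", 24.0, 120.0,
                                "censored"))
            else:
                recs.append(_mk(f"f{i}d{d}", f"f{i}", f"L{i}", 24.0, 80.0,
                                "death"))
    tables["iid_fates"] = ExperimentTable(recs, cfg)

    # two lineages of two drug-time cells each; one cell divides post-drug
    # into a (survivor, death) pair so daughter choices are enumerable
    tables["ld_toy"] = ExperimentTable(
        [
            _mk("x", None, "LX", 0.0, 24.0, "division"),
            _mk("x1", "x", "LX", 24.0, 60.0, "division"),
            _mk("x1a", "x1", "LX", 60.0, 120.0, "censored"),
            _mk("x1b", "x1", "LX", 60.0, 90.0, "death"),
            _mk("x2", "x", "LX", 24.0, 120.0, "censored"),
            _mk("y", None, "LY", 0.0, 24.0, "division"),
            _mk("y1", "y", "LY", 24.0, 70.0, "death"),
            _mk("y2", "y", "LY", 24.0, 120.0, "censored"),
        ],
        cfg,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tbl in tables.items():
            write_cell_table(tbl, outdir / f"{name}.csv")
    return tables


def table_one_fixture() -> ExperimentTable:
    """A deterministic full-tree table reproducing the printed HCT116
    summary arithmetic: 275 cells at drug addition of which 123 die, 112
    divide (daughter pairs: 35 both survive, 25 split, 52 both die) and 40
    survive, so the fully-dying fraction is (123 + 52) / 275 ~ 64%.
    """
    cfg = ExperimentConfig(t_drug=48.0, t_end=120.0)
    recs: list[CellRecord] = []
    drug_cells: list[str] = []
    # 137 founders divide pre-drug at t=24 -> 274 drug-time cells
    for i in range(137):
        fid, lin = f"f{i:03d}", f"L{i:03d}"
        recs.append(_mk(fid, None, lin, 0.0, 24.0, "division"))
        for d in (1, 2):
            drug_cells.append(f"{fid}d{d}")
    # one founder divides post-drug -> the 275th drug-time cell
    recs.append(_mk("f137", None, "L137", 0.0, 60.0, "division"))

    # post-drug fates for the 274 pre-drug daughters:
    # 111 divide, 123 die, 40 survive
    fates = ["divide"] * 111 + ["die"] * 123 + ["survive"] * 40
    pair_kinds = ["both_s"] * 35 + ["split"] * 25 + ["both_d"] * 51
    pi = 0
    for cid, fate in zip(drug_cells, fates):
        fid = cid[:-2]
        lin = "L" + fid[1:]
        if fate == "die":
            recs.append(_mk(cid, fid, lin, 24.0, 80.0, "death"))
        elif fate == "survive":
            recs.append(_mk(cid, fid, lin, 24.0, 120.0, "censored"))
        else:
            recs.append(_mk(cid, fid, lin, 24.0, 60.0, "division"))
            kind = pair_kinds[pi]
            pi += 1
            for d in ("a", "b"):
                surv = kind != "both_d" and (d == "a" or kind == "both_s")
                if surv:
                    recs.append(_mk(f"{cid}{d}", cid, lin, 60.0, 120.0,
                                    "censored"))
                else:
                    recs.append(_mk(f"{cid}{d}", cid, lin, 60.0, 95.0, "death"))
    # the post-drug divider founder contributes the 52nd both-died pair
    recs.append(_mk("f137a", "f137", "L137", 60.0, 95.0, "death"))
    recs.append(_mk("f137b", "f137", "L137", 60.0, 95.0, "death"))
    return ExperimentTable(recs, cfg)
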
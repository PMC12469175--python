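"""Lineage statistics: end-fate correlations, barcode diversity, and the
Luria-Delbrück variance-to-mean test.

The central object is the *end fate* of a cell extant at drug addition:
follow it forward in time, choosing one daughter uniformly at random at
every post-drug division, until it either dies (fate 0) or is censored
alive at the end of the experiment (fate 1, a persister).  The one-random-
daughter rule keeps the number of scored cells equal to the number of cells
at drug time, so post-drug proliferation cannot inflate dispersion
statistics.

If per-lineage persister counts were Binomial (fates assigned i.i.d. at
drug time), their variance-to-mean ratio (VMR) would be 1 - p with p the
persister probability; heritable pre-drug states push the VMR above 1.
Barcode diversity is quantified by the Shannon index over founder-lineage
frequencies, SDI = -sum_i p_i ln p_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .lineage import CellRecord, ExperimentTable
from .simulate import SimConfig, simulate

__all__ = [
    "KINSHIP_CLASSES",
    "BarcodeCensus",
    "LDResult",
    "end_fate",
    "all_end_fates",
    "lineage_fate_correlation",
    "barcode_census",
    "shannon_diversity",
    "delta_sdi",
    "ld_test",
    "binomial_null_vmr",
]

KINSHIP_CLASSES = ("sister", "first_cousin", "second_cousin", "third_cousin")


def end_fate(cell: CellRecord | str, table: ExperimentTable, rng=None) -> int:
    """Follow a drug-time cell forward to its end fate: 1 survive, 0 die.

    At every post-drug division one tracked daughter is chosen uniformly at
    random (seedable via ``rng``).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    r = table[cell] if isinstance(cell, str) else cell
    while True:
        if r.end_event == "death":
            return 0
        if r.end_event == "censored":
            return 1
        kids = [k for k in table.children(r.cell_id) if k.tracked]
        if not kids:  # division at the observation boundary
            return 0
        r = kids[rng.integers(len(kids))] if len(kids) > 1 else kids[0]


def all_end_fates(table: ExperimentTable, rng=None):
    """End fates for every cell extant at drug time.

    Returns ``(cells, fates)`` with fates a 0/1 array.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cells = table.extant_at_drug()
    fates = np.array([end_fate(c, table, rng) for c in cells], dtype=int)
    return cells, fates


# --------------------------------------------------------------------------
# kinship and fate correlations


def _ancestor_chain(table: ExperimentTable, cell: CellRecord) -> list[str]:
    chain = [cell.cell_id]
    r = cell
    while r.parent_id is not None:
        r = table[r.parent_id]
        chain.append(r.cell_id)
    return chain


def _kinship_degree(chain_i: list[str], chain_j: list[str]) -> int | None:
    """Generations back to the most recent common ancestor (max over the
    pair); None if the cells share no ancestor (different founders)."""
    set_j = {c: k for k, c in enumerate(chain_j)}
    for gi, anc in enumerate(chain_i):
        if anc in set_j:
            gj = set_j[anc]
            return max(gi, gj)
    return None


def _pearson_pairs(pairs: np.ndarray) -> float | None:
    """Symmetrized Pearson correlation (phi) over an array of fate pairs."""
    if len(pairs) == 0:
        return None
    x = np.concatenate([pairs[:, 0], pairs[:, 1]]).astype(float)
    y = np.concatenate([pairs[:, 1], pairs[:, 0]]).astype(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def lineage_fate_correlation(table: ExperimentTable, seed=None,
                             min_pairs: int = 5, n_boot: int = 200,
                             n_null_pairs: int = 2000) -> dict:
    """Pearson (phi) correlation of binary end fates by kinship class.

    Pairs are formed among cells extant at drug time; kinship is the
    generation depth of the most recent common ancestor (1 = sisters,
    2 = first cousins, ...).  The null is the correlation over randomly
    sampled pairs of cells from different founders.  Bootstrap percentile
    CIs are computed by resampling pairs.  Classes with fewer than
    ``min_pairs`` pairs are omitted.
    """
    rng = np.random.default_rng(seed)
    cells, fates = all_end_fates(table, rng)
    if len(cells) < 2:
        raise ValueError("need at least two drug-time cells")
    chains = [_ancestor_chain(table, c) for c in cells]
    founders = np.array([ch[-1] for ch in chains])

    by_class: dict[str, list] = {k: [] for k in KINSHIP_CLASSES}
    cross: list[tuple[int, int]] = []
    n = len(cells)
    for i in range(n):
        for j in range(i + 1, n):
            if founders[i] != founders[j]:
                cross.append((i, j))
                continue
            deg = _kinship_degree(chains[i], chains[j])
            if deg is not None and 1 <= deg <= 4:
                by_class[KINSHIP_CLASSES[deg - 1]].append((i, j))

    out = {}
    for cls, idx_pairs in by_class.items():
        if len(idx_pairs) < min_pairs:
            continue
        pairs = np.array([[fates[i], fates[j]] for i, j in idx_pairs])
        r = _pearson_pairs(pairs)
        boot = []
        for _ in range(n_boot):
            res = pairs[rng.integers(len(pairs), size=len(pairs))]
            rb = _pearson_pairs(res)
            if rb is not None:
                boot.append(rb)
        ci = (
            tuple(np.percentile(boot, [2.5, 97.5])) if len(boot) >= 20 else None
        )
        out[cls] = {"r": r, "n_pairs": len(pairs), "ci": ci}

    if cross:
        take = rng.choice(len(cross), size=min(n_null_pairs, len(cross)),
                          replace=False)
        pairs = np.array([[fates[cross[k][0]], fates[cross[k][1]]] for k in take])
        out["unrelated"] = {
            "r": _pearson_pairs(pairs),
            "n_pairs": len(pairs),
            "ci": None,
        }
    return out


# --------------------------------------------------------------------------
# barcode diversity


@dataclass
class BarcodeCensus:
    """Per-barcode cell counts at one time point."""

    time: float
    counts: dict[str, int]

    @property
    def frequencies(self) -> np.ndarray:
        c = np.array([v for v in self.counts.values() if v > 0], dtype=float)
        return c / c.sum()


def barcode_census(table: ExperimentTable, t: float) -> BarcodeCensus:
    """Count alive tracked cells per founder barcode (lineage_id) at ``t``."""
    counts: dict[str, int] = {}
    for r in table.extant_at(t):
        counts[r.lineage_id] = counts.get(r.lineage_id, 0) + 1
    return BarcodeCensus(time=t, counts=counts)


def shannon_diversity(census: BarcodeCensus | dict | np.ndarray) -> float:
    """Shannon diversity index, SDI = -sum p_i ln p_i (natural log)."""
    if isinstance(census, BarcodeCensus):
        counts = np.array(list(census.counts.values()), dtype=float)
    elif isinstance(census, dict):
        counts = np.array(list(census.values()), dtype=float)
    else:
        counts = np.asarray(census, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("empty census: no barcode with a positive count")
    return float(sp_stats.entropy(counts))


def delta_sdi(sim_config: SimConfig, n_reps: int = 100, seed=None,
              post_window: float = 72.0,
              bias_correction: bool = True) -> np.ndarray:
    """Distribution of SDI(t_drug + 72h) - SDI(t_drug-) over replicates.

    Each replicate is a fresh simulation; the post census counts survivors
    only (dead cells carry no barcode forward).  Because the post census is
    much smaller than the pre census and the plug-in entropy is biased low
    in small samples, the Miller-Madow correction (+ (S-1)/2N) is applied
    to both censuses by default so that exchangeable thinning yields a
    change centred on zero.  Replicates with zero survivors yield NaN.
    """
    ss = np.random.SeedSequence(seed)
    out = np.empty(n_reps)
    t_post = min(sim_config.t_drug + post_window, sim_config.t_end)

    def sdi(census: BarcodeCensus) -> float:
        h = shannon_diversity(census)
        if bias_correction:
            c = np.array([v for v in census.counts.values() if v > 0], float)
            h += (len(c) - 1) / (2.0 * c.sum())
        return h

    for k, cs in enumerate(ss.spawn(n_reps)):
        res = simulate(sim_config, seed=cs)
        pre = barcode_census(res.table, sim_config.t_drug - 1e-9)
        post = barcode_census(res.table, t_post)
        if not post.counts:
            out[k] = np.nan
            continue
        out[k] = sdi(post) - sdi(pre)
    return out


# --------------------------------------------------------------------------
# Luria-Delbrück fluctuation test


@dataclass
class LDResult:
    """Luria-Delbrück dispersion of per-lineage persister counts."""

    vmrs: np.ndarray
    per_lineage_counts: np.ndarray  # from the last replicate
    persister_fraction: float
    n_lineages: int

    @property
    def mean_vmr(self) -> float:
        return float(np.nanmean(self.vmrs))

    @property
    def binomial_null(self) -> float:
        return binomial_null_vmr(self.persister_fraction)

    def vmr_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0 * 100.0
        v = self.vmrs[np.isfinite(self.vmrs)]
        return tuple(np.percentile(v, [lo, 100.0 - lo]))


def binomial_null_vmr(p: float) -> float:
    """VMR of Binomial persister counts under i.i.d. fate assignment: 1 - p."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("persister probability must lie in [0, 1]")
    return 1.0 - p


def _one_ld_rep(table: ExperimentTable, rng) -> tuple[np.ndarray, float]:
    cells, fates = all_end_fates(table, rng)
    lineages = np.array([c.lineage_id for c in cells])
    uniq = np.unique(lineages)
    counts = np.array([fates[lineages == u].sum() for u in uniq], dtype=float)
    return counts, float(fates.mean()) if len(fates) else np.nan


def ld_test(table_or_config, n_reps: int = 100, seed=None,
            resimulate: bool | None = None) -> LDResult:
    """Variance-to-mean ratio of per-founder-lineage persister counts.

    On a fixed table the replicates vary only the one-random-daughter
    choices; on a :class:`SimConfig` each replicate is a fresh simulation
    (``resimulate`` overrides the default).  The VMR uses the unbiased
    sample variance across lineages with at least one drug-time cell.
    """
    is_config = isinstance(table_or_config, SimConfig)
    if resimulate is None:
        resimulate = is_config
    if resimulate and not is_config:
        raise ValueError("resimulation requires a SimConfig")
    ss = np.random.SeedSequence(seed)
    vmrs = np.empty(n_reps)
    fracs = np.empty(n_reps)
    counts = None
    for k, cs in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(cs)
        table = (
            simulate(table_or_config, seed=cs).table if resimulate else table_or_config
        )
        counts, frac = _one_ld_rep(table, rng)
        if len(counts) < 2:
            raise ValueError("VMR undefined with fewer than two lineages")
        m = counts.mean()
        vmrs[k] = np.nan if m == 0 else counts.var(ddof=1) / m
        fracs[k] = frac
    return LDResult(
        vmrs=vmrs,
        per_lineage_counts=counts,
        persister_fraction=float(np.nanmean(fracs)),
        n_lineages=len(counts),
    )
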
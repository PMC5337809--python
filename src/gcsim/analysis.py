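"""Repertoire statistics on simulated (or experimental) subclone counts.

The central statistic is the gap-based expansion threshold: from the
histogram F(c) of integer cell/read counts c, T is the lowest count whose
frequency falls below p (p = 1 by default, i.e. the lowest unobserved
count), and subclones with c > T are called expanded.  Downstream summaries
cross the expansion call with an affinity classification at a percentile
(default 75th) of the affinities of every subclone produced during the
reaction, and quantify the abundance-affinity association by Spearman rank
correlation.  Centrocyte (CC) counts stand in for sequencing reads because
centroblasts express little surface BCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SimulationResult

__all__ = [
    "CountHistogram",
    "ExpansionCall",
    "AffinityAbundanceSummary",
    "expansion_threshold",
    "cc_counts_for_expansion",
    "affinity_threshold",
    "affinity_abundance_summary",
    "summary_trajectories",
    "clonal_sizes",
    "replicate_summary",
]

DEFAULT_AFFINITY_BINS = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, np.inf)


@dataclass(frozen=True)
class CountHistogram:
    """Frequencies F(c): number of subclones observed with count c."""

    counts: dict[int, int]

    @classmethod
    def from_counts(cls, values) -> "CountHistogram":
        values = np.asarray(values)
        if values.size == 0:
            raise ValueError("cannot build a count histogram from no counts")
        if (values < 0).any():
            raise ValueError("counts must be nonnegative integers")
        uniq, freq = np.unique(values.astype(np.int64), return_counts=True)
        return cls(dict(zip(uniq.tolist(), freq.tolist())))

    def frequency(self, c: int) -> int:
        return self.counts.get(int(c), 0)


@dataclass(frozen=True)
class ExpansionCall:
    """Result of the gap-threshold rule on one count vector."""

    threshold: int
    expanded_ids: frozenset
    relax_p: int


def expansion_threshold(counts, ids=None, relax_p: int = 1) -> ExpansionCall:
    """Gap-based expansion threshold.

    ``T`` is the lowest count c >= 1 with F(c) < relax_p; subclones with
    count > T are expanded.  With the default relax_p = 1 this is the lowest
    unobserved count, i.e. the first gap of the histogram; counts with no
    gap below the maximum leave nothing expanded (T = max + 1).

    ``ids`` optionally labels the count vector; defaults to positional
    indices.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("expansion threshold needs at least one count")
    if relax_p < 1:
        raise ValueError("relax_p must be >= 1")
    hist = CountHistogram.from_counts(counts)
    t = 1
    while hist.frequency(t) >= relax_p:
        t += 1
    if ids is None:
        ids = np.arange(counts.size)
    ids = np.asarray(ids)
    expanded = frozenset(ids[counts > t].tolist())
    return ExpansionCall(threshold=t, expanded_ids=expanded, relax_p=relax_p)


def cc_counts_for_expansion(result: SimulationResult) -> pd.DataFrame:
    """Integer CC counts at the final time point, one row per subclone.

    CC counts are rounded to the nearest integer (they are continuous ODE
    quantities standing in for discrete sequencing counts) and subclones
    rounding to zero are dropped -- a zero count is unobservable in a
    sequencing experiment.
    """
    final = result.final_state()
    counts = np.rint(final["cc"].to_numpy()).astype(np.int64)
    keep = counts >= 1
    return pd.DataFrame({
        "subclone_id": final["subclone_id"].to_numpy()[keep],
        "count": counts[keep],
        "sigma": final["sigma"].to_numpy()[keep],
    })


def affinity_threshold(sigmas, percentile: float = 75.0) -> float:
    """Percentile (linear interpolation) of a set of absolute affinities."""
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.size == 0:
        raise ValueError("affinity threshold needs at least one affinity")
    return float(np.percentile(sigmas, percentile))


@dataclass(frozen=True)
class AffinityAbundanceSummary:
    """2x2 expansion x affinity-class breakdown of one replicate at day 21."""

    threshold_count: int           # expansion threshold T
    affinity_cutoff: float         # percentile sigma over all subclones ever
    percentile: float
    n_expanded_high: int
    n_expanded_low: int
    n_unexpanded_high: int
    n_unexpanded_low: int
    pct_low_among_expanded: float
    pct_high_among_unexpanded: float
    spearman_rho: float            # NaN when < 3 observable subclones
    most_abundant_sigma: float
    most_abundant_in_top_quartile: bool
    most_abundant_is_top_affinity: bool

    @property
    def n_subclones(self) -> int:
        return (self.n_expanded_high + self.n_expanded_low
                + self.n_unexpanded_high + self.n_unexpanded_low)


def affinity_abundance_summary(
    result: SimulationResult,
    percentile: float = 75.0,
    relax_p: int = 1,
) -> AffinityAbundanceSummary:
    """Cross the expansion call with the affinity classes for one replicate.

    Expansion is called on rounded final CC counts; the affinity cutoff is
    the ``percentile`` of the affinities of every subclone ever produced
    (pruned ones included, each once).  High affinity means sigma strictly
    above the cutoff.  Spearman's rho (average-rank ties) relates final CC
    count to sigma over the observable (CC >= 1) subclones.
    """
    table = cc_counts_for_expansion(result)
    if table.empty:
        raise ValueError("no subclone has an observable CC count at the final step")
    cutoff = affinity_threshold(result.all_subclone_sigmas()["sigma"], percentile)
    call = expansion_threshold(table["count"], ids=table["subclone_id"], relax_p=relax_p)
    expanded = table["subclone_id"].isin(call.expanded_ids).to_numpy()
    high = (table["sigma"] > cutoff).to_numpy()

    if len(table) >= 3 and table["count"].nunique() > 1 and table["sigma"].nunique() > 1:
        rho = float(stats.spearmanr(table["count"], table["sigma"]).statistic)
    else:
        rho = float("nan")  # undefined: too few points or a constant margin

    top = table.loc[table["count"].idxmax()]
    n_eh = int((expanded & high).sum())
    n_el = int((expanded & ~high).sum())
    n_uh = int((~expanded & high).sum())
    n_ul = int((~expanded & ~high).sum())
    return AffinityAbundanceSummary(
        threshold_count=call.threshold,
        affinity_cutoff=cutoff,
        percentile=percentile,
        n_expanded_high=n_eh,
        n_expanded_low=n_el,
        n_unexpanded_high=n_uh,
        n_unexpanded_low=n_ul,
        pct_low_among_expanded=100.0 * n_el / max(n_eh + n_el, 1),
        pct_high_among_unexpanded=100.0 * n_uh / max(n_uh + n_ul, 1),
        spearman_rho=rho,
        most_abundant_sigma=float(top["sigma"]),
        most_abundant_in_top_quartile=bool(top["sigma"] > cutoff),
        most_abundant_is_top_affinity=bool(
            top["sigma"] >= table["sigma"].max()),
    )


def summary_trajectories(
    result: SimulationResult,
    affinity_bins=DEFAULT_AFFINITY_BINS,
) -> pd.DataFrame:
    """Per-step population summaries.

    One row per 6-h step: total CB and CC, their ratio, the number of unique
    subclones (those with CC >= 1 -- sub-unit counts are unobservable), the
    maximum mutation load among those subclones, and CB+CC cell totals per
    absolute-affinity class.
    """
    traj = result.trajectory
    rows = []
    bins = np.asarray(affinity_bins, dtype=float)
    labels = [f"cells_sigma_{bins[i]:g}_{bins[i+1]:g}" for i in range(len(bins) - 1)]
    for (step, time), group in traj.groupby(["step", "time"], sort=True):
        cb_tot, cc_tot = group["cb"].sum(), group["cc"].sum()
        observable = group[group["cc"] >= 1.0]
        row = {
            "step": step,
            "time": time,
            "cb_total": cb_tot,
            "cc_total": cc_tot,
            "cb_cc_ratio": cb_tot / cc_tot if cc_tot > 0 else np.nan,
            "n_subclones_total": len(group),
            "n_unique_subclones": len(observable),
            # mutation load among observable subclones; if none carries a
            # whole CC cell, fall back to all living subclones
            "max_n_mutations": int((observable if len(observable) else group)
                                   ["n_mutations"].max()),
            "mean_sigma_cellweighted": (
                np.average(group["sigma"], weights=group["cb"] + group["cc"])
                if (group["cb"] + group["cc"]).sum() > 0 else np.nan),
        }
        cells = (group["cb"] + group["cc"]).to_numpy()
        which = np.digitize(group["sigma"].to_numpy(), bins) - 1
        for i, lab in enumerate(labels):
            row[lab] = float(cells[which == i].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def clonal_sizes(counts) -> np.ndarray:
    """Counts as fractions of the total (a subclone's clonal size)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("clonal sizes need at least one count")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    return counts / total


def replicate_summary(result: SimulationResult) -> dict:
    """Flat per-replicate summary row (used by parameter sweeps)."""
    summ = summary_trajectories(result)
    total = summ["cb_total"] + summ["cc_total"]
    peak_idx = int(total.idxmax())
    out = {
        "seed": result.seed,
        "extinct": result.extinct,
        "peak_total_cells": float(total.iloc[peak_idx]),
        "peak_day": float(summ["time"].iloc[peak_idx]),
        "final_total_cells": float(total.iloc[-1]),
        "final_n_unique_subclones": int(summ["n_unique_subclones"].iloc[-1]),
        "final_max_n_mutations": int(summ["max_n_mutations"].iloc[-1]),
        "n_subclones_ever": int(len(result.all_subclone_sigmas())),
    }
    try:
        aa = affinity_abundance_summary(result)
        out.update({
            "expansion_threshold": aa.threshold_count,
            "affinity_cutoff": aa.affinity_cutoff,
            "pct_low_among_expanded": aa.pct_low_among_expanded,
            "pct_high_among_unexpanded": aa.pct_high_among_unexpanded,
            "spearman_rho": aa.spearman_rho,
        })
    except ValueError:
        out.update({"expansion_threshold": np.nan, "affinity_cutoff": np.nan,
                    "pct_low_among_expanded": np.nan,
                    "pct_high_among_unexpanded": np.nan, "spearman_rho": np.nan})
    return out
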
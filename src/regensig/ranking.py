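"""Fold-change computation, probe→gene collapse, within-experiment ranking,
cross-experiment rank aggregation, and top-N signature extraction.

Platforms are never compared on raw signal.  Each experiment contributes only
the log2 ratio of its high-regeneration over low-regeneration group means,
computed within-platform; those ratios are ranked within each experiment
(rank 1 = largest fold change, ties get the average of the tied positions),
the per-gene ranks are averaged across experiments, and the top N genes of
the aggregate ordering form the signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError
from .ingest import (
    FC_COL,
    GROUP_HIGH,
    GROUP_LOW,
    PROBE_COL,
    SYMBOL_COL,
    ExpressionExperiment,
    GeneUniverse,
)

CollapseMethod = Literal["median", "mean", "max_abs"]


@dataclass(frozen=True)
class FoldChangeTable:
    """One log2 fold change per gene for one experiment."""

    experiment_id: str
    log2fc: pd.Series  # index: gene symbol, values: finite floats
    n_probes: pd.Series  # index: gene symbol, probes collapsed per gene

    def __post_init__(self) -> None:
        if self.log2fc.index.has_duplicates:
            raise InputError(f"{self.experiment_id}: duplicate genes in fold-change table")
        if not np.isfinite(self.log2fc.to_numpy(dtype=float)).all():
            raise InputError(f"{self.experiment_id}: non-finite log2fc")

    @property
    def genes(self) -> set[str]:
        return set(self.log2fc.index)

    def restrict(self, universe: GeneUniverse) -> "FoldChangeTable":
        """Exactly one row per universe gene, in universe order."""
        missing = [g for g in universe.genes if g not in self.log2fc.index]
        if missing:
            raise InputError(
                f"{self.experiment_id}: universe gene(s) missing from fold changes, "
                f"e.g. {missing[:3]}"
            )
        idx = list(universe.genes)
        return FoldChangeTable(
            experiment_id=self.experiment_id,
            log2fc=self.log2fc.loc[idx],
            n_probes=self.n_probes.loc[idx],
        )


@dataclass(frozen=True)
class RankTable:
    """Descending fold-change ranks for one experiment.

    Rank 1 is the largest log2fc; ties carry the average of the tied
    positions, so the ranks always sum to U(U+1)/2.
    """

    experiment_id: str
    ranks: pd.Series  # index: gene symbol

    @property
    def universe(self) -> frozenset:
        return frozenset(self.ranks.index)


@dataclass(frozen=True)
class AggregateRanking:
    """Mean per-gene rank over k experiments, sorted ascending.

    Ties in the mean rank are ordered lexicographically by gene symbol, so the
    ordering is deterministic and invariant under experiment permutation.
    """

    mean_rank: pd.Series  # sorted ascending; ties broken by gene symbol
    k: int

    @property
    def genes(self) -> tuple:
        return tuple(self.mean_rank.index)


@dataclass(frozen=True)
class SignatureList:
    """An ordered top-N gene list with provenance."""

    genes: tuple[str, ...]
    n_top: int
    tie_break: tuple[str, ...] = ()  # genes whose boundary position was tie-broken
    provenance: dict = field(default_factory=dict, hash=False, compare=False)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


# ---------------------------------------------------------------------------
# fold changes


def log2_fold_change(mean_high, mean_low, floor: float):
    """log2(max(mean_high, floor) / max(mean_low, floor)).

    The floor keeps the ratio finite for genes absent in one condition.
    Accepts scalars or arrays; inputs must be non-negative.
    """
    if floor <= 0:
        raise InputError(f"floor must be positive, got {floor}")
    hi = np.asarray(mean_high, dtype=float)
    lo = np.asarray(mean_low, dtype=float)
    if (hi < 0).any() or (lo < 0).any():
        raise InputError("intensity means must be non-negative")
    out = np.log2(np.maximum(hi, floor) / np.maximum(lo, floor))
    return float(out) if out.ndim == 0 else out


def collapse_probes(values: Sequence[float], method: CollapseMethod = "median") -> float:
    """Collapse one gene's per-probe log2 fold changes to a single value.

    ``median`` (default) is robust to a single aberrant probe; ``mean`` and
    ``max_abs`` (value of largest magnitude, earliest on ties) are provided
    for sensitivity analysis.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InputError("collapse_probes: empty probe list")
    if method == "median":
        return float(np.median(arr))
    if method == "mean":
        return float(np.mean(arr))
    if method == "max_abs":
        return float(arr[int(np.argmax(np.abs(arr)))])
    raise InputError(f"unknown collapse method {method!r}")


def default_floor(experiment: ExpressionExperiment) -> float:
    """Smallest positive observed intensity — the floor used when none is given."""
    mat = experiment.table[experiment.sample_columns].to_numpy(dtype=float)
    pos = mat[mat > 0]
    if pos.size == 0:
        raise InputError(f"{experiment.experiment_id}: all intensities are zero")
    return float(pos.min())


def probe_log2fc(experiment: ExpressionExperiment, floor: float | None = None) -> pd.DataFrame:
    """Per-probe log2 fold change of group means (high over low regeneration).

    For precomputed fold-change experiments the stored column is returned
    as-is.  Returns a frame with ``gene_symbol`` and ``log2fc`` indexed by
    probe.
    """
    if not experiment.has_matrix:
        return experiment.table.set_index(PROBE_COL)[[SYMBOL_COL, FC_COL]].copy()
    if floor is None:
        floor = default_floor(experiment)
    hi_cols = experiment.samples_in_group(GROUP_HIGH)
    lo_cols = experiment.samples_in_group(GROUP_LOW)
    table = experiment.table.set_index(PROBE_COL)
    mean_hi = table[hi_cols].to_numpy(dtype=float).mean(axis=1)
    mean_lo = table[lo_cols].to_numpy(dtype=float).mean(axis=1)
    fc = log2_fold_change(mean_hi, mean_lo, floor)
    out = table[[SYMBOL_COL]].copy()
    out[FC_COL] = fc
    return out


def fold_change_table(
    experiment: ExpressionExperiment,
    collapse: CollapseMethod = "median",
    floor: float | None = None,
) -> FoldChangeTable:
    """Probe-level fold changes collapsed to one value per gene."""
    per_probe = probe_log2fc(experiment, floor=floor)
    grouped = per_probe.groupby(SYMBOL_COL, sort=True)[FC_COL]
    if collapse == "median":
        log2fc = grouped.median()
    elif collapse == "mean":
        log2fc = grouped.mean()
    elif collapse == "max_abs":
        log2fc = grouped.agg(lambda v: collapse_probes(v, method="max_abs"))
    else:
        raise InputError(f"unknown collapse method {collapse!r}")
    n_probes = grouped.size()
    return FoldChangeTable(
        experiment_id=experiment.experiment_id,
        log2fc=log2fc.rename(FC_COL),
        n_probes=n_probes.rename("n_probes"),
    )


# ---------------------------------------------------------------------------
# ranking and aggregation


def rank_by_fc(fc: FoldChangeTable) -> RankTable:
    """Rank genes by descending log2 fold change (rank 1 = highest ratio)."""
    values = fc.log2fc.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError(f"{fc.experiment_id}: non-finite fold change cannot be ranked")
    ranks = rankdata(-values, method="average")
    return RankTable(
        experiment_id=fc.experiment_id,
        ranks=pd.Series(ranks, index=fc.log2fc.index, name="rank"),
    )


def aggregate_ranks(rank_tables: Sequence[RankTable]) -> AggregateRanking:
    """Average each gene's rank over the k experiments and sort ascending.

    All tables must share the identical universe; the result is invariant
    under permutation of the experiment list.
    """
    if not rank_tables:
        raise InputError("aggregate_ranks: no rank tables supplied")
    universe = rank_tables[0].universe
    for rt in rank_tables[1:]:
        if rt.universe != universe:
            diff = sorted(universe.symmetric_difference(rt.universe))
            raise InputError(
                f"universe mismatch between {rank_tables[0].experiment_id!r} and "
                f"{rt.experiment_id!r}; symmetric difference e.g. {diff[:5]}"
            )
    stacked = pd.concat([rt.ranks for rt in rank_tables], axis=1)
    mean_rank = stacked.mean(axis=1).rename("mean_rank")
    order = sorted(mean_rank.index, key=lambda g: (mean_rank[g], g))
    return AggregateRanking(mean_rank=mean_rank.loc[order], k=len(rank_tables))


def top_n(agg: AggregateRanking, n: int, provenance: dict | None = None) -> SignatureList:
    """First min(N, U) genes of the aggregate ordering.

    Exact mean-rank ties that straddle the cutoff are broken lexicographically
    by gene symbol (already the sort order of :class:`AggregateRanking`); the
    tied boundary genes are recorded so the event is visible in provenance.
    """
    if n < 0:
        raise InputError(f"n_top must be >= 0, got {n}")
    genes = agg.genes
    cut = min(n, len(genes))
    chosen = genes[:cut]
    tie_break: tuple[str, ...] = ()
    if 0 < cut < len(genes):
        boundary = agg.mean_rank.iloc[cut - 1]
        if agg.mean_rank.iloc[cut] == boundary:
            tied = tuple(g for g in genes if agg.mean_rank[g] == boundary)
            tie_break = tied
    return SignatureList(
        genes=tuple(chosen),
        n_top=n,
        tie_break=tie_break,
        provenance=dict(provenance or {}),
    )


def per_experiment_signature(
    rank_table: RankTable, n: int, provenance: dict | None = None
) -> SignatureList:
    """Top-N list of a single experiment (a k=1 aggregate)."""
    agg = aggregate_ranks([rank_table])
    prov = {"experiment_id": rank_table.experiment_id}
    prov.update(provenance or {})
    return top_n(agg, n, provenance=prov)
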
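"""k-way Venn intersections of signature lists and a permutation null for the
central overlap.

The headline statistic of the meta-analysis is the central Venn region — the
genes present in *every* top-N list.  Under the null that each list is an
independent uniform draw of n_i genes from a universe of size U, the expected
central overlap is U·∏(n_i/U); a seeded permutation test gives a Monte-Carlo
p-value for the observed size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .ingest import GeneUniverse
from .ranking import SignatureList


@dataclass(frozen=True)
class OverlapResult:
    """Venn region memberships plus (optionally) the permutation-null summary.

    ``regions`` maps each non-empty combination of list ids (a sorted tuple)
    to the genes belonging to exactly those lists; for k lists there are
    2^k − 1 regions and the region counts sum to the size of the union.
    """

    list_ids: tuple[str, ...]
    list_sizes: dict[str, int]
    regions: dict[tuple[str, ...], tuple[str, ...]]
    central: tuple[str, ...]
    expected: float | None = None
    p_value: float | None = None
    permutations: int = 0
    seed: int | None = None
    extras: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def central_size(self) -> int:
        return len(self.central)

    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}


def _as_gene_set(lst) -> set:
    if isinstance(lst, SignatureList):
        return set(lst.genes)
    return set(lst)


def venn_regions(
    lists: Mapping[str, Sequence[str] | SignatureList],
    universe: GeneUniverse | None = None,
) -> OverlapResult:
    """Exact Venn region memberships for 1–3 signature lists.

    Every list must lie within the given universe (when one is supplied).
    Region keys are sorted tuples of the list ids whose intersection, minus
    all other lists, the region represents.
    """
    if not 1 <= len(lists) <= 3:
        raise InputError(f"venn_regions supports 1-3 lists, got {len(lists)}")
    sets = {lid: _as_gene_set(lst) for lid, lst in lists.items()}
    if universe is not None:
        uni = universe.as_set()
        for lid, s in sets.items():
            outside = s - uni
            if outside:
                raise InputError(
                    f"list {lid!r} contains gene(s) outside the universe, "
                    f"e.g. {sorted(outside)[:3]}"
                )
    ids = tuple(sorted(sets))
    regions: dict[tuple[str, ...], tuple[str, ...]] = {}
    for r in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, r):
            inside = set.intersection(*(sets[i] for i in combo))
            for other in ids:
                if other not in combo:
                    inside -= sets[other]
            regions[combo] = tuple(sorted(inside))
    central = tuple(sorted(set.intersection(*sets.values())))
    return OverlapResult(
        list_ids=ids,
        list_sizes={lid: len(s) for lid, s in sets.items()},
        regions=regions,
        central=central,
    )


def expected_central_overlap(list_sizes: Sequence[int], universe_size: int) -> float:
    """U·∏(n_i/U): expected k-way overlap of independent uniform lists."""
    u = float(universe_size)
    expected = u
    for n in list_sizes:
        expected *= n / u
    return expected


def overlap_null_pvalue(
    observed: int,
    list_sizes: Sequence[int],
    universe_size: int,
    permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for an observed central overlap.

    Each permutation draws every list uniformly at random without replacement
    from the universe and records the size of the full intersection; the
    p-value uses the add-one Monte-Carlo convention
    p = (1 + #{perm ≥ observed}) / (M + 1), guaranteeing p ∈ (0, 1].
    """
    sizes = list(list_sizes)
    if not sizes:
        raise InputError("overlap_null_pvalue: no list sizes")
    if any(n > universe_size for n in sizes):
        raise InputError("list size exceeds universe size")
    if observed > min(sizes):
        raise InputError(
            f"observed overlap {observed} exceeds smallest list size {min(sizes)}"
        )
    if permutations < 1:
        raise InputError("permutations must be >= 1")
    expected = expected_central_overlap(sizes, universe_size)
    if len(sizes) == 1:
        # a single list always coincides with itself
        return expected, 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    membership = np.zeros(universe_size, dtype=np.int32)
    for _ in range(permutations):
        membership[:] = 0
        for n in sizes:
            membership[rng.choice(universe_size, size=n, replace=False)] += 1
        overlap = int((membership == len(sizes)).sum())
        if overlap >= observed:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    return expected, p


def assess_overlap(
    lists: Mapping[str, Sequence[str] | SignatureList],
    universe: GeneUniverse,
    permutations: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Venn regions plus null expectation and permutation p for the centre.

    With ``permutations=0`` the permutation test is skipped (p is ``None``);
    the closed-form expectation is always reported.
    """
    base = venn_regions(lists, universe)
    sizes = [base.list_sizes[lid] for lid in base.list_ids]
    expected = expected_central_overlap(sizes, universe.size)
    p: float | None = None
    if permutations > 0:
        _, p = overlap_null_pvalue(
            base.central_size, sizes, universe.size, permutations=permutations, seed=seed
        )
    return OverlapResult(
        list_ids=base.list_ids,
        list_sizes=base.list_sizes,
        regions=base.regions,
        central=base.central,
        expected=expected,
        p_value=p,
        permutations=permutations,
        seed=seed,
    )
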
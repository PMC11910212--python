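"""Reading expression tables, symbol canonicalization, ortholog mapping, and
construction of the common gene universe.

The meta-analysis compares experiments run on different platforms and in two
species (mouse and human).  Before any ranking can happen, every experiment
must be expressed over the *same* set of human gene symbols:

1. probe-level tables are read and validated (:func:`read_expression_table`),
2. gene symbols are updated to current nomenclature via an alias table
   (:func:`canonicalize_symbols`),
3. mouse genes are relabelled with their human orthologs
   (:func:`map_to_human`), and
4. the common universe is the intersection of the per-experiment gene sets
   (:func:`build_common_universe`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

GROUP_HIGH = "high_regeneration"
GROUP_LOW = "low_regeneration"
VALID_GROUPS = (GROUP_HIGH, GROUP_LOW)

PROBE_COL = "probe_id"
SYMBOL_COL = "gene_symbol"
FC_COL = "log2fc"


@dataclass
class ExpressionExperiment:
    """One platform/species dataset with a two-group regeneration design.

    ``table`` holds one row per probe with columns ``probe_id``,
    ``gene_symbol`` and either sample intensity columns (non-negative, one per
    sample in ``design``) or a single precomputed ``log2fc`` column, in which
    case ``design`` is ``None``.
    """

    experiment_id: str
    species: str  # "mouse" | "human"
    platform: str
    table: pd.DataFrame
    design: dict[str, str] | None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def has_matrix(self) -> bool:
        return self.design is not None

    @property
    def sample_columns(self) -> list[str]:
        return list(self.design) if self.design else []

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in (self.design or {}).items() if g == group]

    @property
    def genes(self) -> set[str]:
        return set(self.table[SYMBOL_COL])

    def validate(self) -> None:
        if self.species not in ("mouse", "human"):
            raise InputError(
                f"{self.experiment_id}: species must be 'mouse' or 'human', got {self.species!r}"
            )
        if len(self.table) < 1:
            raise InputError(f"{self.experiment_id}: experiment has no probes")
        for col in (PROBE_COL, SYMBOL_COL):
            if col not in self.table.columns:
                raise InputError(f"{self.experiment_id}: missing column {col!r}")
        dup = self.table[PROBE_COL].duplicated()
        if dup.any():
            raise InputError(
                f"{self.experiment_id}: duplicate probe_ids, e.g. "
                f"{self.table.loc[dup, PROBE_COL].iloc[0]!r}"
            )
        if self.has_matrix:
            assert self.design is not None
            bad_group = {g for g in self.design.values() if g not in VALID_GROUPS}
            if bad_group:
                raise InputError(
                    f"{self.experiment_id}: unknown design group(s) {sorted(bad_group)}; "
                    f"expected one of {VALID_GROUPS}"
                )
            for grp in VALID_GROUPS:
                if not self.samples_in_group(grp):
                    raise InputError(f"{self.experiment_id}: no samples in group {grp!r}")
            missing = [s for s in self.design if s not in self.table.columns]
            if missing:
                raise InputError(
                    f"{self.experiment_id}: design sample(s) {missing} absent from table"
                )
            mat = self.table[self.sample_columns].to_numpy(dtype=float)
            if not np.isfinite(mat).all():
                raise InputError(f"{self.experiment_id}: non-finite intensities")
            if (mat < 0).any():
                raise InputError(f"{self.experiment_id}: negative intensities")
        else:
            if FC_COL not in self.table.columns:
                raise InputError(
                    f"{self.experiment_id}: no design and no {FC_COL!r} column — "
                    "provide either a sample matrix or precomputed fold changes"
                )
            fc = self.table[FC_COL].to_numpy(dtype=float)
            if not np.isfinite(fc).all():
                raise InputError(f"{self.experiment_id}: non-finite log2fc values")


@dataclass(frozen=True)
class AliasTable:
    """Maps outdated/alias gene symbols to current canonical nomenclature.

    Canonical symbols are fixed points: looking one up returns it unchanged.
    """

    frame: pd.DataFrame  # columns: alias, canonical, species

    COLUMNS = ("alias", "canonical", "species")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.frame.columns:
                raise ParseError(f"alias table missing column {col!r}")
        for col in ("alias", "canonical"):
            if (self.frame[col].astype(str).str.len() == 0).any():
                raise ParseError(f"alias table has empty {col} symbols")

    def mapping(self, species: str) -> dict[str, str]:
        sub = self.frame[self.frame["species"] == species]
        return dict(zip(sub["alias"], sub["canonical"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasTable":
        return cls(_read_table(path, cls.COLUMNS, "alias table"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class OrthologMap:
    """Mouse→human gene symbol correspondences (HomoloGene/HCOP style).

    Duplicate (mouse, human) pairs are collapsed on construction.
    """

    frame: pd.DataFrame  # columns: mouse_symbol, human_symbol, source_db

    COLUMNS = ("mouse_symbol", "human_symbol", "source_db")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.frame.columns:
                raise ParseError(f"ortholog map missing column {col!r}")
        for col in ("mouse_symbol", "human_symbol"):
            if (self.frame[col].astype(str).str.len() == 0).any():
                raise ParseError(f"ortholog map has empty {col} entries")
        deduped = self.frame.drop_duplicates(subset=["mouse_symbol", "human_symbol"])
        object.__setattr__(self, "frame", deduped.reset_index(drop=True))

    def human_targets(self) -> dict[str, list[str]]:
        """Mouse symbol → list of human symbols (usually length 1)."""
        out: dict[str, list[str]] = {}
        for m, h in zip(self.frame["mouse_symbol"], self.frame["human_symbol"]):
            out.setdefault(m, []).append(h)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        return cls(_read_table(path, cls.COLUMNS, "ortholog map"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneUniverse:
    """The identical human-symbol gene set shared by every experiment.

    ``dropped`` records, per experiment, the genes excluded by the
    intersection, so annotation-drift effects remain diagnosable.
    """

    genes: tuple[str, ...]
    dropped: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset:
        return frozenset(self.genes)


# ---------------------------------------------------------------------------
# file readers


def _read_table(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read {what} {path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{what} {path}: missing column(s) {missing}")
    return frame


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→group TSV (header: sample, group)."""
    frame = _read_table(path, ("sample", "group"), "design file")
    dup = frame["sample"].duplicated()
    if dup.any():
        raise ParseError(f"design {path}: duplicate sample {frame.loc[dup, 'sample'].iloc[0]!r}")
    return dict(zip(frame["sample"], frame["group"]))


def read_expression_table(
    path: str | Path,
    design_path: str | Path | None,
    species: str,
    platform: str,
    experiment_id: str | None = None,
    fc_column: str | None = None,
) -> ExpressionExperiment:
    """Read a probe-level expression (or precomputed fold-change) TSV/CSV.

    Rows with an empty ``gene_symbol`` are dropped; the count is recorded in
    ``meta['n_dropped_empty_symbol']``.  When ``fc_column`` is given the table
    is treated as precomputed per-probe log2 fold changes and no design is
    required.
    """
    path = Path(path)
    experiment_id = experiment_id or path.stem
    frame = _read_table(path, (PROBE_COL, SYMBOL_COL), f"expression table")

    empty = frame[SYMBOL_COL].astype(str).str.strip() == ""
    n_dropped = int(empty.sum())
    frame = frame[~empty].copy()
    if frame.empty:
        raise ParseError(f"{path}: no rows with a gene_symbol remain")

    if fc_column is not None:
        if fc_column not in frame.columns:
            raise ParseError(f"{path}: fold-change column {fc_column!r} not found")
        try:
            fc = frame[fc_column].astype(float)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value in column {fc_column!r}: {exc}") from exc
        table = frame[[PROBE_COL, SYMBOL_COL]].copy()
        table[FC_COL] = fc.to_numpy()
        design = None
    else:
        if design_path is None:
            raise ParseError(f"{path}: a design file is required for intensity tables")
        design = read_design(design_path)
        missing = [s for s in design if s not in frame.columns]
        if missing:
            raise ParseError(f"{path}: design sample(s) {missing} not found in table header")
        cols = [PROBE_COL, SYMBOL_COL] + list(design)
        table = frame[cols].copy()
        for s in design:
            try:
                table[s] = table[s].astype(float)
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric intensity in column {s!r}: {exc}") from exc

    table = table.reset_index(drop=True)
    exp = ExpressionExperiment(
        experiment_id=experiment_id,
        species=species,
        platform=platform,
        table=table,
        design=design,
        meta={"source": str(path), "n_dropped_empty_symbol": n_dropped},
    )
    return exp


# ---------------------------------------------------------------------------
# annotation operations


def canonicalize_symbols(
    experiment: ExpressionExperiment, aliases: AliasTable
) -> ExpressionExperiment:
    """Replace each probe's symbol with its canonical form where an alias
    record exists for the experiment's species.

    Unknown symbols pass through unchanged; their count is recorded in
    ``meta['n_alias_unmapped']``.  Idempotent, because canonical symbols are
    fixed points of the alias table.
    """
    mapping = aliases.mapping(experiment.species)
    table = experiment.table.copy()
    symbols = table[SYMBOL_COL]
    mapped = symbols.map(mapping)
    hit = mapped.notna()
    table[SYMBOL_COL] = symbols.where(~hit, mapped)
    meta = dict(experiment.meta)
    meta["n_alias_mapped"] = int(hit.sum())
    meta["n_alias_unmapped"] = int((~hit).sum())
    return replace(experiment, table=table, meta=meta)


def map_to_human(
    experiment: ExpressionExperiment, orthologs: OrthologMap
) -> tuple[ExpressionExperiment, list[str]]:
    """Relabel a mouse experiment's probes with human ortholog symbols.

    Human experiments pass through unchanged (empty dropped list).  A mouse
    gene with no ortholog record is dropped and returned in the dropped list.
    When a mouse gene maps to several human symbols its probes are duplicated
    under each; when two mouse genes map to one human symbol both probe sets
    are retained — the single gene-level value emerges later at probe
    collapse.
    """
    if experiment.species != "mouse":
        return experiment, []

    table = experiment.table
    pairs = (
        orthologs.frame[["mouse_symbol", "human_symbol"]]
        .drop_duplicates()
        .sort_values(["mouse_symbol", "human_symbol"])
    )
    mapped = table.merge(
        pairs, left_on=SYMBOL_COL, right_on="mouse_symbol", how="inner"
    )
    dropped = sorted(set(table[SYMBOL_COL]) - set(pairs["mouse_symbol"]))
    if mapped.empty:
        raise InputError(
            f"{experiment.experiment_id}: no genes remain after ortholog mapping"
        )
    mapped[SYMBOL_COL] = mapped["human_symbol"]
    # one mouse gene → several human symbols duplicates its probes; suffix the
    # copies so probe_ids stay unique within the experiment
    dup = mapped.duplicated(subset=PROBE_COL, keep="first")
    if dup.any():
        mapped.loc[dup, PROBE_COL] = (
            mapped.loc[dup, PROBE_COL].astype(str) + "@" + mapped.loc[dup, SYMBOL_COL]
        )
    mapped = mapped.drop(columns=["mouse_symbol", "human_symbol"]).reset_index(drop=True)
    meta = dict(experiment.meta)
    meta["n_unmapped_orthologs"] = len(dropped)
    new = replace(experiment, species="human", table=mapped, meta=meta)
    return new, sorted(dropped)


def build_common_universe(gene_sets: Mapping[str, Iterable[str]]) -> GeneUniverse:
    """Intersect per-experiment human-space gene sets into the common universe.

    Order-invariant in the experiments; the universe is stored sorted.  Raises
    :class:`InputError` if the intersection is empty.
    """
    if not gene_sets:
        raise InputError("no experiments supplied to build_common_universe")
    sets = {exp_id: set(genes) for exp_id, genes in gene_sets.items()}
    for exp_id, s in sets.items():
        if not s:
            raise InputError(f"experiment {exp_id!r} contributes no genes")
    universe: set[str] = set.intersection(*sets.values())
    if not universe:
        raise InputError(
            "empty common universe: no gene is present in every experiment"
        )
    dropped = {
        exp_id: tuple(sorted(s - universe)) for exp_id, s in sorted(sets.items())
    }
    return GeneUniverse(genes=tuple(sorted(universe)), dropped=dropped)
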
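"""Synthetic multi-platform, two-species regeneration studies with a planted
shared signature.

The generator emulates the design of the real meta-analysis: k independent
two-group experiments (one mouse-labelled by default, the rest human) over a
shared universe of orthologous genes, with platform-specific probe
multiplicity, log2-normal intensity noise, and a planted set of S genes
carrying a common positive log2 effect in the high-regeneration group of
every experiment.  Matching alias, ortholog and term-database fixtures are
produced alongside, so the whole pipeline — canonicalization, ortholog
mapping, probe collapse, ranking, overlap, enrichment — is exercised without
any external download.

Everything is driven by a single integer seed: identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .ingest import (
    GROUP_HIGH,
    GROUP_LOW,
    PROBE_COL,
    SYMBOL_COL,
    AliasTable,
    ExpressionExperiment,
    OrthologMap,
)
from .enrichment import Term, TermDatabase
from .ranking import SignatureList

# fraction of genes whose expression table carries a legacy alias symbol
ALIAS_FRACTION = 0.10
# decoy term count and size range for the synthetic term database
N_DECOY_TERMS = 20
DECOY_SIZE_RANGE = (10, 50)
PLANTED_TERM_ID = "T000"
PLANTED_TERM_NAME = "planted_shared_regeneration_signature"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic study.

    Defaults mirror the three-experiment design of the real analysis at desk
    scale: one mouse and two human experiments over a shared orthologous
    universe, a planted signature well separated from the noise floor, and
    microarray-like probe multiplicity.
    """

    universe_size: int = 5000  # U: orthologous genes in the shared universe
    n_experiments: int = 3  # k
    n_planted: int = 20  # S: genes carrying the shared signature
    effect_log2: float = 3.0  # delta: planted shift, log2 scale
    noise_sd: float = 1.0  # sigma: per-sample log2-intensity noise SD
    probes_per_gene_range: tuple[int, int] = (1, 3)
    samples_per_group: int = 3
    frac_unmapped: float = 0.05  # mouse genes lacking an ortholog record
    frac_many_to_one: float = 0.05  # human genes receiving two mouse paralogs
    seed: int = 0
    mouse_experiments: tuple[int, ...] = (0,)  # indices of mouse-labelled experiments

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ConfigError("universe_size must be >= 1")
        if not 0 <= self.n_planted <= self.universe_size:
            raise ConfigError("n_planted must satisfy 0 <= n_planted <= universe_size")
        if self.n_experiments < 1:
            raise ConfigError("n_experiments must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        lo, hi = self.probes_per_gene_range
        if lo < 1 or hi < lo:
            raise ConfigError("probes_per_gene_range must be an increasing range with min >= 1")
        if self.samples_per_group < 1:
            raise ConfigError("samples_per_group must be >= 1")
        for name in ("frac_unmapped", "frac_many_to_one"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        bad = [i for i in self.mouse_experiments if not 0 <= i < self.n_experiments]
        if bad:
            raise ConfigError(f"mouse_experiments indices out of range: {bad}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["probes_per_gene_range"] = list(self.probes_per_gene_range)
        d["mouse_experiments"] = list(self.mouse_experiments)
        return d


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated study, for recovery scoring."""

    planted_genes: frozenset
    config: SyntheticConfig
    per_experiment_effect: tuple[float, ...]
    universe: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "planted_genes": sorted(self.planted_genes),
            "config": self.config.to_dict(),
            "per_experiment_effect": list(self.per_experiment_effect),
        }


@dataclass(frozen=True)
class RecoveryMetrics:
    """Recall/precision of a signature against the planted truth.

    ``precision`` is ``None`` (undefined) for an empty signature.
    """

    recall: float
    precision: float | None
    recovered: frozenset


class SyntheticStudy(NamedTuple):
    experiments: list[ExpressionExperiment]
    aliases: AliasTable
    orthologs: OrthologMap
    terms: TermDatabase
    truth: SyntheticTruth


def _human_symbol(i: int) -> str:
    return f"GENE{i:05d}"


def _mouse_symbol(i: int) -> str:
    return f"Gene{i:05d}"


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate k experiments, annotation fixtures and the planted truth.

    Mouse-labelled experiments use mouse symbols that the returned ortholog
    map sends back to the human universe; a configured fraction of mouse
    genes has no ortholog record (these never include planted genes, so the
    planted set always survives into the common universe).  The term database
    contains one term equal to the planted set plus seeded decoy terms drawn
    from non-planted genes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    u = cfg.universe_size

    human = np.array([_human_symbol(i) for i in range(1, u + 1)])
    planted_idx = np.sort(rng.choice(u, size=cfg.n_planted, replace=False))
    planted_mask = np.zeros(u, dtype=bool)
    planted_mask[planted_idx] = True

    # ortholog bookkeeping: unmapped mouse genes never include planted genes
    n_unmapped = int(round(cfg.frac_unmapped * u))
    non_planted = np.flatnonzero(~planted_mask)
    n_unmapped = min(n_unmapped, non_planted.size)
    unmapped_idx = rng.choice(non_planted, size=n_unmapped, replace=False)
    mapped_mask = np.ones(u, dtype=bool)
    mapped_mask[unmapped_idx] = False
    mapped_idx = np.flatnonzero(mapped_mask)

    n_m2o = int(round(cfg.frac_many_to_one * u))
    n_m2o = min(n_m2o, mapped_idx.size)
    m2o_idx = np.sort(rng.choice(mapped_idx, size=n_m2o, replace=False))
    m2o_set = set(m2o_idx.tolist())

    ortho_rows = []
    for i in mapped_idx:
        ortho_rows.append((_mouse_symbol(i + 1), human[i], "fixture"))
        if i in m2o_set:
            ortho_rows.append((_mouse_symbol(i + 1) + "b", human[i], "fixture"))
    orthologs = OrthologMap(
        pd.DataFrame(ortho_rows, columns=list(OrthologMap.COLUMNS))
    )

    # alias fixtures: legacy LOC-style (human) / Gm-style (mouse) symbols
    n_alias = int(round(ALIAS_FRACTION * u))
    alias_h_idx = np.sort(rng.choice(u, size=n_alias, replace=False))
    alias_m_idx = np.sort(rng.choice(mapped_idx, size=min(n_alias, mapped_idx.size), replace=False))
    human_alias = {i: f"LOC9{i + 1:05d}" for i in alias_h_idx.tolist()}
    mouse_alias = {i: f"Gm9{i + 1:05d}" for i in alias_m_idx.tolist()}
    alias_rows = [(human_alias[i], human[i], "human") for i in sorted(human_alias)]
    alias_rows += [(mouse_alias[i], _mouse_symbol(i + 1), "mouse") for i in sorted(mouse_alias)]
    aliases = AliasTable(pd.DataFrame(alias_rows, columns=list(AliasTable.COLUMNS)))

    # term database: the planted set plus seeded decoys from non-planted genes
    terms = [
        Term(
            term_id=PLANTED_TERM_ID,
            name=PLANTED_TERM_NAME,
            genes=frozenset(human[planted_idx].tolist()),
        )
    ] if cfg.n_planted > 0 else []
    lo_t, hi_t = DECOY_SIZE_RANGE
    for t in range(1, N_DECOY_TERMS + 1):
        size = int(rng.integers(lo_t, hi_t + 1))
        size = min(size, non_planted.size)
        if size == 0:
            break
        members = rng.choice(non_planted, size=size, replace=False)
        terms.append(
            Term(
                term_id=f"T{t:03d}",
                name=f"decoy_pathway_{t:02d}",
                genes=frozenset(human[np.sort(members)].tolist()),
            )
        )
    term_db = TermDatabase(terms=tuple(terms))

    experiments = [
        _generate_experiment(
            cfg,
            exp_index=e,
            rng=rng,
            human=human,
            planted_mask=planted_mask,
            mapped_idx=mapped_idx,
            m2o_set=m2o_set,
            human_alias=human_alias,
            mouse_alias=mouse_alias,
        )
        for e in range(cfg.n_experiments)
    ]

    truth = SyntheticTruth(
        planted_genes=frozenset(human[planted_idx].tolist()),
        config=cfg,
        per_experiment_effect=tuple([cfg.effect_log2] * cfg.n_experiments),
        universe=tuple(human.tolist()),
    )
    return SyntheticStudy(experiments, aliases, orthologs, term_db, truth)


def _generate_experiment(
    cfg: SyntheticConfig,
    exp_index: int,
    rng: np.random.Generator,
    human: np.ndarray,
    planted_mask: np.ndarray,
    mapped_idx: np.ndarray,
    m2o_set: set,
    human_alias: dict,
    mouse_alias: dict,
) -> ExpressionExperiment:
    """One two-group experiment; log2-normal intensities, planted mean shift."""
    is_mouse = exp_index in cfg.mouse_experiments
    exp_id = f"exp{exp_index + 1}_{'mouse' if is_mouse else 'human'}"

    if is_mouse:
        # all mouse genes (the unmapped fraction is dropped later at ortholog
        # mapping) plus paralogs for many-to-one human targets
        gene_idx = list(range(len(human))) + sorted(m2o_set)
        symbols = [
            mouse_alias.get(i, _mouse_symbol(i + 1)) for i in range(len(human))
        ] + [_mouse_symbol(i + 1) + "b" for i in sorted(m2o_set)]
        platform = "synthetic-mouse-array"
        species = "mouse"
    else:
        gene_idx = list(range(len(human)))
        symbols = [human_alias.get(i, human[i]) for i in gene_idx]
        platform = "synthetic-human-array"
        species = "human"

    gene_idx_arr = np.asarray(gene_idx)
    n_genes = gene_idx_arr.size
    lo, hi = cfg.probes_per_gene_range
    n_probes_per_gene = rng.integers(lo, hi + 1, size=n_genes)
    probe_gene = np.repeat(np.arange(n_genes), n_probes_per_gene)
    total_probes = probe_gene.size

    baseline = rng.normal(8.0, 2.0, size=n_genes)  # platform-specific gene level
    probe_offset = rng.normal(0.0, 0.25, size=total_probes)
    effect = np.where(planted_mask[gene_idx_arr], cfg.effect_log2, 0.0)

    spg = cfg.samples_per_group
    n_samples = 2 * spg
    is_high = np.concatenate([np.ones(spg), np.zeros(spg)])
    noise = (
        rng.normal(0.0, cfg.noise_sd, size=(total_probes, n_samples))
        if cfg.noise_sd > 0
        else np.zeros((total_probes, n_samples))
    )
    log2_int = (
        baseline[probe_gene][:, None]
        + probe_offset[:, None]
        + np.outer(effect[probe_gene], is_high)
        + noise
    )
    intensities = np.exp2(log2_int)

    sample_names = [f"{exp_id}_hi{j + 1}" for j in range(spg)] + [
        f"{exp_id}_lo{j + 1}" for j in range(spg)
    ]
    design = {
        name: (GROUP_HIGH if j < spg else GROUP_LOW)
        for j, name in enumerate(sample_names)
    }
    table = pd.DataFrame(
        {
            PROBE_COL: [f"{exp_id}_p{j + 1:06d}" for j in range(total_probes)],
            SYMBOL_COL: np.asarray(symbols, dtype=object)[probe_gene],
        }
    )
    for col, values in zip(sample_names, intensities.T):
        table[col] = values
    return ExpressionExperiment(
        experiment_id=exp_id,
        species=species,
        platform=platform,
        table=table,
        design=design,
        meta={"synthetic": True, "exp_index": exp_index},
    )


def evaluate_recovery(
    signature: SignatureList | Iterable[str], truth: SyntheticTruth
) -> RecoveryMetrics:
    """Score a signature against the planted truth.

    recall = |signature ∩ planted| / S; precision = |signature ∩ planted| /
    |signature| (undefined, reported as ``None``, for an empty signature).
    """
    genes = list(signature.genes) if isinstance(signature, SignatureList) else list(signature)
    gene_set = set(genes)
    universe = set(truth.universe)
    if gene_set and not (gene_set & universe):
        raise InputError("signature and truth universes are disjoint")
    recovered = frozenset(gene_set & truth.planted_genes)
    s = len(truth.planted_genes)
    recall = len(recovered) / s if s else 0.0
    precision = len(recovered) / len(gene_set) if gene_set else None
    return RecoveryMetrics(recall=recall, precision=precision, recovered=recovered)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict:
    """Write a generated study as plain-text fixtures (TSV/GMT/JSON).

    Returns a manifest of the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"experiments": []}
    for exp in study.experiments:
        expr_path = out / f"{exp.experiment_id}.expression.tsv"
        design_path = out / f"{exp.experiment_id}.design.tsv"
        exp.table.to_csv(expr_path, sep="\t", index=False)
        pd.DataFrame(
            {"sample": list(exp.design), "group": list(exp.design.values())}
        ).to_csv(design_path, sep="\t", index=False)
        manifest["experiments"].append(
            {
                "experiment_id": exp.experiment_id,
                "species": exp.species,
                "platform": exp.platform,
                "expression": str(expr_path),
                "design": str(design_path),
            }
        )
    alias_path = out / "aliases.tsv"
    ortho_path = out / "orthologs.tsv"
    terms_path = out / "terms.gmt"
    truth_path = out / "truth.json"
    study.aliases.to_tsv(alias_path)
    study.orthologs.to_tsv(ortho_path)
    study.terms.to_gmt(terms_path)
    truth_path.write_text(json.dumps(study.truth.to_dict(), indent=2, sort_keys=True) + "\n")
    manifest.update(
        aliases=str(alias_path),
        orthologs=str(ortho_path),
        terms=str(terms_path),
        truth=str(truth_path),
    )
    return manifest
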
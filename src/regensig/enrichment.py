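"""Fisher's-exact term enrichment with Benjamini–Hochberg and Bonferroni
adjustment, plus GMT gene-set IO.

For a signature of n genes drawn from a universe of U genes and a term with K
universe members, the 2×2 table is

    a = |signature ∩ term|    b = |signature \\ term|
    c = |term \\ signature|   d = U − a − b − c

and the one-sided (over-representation) p-value is the hypergeometric upper
tail P(X ≥ a) with X ~ Hypergeom(U, K, n) — Fisher's exact test in its
enrichment direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParseError
from .ingest import GeneUniverse
from .ranking import SignatureList

Adjustment = Literal["bh", "bonferroni", "both"]
Alternative = Literal["greater", "two-sided"]


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"term {self.term_id!r} has no member genes")


@dataclass(frozen=True)
class TermDatabase:
    """A collection of gene-set terms (GMT-style)."""

    terms: tuple[Term, ...]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "TermDatabase":
        """Read a GMT file: term_id TAB description TAB gene TAB gene ..."""
        terms = []
        seen = set()
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs id, description and >=1 gene")
            term_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term_id in seen:
                raise ParseError(f"{path}:{ln}: duplicate term id {term_id!r}")
            seen.add(term_id)
            terms.append(Term(term_id=term_id, name=name, genes=frozenset(genes)))
        if not terms:
            raise ParseError(f"{path}: empty GMT file")
        return cls(terms=tuple(terms))

    def to_gmt(self, path: str | Path) -> None:
        lines = [
            "\t".join([t.term_id, t.name, *sorted(t.genes)]) for t in self.terms
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term 2×2 counts, odds ratios and raw/adjusted p-values.

    ``table`` is sorted by raw p (ties by term_id) with columns term_id,
    term_name, a, b, c, d, odds_ratio, p_value and, depending on the
    adjustment requested, p_bh and/or p_bonferroni.  ``skipped`` lists terms
    with no members inside the universe.
    """

    table: pd.DataFrame
    universe_size: int
    skipped: tuple[str, ...] = ()

    def top_term(self) -> str:
        return str(self.table.iloc[0]["term_id"])


def fisher_greater_pvalue(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p for over-representation: P(X >= a), hypergeometric.

    X counts term genes in a draw of a+b from a universe of a+b+c+d containing
    a+c term genes.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise InputError(f"table cell {name} is negative")
    total = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, total, a + c, a + b))


def fisher_enrichment(
    signature: SignatureList | Iterable[str],
    terms: TermDatabase,
    universe: GeneUniverse,
    adjustment: Adjustment = "both",
    alternative: Alternative = "greater",
) -> EnrichmentResult:
    """Fisher's-exact enrichment of a gene list against each term.

    Term membership is restricted to the universe before testing; terms with
    no universe members are skipped and reported.  BH adjustment is computed
    over all tested terms with step-up monotonicity; Bonferroni is
    min(1, p·m).
    """
    genes = set(signature.genes) if isinstance(signature, SignatureList) else set(signature)
    uni = universe.as_set()
    outside = genes - uni
    if outside:
        raise InputError(
            f"signature gene(s) outside the universe, e.g. {sorted(outside)[:3]}"
        )
    if not genes:
        raise InputError("empty signature: nothing to enrich")

    rows = []
    skipped = []
    u_size = universe.size
    n = len(genes)
    for term in terms:
        members = term.genes & uni
        if not members:
            skipped.append(term.term_id)
            continue
        a = len(genes & members)
        b = n - a
        c = len(members) - a
        d = u_size - a - b - c
        if alternative == "greater":
            p = fisher_greater_pvalue(a, b, c, d)
        else:
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.name,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p_value": float(p),
            }
        )
    if not rows:
        raise InputError("no term has members inside the universe")
    table = pd.DataFrame(rows)
    m = len(table)
    if adjustment in ("bh", "both"):
        table["p_bh"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    if adjustment in ("bonferroni", "both"):
        table["p_bonferroni"] = np.minimum(1.0, table["p_value"].to_numpy() * m)
    table = table.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(table=table, universe_size=u_size, skipped=tuple(skipped))
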
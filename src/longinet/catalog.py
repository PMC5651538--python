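"""Curation of aging-associated genes (AAGs) across organisms.

Aging-associated genes are collected per organism — human (HS) plus four
model organisms: *C. elegans* (CE), *D. melanogaster* (DM), *M. musculus*
(MM) and *S. cerevisiae* (SC). Non-human lists are mapped to human gene
symbols through an ortholog table, pooled into a single catalogue with
per-organism evidence flags, and filtered by how many non-human organisms
support each gene. Overlap between gene sets is tested with a one-sided
(over-representation) hypergeometric test, equivalent to the one-sided
Fisher's exact test on the 2x2 table.

Gene identity is the upper-cased symbol string; no alias resolution is
attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

ORGANISMS = ("HS", "CE", "DM", "MM", "SC")
NON_HUMAN = ("CE", "DM", "MM", "SC")

#: NCBI protein-coding gene count used as the default background universe.
DEFAULT_UNIVERSE_SIZE = 20_462


def _normalize_symbol(symbol: str) -> str:
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


@dataclass(frozen=True)
class OrganismGeneList:
    """A set of gene symbols with experimental aging evidence in one organism."""

    organism: str
    genes: frozenset[str]

    def __init__(self, organism: str, genes: Iterable[str]):
        organism = str(organism).strip().upper()
        if organism not in ORGANISMS:
            raise ValueError(
                f"unknown organism code {organism!r}; expected one of {ORGANISMS}"
            )
        object.__setattr__(self, "organism", organism)
        object.__setattr__(
            self, "genes", frozenset(_normalize_symbol(g) for g in genes)
        )

    def __len__(self) -> int:
        return len(self.genes)


class OrthologTable:
    """Mapping from non-human source genes to human gene symbols.

    One source gene may map to several human symbols (one-to-many is kept;
    deduplication happens at the catalogue level).
    """

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        mapping: dict[tuple[str, str], set[str]] = {}
        n = 0
        for organism, source_gene, human_symbol in rows:
            organism = str(organism).strip().upper()
            if organism not in NON_HUMAN:
                raise ValueError(
                    f"ortholog table organism {organism!r} not in {NON_HUMAN}"
                )
            source = _normalize_symbol(source_gene)
            human = _normalize_symbol(human_symbol)
            mapping.setdefault((organism, source), set()).add(human)
            n += 1
        self._mapping = mapping
        self.n_rows = n

    def lookup(self, organism: str, source_gene: str) -> set[str]:
        key = (organism.strip().upper(), _normalize_symbol(source_gene))
        return set(self._mapping.get(key, ()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (org, src, human)
            for (org, src), humans in sorted(self._mapping.items())
            for human in sorted(humans)
        ]
        return pd.DataFrame(rows, columns=["organism", "source_gene", "human_symbol"])


@dataclass
class AAGCatalog:
    """Pooled aging-associated gene catalogue with per-organism evidence."""

    evidence: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, ev in self.evidence.items():
            if not ev:
                raise ValueError(f"gene {sym!r} has empty evidence")
            bad = set(ev) - set(ORGANISMS)
            if bad:
                raise ValueError(f"gene {sym!r} has unknown evidence codes {bad}")

    def organism_support_count(self, symbol: str) -> int:
        """Number of *non-human* organisms supporting a gene (HS not counted)."""
        return len(self.evidence[symbol] & set(NON_HUMAN))

    @property
    def symbols(self) -> set[str]:
        return set(self.evidence)

    def __len__(self) -> int:
        return len(self.evidence)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                sym,
                ";".join(o for o in ORGANISMS if o in ev),
                len(ev & set(NON_HUMAN)),
            )
            for sym, ev in sorted(self.evidence.items())
        ]
        return pd.DataFrame(rows, columns=["symbol", "evidence", "organism_support"])


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided hypergeometric overlap test between two gene sets."""

    overlap: int
    size_a: int
    size_b: int
    universe_size: int
    p_value: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.size_a, self.size_b):
            raise ValueError("overlap exceeds the smaller set")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def map_to_human_orthologs(
    gene_list: OrganismGeneList, table: OrthologTable
) -> set[str]:
    """Map a non-human gene list to the union of its human ortholog symbols.

    Genes with no mapping are dropped; one-to-many mappings expand to all
    human symbols; the result is deduplicated.
    """
    if gene_list.organism == "HS":
        raise ValueError("human lists pass through unchanged; do not map them")
    out: set[str] = set()
    for gene in gene_list.genes:
        out |= table.lookup(gene_list.organism, gene)
    return out


def build_catalog(
    human_list: OrganismGeneList | Iterable[str],
    orth_sets: Mapping[str, Iterable[str]],
) -> AAGCatalog:
    """Pool a human gene list and per-organism mapped human-symbol sets.

    Each symbol's evidence is the set of organisms whose (mapped) list
    contains it; the human list contributes HS evidence.
    """
    if isinstance(human_list, OrganismGeneList):
        if human_list.organism != "HS":
            raise ValueError("human_list must carry organism code HS")
        human_genes = set(human_list.genes)
    else:
        human_genes = {_normalize_symbol(g) for g in human_list}

    bad = set(orth_sets) - set(NON_HUMAN)
    if bad:
        raise ValueError(f"orth_sets keyed by unknown organisms {bad}")

    evidence: dict[str, set[str]] = {}
    for sym in human_genes:
        evidence.setdefault(sym, set()).add("HS")
    for organism, symbols in orth_sets.items():
        for sym in symbols:
            evidence.setdefault(_normalize_symbol(sym), set()).add(organism)
    return AAGCatalog({sym: frozenset(ev) for sym, ev in evidence.items()})


def filter_by_organism_support(
    catalog: AAGCatalog, min_organisms: int = 2
) -> set[str]:
    """Symbols supported by at least ``min_organisms`` non-human organisms.

    HS evidence never counts toward support: the filter selects genes whose
    aging association replicates across model organisms.
    """
    if not 1 <= min_organisms <= len(NON_HUMAN):
        raise ValueError(f"min_organisms must be in [1, {len(NON_HUMAN)}]")
    return {
        sym
        for sym in catalog.evidence
        if catalog.organism_support_count(sym) >= min_organisms
    }


def pool_aag_sets(orthologous_set: Iterable[str], human_set: Iterable[str]) -> set[str]:
    """Union of the cross-organism and human aging-gene sets."""
    return set(orthologous_set) | set(human_set)


def overlap_enrichment(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> EnrichmentResult:
    """Over-representation test for the overlap of two gene sets.

    P(X >= overlap) where X is hypergeometric: |A| draws from a universe of
    ``universe_size`` genes containing |B| successes. Symmetric in A and B.
    The odds ratio is the sample odds ratio of the 2x2 table (``inf`` when a
    zero cell makes it undefined).
    """
    a, b = set(set_a), set(set_b)
    overlap = len(a & b)
    n_a, n_b, n = len(a), len(b), int(universe_size)
    if n < n_a + n_b - overlap:
        raise ValueError(
            f"universe size {n} smaller than |A ∪ B| = {n_a + n_b - overlap}"
        )
    p = float(stats.hypergeom.sf(overlap - 1, n, n_b, n_a))
    p = min(p, 1.0)
    only_a = n_a - overlap
    only_b = n_b - overlap
    neither = n - n_a - n_b + overlap
    if only_a * only_b == 0:
        odds = float("inf") if overlap * neither > 0 else 0.0
    else:
        odds = overlap * neither / (only_a * only_b)
    return EnrichmentResult(overlap, n_a, n_b, n, p, odds)


def enrich_gene_sets(
    genes: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in named gene sets.

    Returns a frame (term, term_size, overlap, p_value, q_value) with
    Benjamini-Hochberg q-values across all terms.
    """
    from .scoring import bh_adjust

    query = {_normalize_symbol(g) for g in genes}
    columns = ["term", "term_size", "overlap", "p_value", "q_value"]
    if not query:
        warnings.warn("empty query gene set; returning empty enrichment table")
        return pd.DataFrame(columns=columns)

    rows = []
    for term, members in collections.items():
        member_set = {_normalize_symbol(g) for g in members}
        if not member_set:
            raise ValueError(f"collection term {term!r} has an empty gene set")
        res = overlap_enrichment(query, member_set, universe_size)
        rows.append((term, len(member_set), res.overlap, res.p_value))
    frame = pd.DataFrame(rows, columns=columns[:-1])
    frame["q_value"] = bh_adjust(frame["p_value"].to_numpy())
    return frame.sort_values(["p_value", "term"], ignore_index=True)
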
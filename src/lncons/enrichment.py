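"""Hypergeometric GO enrichment of co-expression modules and transfer of
enriched terms to the modules' lncRNAs, optionally supported by
lncRNA-protein interaction scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import ModulePartition

logger = logging.getLogger(__name__)


@dataclass
class GeneTermMap:
    """term_id -> gene set, with the background universe of genes."""

    term_genes: dict[str, set[str]]
    universe: set[str]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.term_genes.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"term {term} has genes outside the universe: {sorted(extra)[:5]}"
                )

    @classmethod
    def from_tsv(cls, path, universe: Iterable[str] | None = None) -> "GeneTermMap":
        """Read a gene->term TSV with columns gene_id, term_id[, term_name].
        When *universe* is given, mappings outside it are dropped; otherwise
        the universe is the set of mapped genes."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "term_id"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: needs columns {sorted(required)}")
        term_genes: dict[str, set[str]] = {}
        term_names: dict[str, str] = {}
        uni = set(universe) if universe is not None else set(df["gene_id"])
        for _, row in df.iterrows():
            if row["gene_id"] not in uni:
                continue
            term_genes.setdefault(row["term_id"], set()).add(row["gene_id"])
            if "term_name" in df.columns and pd.notna(row.get("term_name")):
                term_names[row["term_id"]] = row["term_name"]
        return cls(term_genes=term_genes, universe=uni, term_names=term_names)


@dataclass
class EnrichmentResult:
    module: str
    term_id: str
    k: int  # term genes in the module
    n: int  # module genes in the universe
    K: int  # term genes in the universe
    N: int  # universe size
    p_value: float
    adjusted_p: float | None = None
    significant: bool = False


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of drawing *k* or
    more term genes in a module of *n* genes, given *K* term genes among
    *N* universe genes."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_module(
    module_genes: Iterable[str],
    gene_terms: GeneTermMap,
    alpha: float = 0.05,
    correction: str = "none",
    module: str = "",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test of every term with >= 1 gene.

    Module genes outside the universe are dropped with a warning. Results
    are sorted by ascending p; significance uses raw p < alpha, or BH
    adjusted p < alpha when ``correction='BH'``.
    """
    if not gene_terms.universe:
        raise ValueError("empty gene universe")
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    genes = set(module_genes)
    outside = genes - gene_terms.universe
    if outside:
        logger.warning(
            "%d module genes outside the universe dropped: %s...",
            len(outside), sorted(outside)[:3],
        )
        genes -= outside
    N = len(gene_terms.universe)
    n = len(genes)
    results = []
    for term, term_set in sorted(gene_terms.term_genes.items()):
        K = len(term_set)
        if K < 1:
            continue
        k = len(genes & term_set)
        p = hypergeom_test(k, n, K, N)
        results.append(
            EnrichmentResult(module=module, term_id=term, k=k, n=n, K=K, N=N, p_value=p)
        )
    if correction == "BH" and results:
        _, adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
            r.significant = a < alpha
    else:
        for r in results:
            r.significant = r.p_value < alpha
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrich_partition(
    partition: ModulePartition,
    gene_terms: GeneTermMap,
    alpha: float = 0.05,
    correction: str = "none",
    gene_filter: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Enrichment of every module's (optionally filtered) gene set.

    *gene_filter* restricts the tested genes, e.g. to protein-coding genes
    only, matching the practice of testing module PCGs and transferring the
    terms to the module's lncRNAs."""
    allowed = set(gene_filter) if gene_filter is not None else None
    out: list[EnrichmentResult] = []
    for module, members in sorted(partition.modules.items()):
        genes = [g for g in members if allowed is None or g in allowed]
        genes = [g for g in genes if g in gene_terms.universe]
        if not genes:
            continue
        out.extend(
            enrich_module(genes, gene_terms, alpha=alpha, correction=correction,
                          module=module)
        )
    return out


@dataclass
class InteractionScoreTable:
    """(lncRNA id, protein-coding gene id) -> predicted interaction score,
    on a 0-100 scale; scores above *threshold* count as supported."""

    scores: dict[tuple[str, str], float]
    threshold: float = 50.0

    @classmethod
    def from_tsv(cls, path, threshold: float = 50.0) -> "InteractionScoreTable":
        df = pd.read_csv(path, sep="\t", dtype={"lncrna_id": str, "gene_id": str})
        scores = {
            (row["lncrna_id"], row["gene_id"]): float(row["score"])
            for _, row in df.iterrows()
        }
        return cls(scores=scores, threshold=threshold)

    def supported(self, lncrna_id: str, gene_id: str) -> bool:
        return self.scores.get((lncrna_id, gene_id), float("-inf")) > self.threshold


@dataclass
class LncRnaAnnotation:
    lncrna_id: str
    module: str
    term_id: str
    p_value: float
    interaction_supported: bool | None = None  # None when no scores supplied


def annotate_lncrnas(
    partition: ModulePartition,
    results: Iterable[EnrichmentResult],
    lncrna_ids: Iterable[str],
    gene_terms: GeneTermMap,
    interactions: InteractionScoreTable | None = None,
) -> list[LncRnaAnnotation]:
    """Transfer each module's significant terms to the module's lncRNAs.

    With interaction scores, a (lncRNA, term) annotation is flagged
    interaction-supported when the lncRNA's score with at least one module
    gene annotated to that term exceeds the threshold.
    """
    sig_by_module: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        if r.significant:
            sig_by_module.setdefault(r.module, []).append(r)
    lnc_set = set(lncrna_ids)
    modules = partition.modules
    out: list[LncRnaAnnotation] = []
    for module, members in sorted(modules.items()):
        lncs = sorted(m for m in members if m in lnc_set)
        for r in sig_by_module.get(module, []):
            term_members = gene_terms.term_genes.get(r.term_id, set()) & set(members)
            for lnc in lncs:
                flag: bool | None = None
                if interactions is not None:
                    flag = any(
                        interactions.supported(lnc, g) for g in term_members
                    )
                out.append(
                    LncRnaAnnotation(
                        lncrna_id=lnc,
                        module=module,
                        term_id=r.term_id,
                        p_value=r.p_value,
                        interaction_supported=flag,
                    )
                )
    return out


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in results],
        columns=["module", "term_id", "k", "n", "K", "N", "p_value",
                 "adjusted_p", "significant"],
    )
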
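"""Hypergeometric gene-set enrichment with multiplicity correction.

Terms are flat gene sets (no ontology propagation). For a query set of n
genes from a universe of N, a term covering K universe genes with k of
them in the query gets the upper-tail hypergeometric probability

    p_raw = P(X >= k),  X ~ Hypergeom(N, K, n),

and p-values are corrected across all tested terms with Benjamini-
Hochberg (default) or Bonferroni. The overlap analysis compares the
enriched-term sets of two queries (e.g. herb targets vs disease genes)
run against the same annotation collection.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term (GO-like process or KEGG-like pathway) as a gene set."""

    term_id: str
    term_name: str
    genes: frozenset[str]
    namespace: str = "process"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no genes")
        if self.namespace not in ("process", "pathway"):
            raise ValueError(f"unknown namespace {self.namespace!r}")


def hypergeometric_enrichment(
    query: Iterable[str],
    annotations: Sequence[AnnotationSet],
    universe: Iterable[str],
    *,
    method: str = "bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set against terms.

    Returns a DataFrame sorted by adjusted p ascending with columns
    ``term_id, term_name, k, K, n, N, p_raw, p_adj``. ``method`` is
    ``"bh"`` (Benjamini-Hochberg, default) or ``"bonferroni"``.
    """
    universe = set(universe)
    query = set(query)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    for ann in annotations:
        if not ann.genes <= universe:
            raise ValueError(f"term {ann.term_id!r} not contained in the universe")
    if method not in ("bh", "bonferroni"):
        raise ValueError("method must be 'bh' or 'bonferroni'")
    n_total = len(universe)
    n_query = len(query)
    rows = []
    for ann in annotations:
        k = len(ann.genes & query)
        big_k = len(ann.genes)
        p_raw = float(hypergeom.sf(k - 1, n_total, big_k, n_query))
        rows.append((ann.term_id, ann.term_name, k, big_k, n_query, n_total, p_raw))
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_raw"]
    )
    if len(df):
        mt_method = "fdr_bh" if method == "bh" else "bonferroni"
        df["p_adj"] = multipletests(df["p_raw"], method=mt_method)[1]
    else:
        df["p_adj"] = []
    return df.sort_values(
        ["p_adj", "p_raw", "term_id"], ignore_index=True
    )


def enriched_terms(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Term ids with adjusted p strictly below alpha."""
    if len(results) == 0:
        return set()
    return set(results.loc[results["p_adj"] < alpha, "term_id"])


def overlap_analysis(
    herb_terms: Iterable[str], disease_terms: Iterable[str]
) -> dict[str, list[str]]:
    """Shared and side-exclusive enriched terms of two analyses."""
    a, b = set(herb_terms), set(disease_terms)
    return {
        "shared": sorted(a & b),
        "herb_only": sorted(a - b),
        "disease_only": sorted(b - a),
    }


# ---------------------------------------------------------------------------
# File interfaces


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    """GMT: one term per line, ``term_id<TAB>term_name<TAB>gene...``."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        out.append(
            AnnotationSet(
                term_id=parts[0],
                term_name=parts[1],
                genes=frozenset(g for g in parts[2:] if g),
            )
        )
    return out


def write_gmt(annotations: Iterable[AnnotationSet], path: str | Path) -> None:
    lines = [
        "\t".join([a.term_id, a.term_name, *sorted(a.genes)])
        for a in annotations
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def write_overlap_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
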
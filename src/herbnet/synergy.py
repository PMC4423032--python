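"""Network-based multicomponent synergy scoring of compound and herb pairs.

The synergy of two agents (compounds, or herbs summarizing their
compounds) is evaluated on a disease-related background network as

    total = topology_score * agent_score.

The topology score measures how tightly the two agents' target sets
interlock on the background network. Each node carries an *importance*,
the min-max-normalized mean of three centralities (betweenness, closeness,
PageRank with damping 0.85). The directional score from target set T1
toward T2 is the importance-weighted mean of an exponential decay of each
T1 member's distance to the nearest T2 member,

    TS(T1 -> T2) = sum_{i in T1} imp(i) exp(-minspl(i, T2)) / sum imp(i),

and the topology score is the average of the two directions. Identical
sets score 1; sets in different components score 0.

The agent score is a phenotype-similarity term, cosine similarity mapped
to [0, 1]; with no phenotype data (the default here) it is 1 and the total
reduces to the topology score. This combining rule is a reconstruction of
the published NIMS design from its stated ingredients (topology score,
agent score, betweenness/closeness/PageRank); the exact published formula
is not public, so the rule above is fully specified here for
reproducibility.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _minmax(values: dict) -> dict:
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        # all-equal metric carries no ranking information; score everyone 1
        return {k: 1.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def node_importance(
    background: nx.Graph, damping: float = 0.85
) -> pd.DataFrame:
    """Per-node importance on the background network.

    Returns a DataFrame indexed by node with columns ``betweenness``,
    ``closeness``, ``pagerank`` (raw values) and ``importance`` (the mean
    of the three after min-max normalization over nodes). A single-node
    network gets importance 1 by convention.
    """
    nodes = sorted(background.nodes)
    if not nodes:
        raise ValueError("empty background network")
    if len(nodes) == 1:
        return pd.DataFrame(
            {"betweenness": [0.0], "closeness": [0.0], "pagerank": [1.0],
             "importance": [1.0]},
            index=nodes,
        )
    bet = nx.betweenness_centrality(background)
    clo = nx.closeness_centrality(background)
    pr = nx.pagerank(background, alpha=damping)
    nbet, nclo, npr = _minmax(bet), _minmax(clo), _minmax(pr)
    df = pd.DataFrame(
        {
            "betweenness": [bet[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "pagerank": [pr[n] for n in nodes],
            "importance": [
                (nbet[n] + nclo[n] + npr[n]) / 3.0 for n in nodes
            ],
        },
        index=nodes,
    )
    return df


def importance_dict(background: nx.Graph, damping: float = 0.85) -> dict:
    return node_importance(background, damping)["importance"].to_dict()


def _decay(dist: float, kind: str) -> float:
    if math.isinf(dist):
        return 0.0
    if kind == "exp":
        return math.exp(-dist)
    if kind == "inverse":
        return 1.0 / (1.0 + dist)
    raise ValueError(f"unknown decay kind {kind!r}")


def _distance_map(background: nx.Graph, targets: Iterable[str]) -> dict:
    """Distance from every background node to the nearest target (multi-source BFS)."""
    sources = [t for t in targets if t in background]
    if not sources:
        return {}
    return nx.multi_source_dijkstra_path_length(background, sources, weight=None)


def topology_score(
    t1: Iterable[str],
    t2: Iterable[str],
    importance: Mapping[str, float],
    background: nx.Graph,
    *,
    decay: str = "exp",
    _dmap1: Mapping[str, float] | None = None,
    _dmap2: Mapping[str, float] | None = None,
) -> float:
    """Symmetrized importance-weighted distance-decay score of two target sets.

    Both sets must be non-empty subsets of the background nodes. ``_dmap1``
    / ``_dmap2`` accept precomputed nearest-member distance maps (from
    :func:`_distance_map`) when scoring many pairs.
    """
    t1, t2 = sorted(set(t1)), sorted(set(t2))
    if not t1 or not t2:
        raise ValueError("topology score requires non-empty target sets")
    for t in (*t1, *t2):
        if t not in background:
            raise ValueError(f"target {t!r} absent from background network")

    def directional(src: list[str], dmap: Mapping[str, float]) -> float:
        weights = np.array([importance.get(i, 0.0) for i in src])
        if weights.sum() == 0:
            weights = np.ones(len(src))  # uniform fallback for zero-importance sets
        decays = np.array([_decay(dmap.get(i, math.inf), decay) for i in src])
        # clamp: the weighted mean of values in [0,1] can overshoot by eps
        return float(np.clip(weights @ decays / weights.sum(), 0.0, 1.0))

    dmap2 = _dmap2 if _dmap2 is not None else _distance_map(background, t2)
    dmap1 = _dmap1 if _dmap1 is not None else _distance_map(background, t1)
    return 0.5 * (directional(t1, dmap2) + directional(t2, dmap1))


def agent_score(
    pheno_a: np.ndarray | None, pheno_b: np.ndarray | None
) -> float:
    """Phenotype-similarity score in [0, 1]: (1 + cosine) / 2.

    Absent or all-zero phenotype vectors give the neutral default 1.0,
    reducing the total synergy to its topology component.
    """
    if pheno_a is None or pheno_b is None:
        return 1.0
    a = np.asarray(pheno_a, dtype=float)
    b = np.asarray(pheno_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phenotype vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0  # zero vector treated as absent
    cos = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return (1.0 + cos) / 2.0


@dataclass(frozen=True)
class SynergyScore:
    agent_a: str
    agent_b: str
    topology: float
    agent: float

    @property
    def total(self) -> float:
        return self.topology * self.agent


@dataclass
class SynergyMatrix:
    """All compound-pair scores plus herb-pair summaries.

    ``pairs`` is long-format with one row per unordered compound pair
    (including the self-synergy diagonal, which is excluded from herb
    summaries); ``herb_summary`` averages cross-herb compound-pair totals,
    the herb-level synergy readout.
    """

    pairs: pd.DataFrame
    herb_summary: pd.DataFrame
    compounds: list[str]
    herb_of: dict[str, str]
    excluded: list[str] = field(default_factory=list)

    def to_matrix(self) -> pd.DataFrame:
        """Square total-score matrix with rows/columns blocked by herb."""
        order = sorted(self.compounds, key=lambda c: (self.herb_of[c], c))
        m = pd.DataFrame(np.nan, index=order, columns=order)
        for row in self.pairs.itertuples(index=False):
            m.loc[row.compound_a, row.compound_b] = row.total
            m.loc[row.compound_b, row.compound_a] = row.total
        return m


def synergy_matrix(
    target_sets: Mapping[str, Iterable[str]],
    herb_of: Mapping[str, str],
    background: nx.Graph,
    *,
    phenotypes: Mapping[str, np.ndarray] | None = None,
    damping: float = 0.85,
    decay: str = "exp",
) -> SynergyMatrix:
    """Score every compound pair and summarize per herb pair.

    Compound target sets are restricted to the background network;
    compounds left with no in-network target are excluded with a warning
    and reported in ``excluded``.
    """
    restricted: dict[str, list[str]] = {}
    excluded: list[str] = []
    for cid, ts in target_sets.items():
        kept = sorted(set(ts) & set(background.nodes))
        if kept:
            restricted[cid] = kept
        else:
            excluded.append(cid)
    if excluded:
        logger.warning(
            "%d compounds have no targets on the background network", len(excluded)
        )
    if not restricted:
        raise ValueError("no compound has targets on the background network")
    imp = importance_dict(background, damping)
    dmaps = {cid: _distance_map(background, ts) for cid, ts in restricted.items()}
    phenotypes = phenotypes or {}
    ids = sorted(restricted)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i:]:
            ts = topology_score(
                restricted[a], restricted[b], imp, background,
                decay=decay, _dmap1=dmaps[a], _dmap2=dmaps[b],
            )
            asc = agent_score(phenotypes.get(a), phenotypes.get(b))
            rows.append(
                (a, b, herb_of[a], herb_of[b], ts, asc, ts * asc)
            )
    pairs = pd.DataFrame(
        rows,
        columns=["compound_a", "compound_b", "herb_a", "herb_b", "ts", "as_", "total"],
    ).rename(columns={"as_": "agent"})
    cross = pairs[pairs.herb_a != pairs.herb_b].copy()
    key = cross.apply(
        lambda r: tuple(sorted((r.herb_a, r.herb_b))), axis=1
    )
    if len(cross):
        cross = cross.assign(_key=key)
        summary = (
            cross.groupby("_key")["total"]
            .agg(mean_total="mean", n_pairs="size")
            .reset_index()
        )
        summary[["herb_a", "herb_b"]] = pd.DataFrame(
            summary["_key"].tolist(), index=summary.index
        )
        summary = summary[["herb_a", "herb_b", "mean_total", "n_pairs"]]
        summary = summary.sort_values(
            "mean_total", ascending=False, ignore_index=True
        )
    else:
        summary = pd.DataFrame(
            columns=["herb_a", "herb_b", "mean_total", "n_pairs"]
        )
    return SynergyMatrix(
        pairs=pairs,
        herb_summary=summary,
        compounds=ids,
        herb_of={c: herb_of[c] for c in ids},
        excluded=excluded,
    )


def write_synergy_tsv(matrix: SynergyMatrix, path: str | Path) -> None:
    matrix.pairs.to_csv(path, sep="\t", index=False)


def write_herb_summary_tsv(matrix: SynergyMatrix, path: str | Path) -> None:
    matrix.herb_summary.to_csv(path, sep="\t", index=False)


def plot_heatmap(matrix: SynergyMatrix, path: str | Path) -> None:
    """Herb-blocked heatmap of total synergy scores (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = matrix.to_matrix()
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(m.to_numpy(), cmap="viridis", vmin=0, vmax=1)
    herbs = [matrix.herb_of[c] for c in m.index]
    boundaries = [i for i in range(1, len(herbs)) if herbs[i] != herbs[i - 1]]
    for b in boundaries:
        ax.axhline(b - 0.5, color="white", lw=0.6)
        ax.axvline(b - 0.5, color="white", lw=0.6)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_xlabel("compounds (grouped by herb)")
    ax.set_ylabel("compounds (grouped by herb)")
    fig.colorbar(im, ax=ax, label="synergy score")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
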
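"""Distance-based mutual information scoring of herb pairs and core networks.

The pairing propensity of two herbs x, y across a prescription corpus is

    score(x, y) = MI(x, y) / d(x, y)

where MI is the joint-probability-weighted pointwise mutual information of
prescription-level occurrence,

    MI(x, y) = P(x, y) * log2( P(x, y) / (P(x) P(y)) ),

clamped at zero (below-independence co-occurrence carries no pairing
tendency), and d is the between-herb distance: the mean absolute difference
of the two herbs' positions over the prescriptions in which they co-occur.
Because herbs are distinct entries of an ordered formula, d >= 1, so the
quotient is always defined; a pair that never co-occurs scores 0 outright.

Two kinds of core network are built on top of the pair score: the
high-frequency network (the most frequent herbs as nodes, significant
co-occurrences as edges) and the intersection network (the intersection of
the per-seed subnetworks of each top herb).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from functools import reduce
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import Prescription

logger = logging.getLogger(__name__)


class CorpusIndex:
    """Occurrence/position index over a normalized corpus.

    Pair statistics need, per herb, the set of prescriptions containing it
    and the herb's position in each; building this once makes all-pairs
    scoring linear in corpus size.
    """

    def __init__(self, corpus: Sequence[Prescription]):
        if not corpus:
            raise ValueError("empty corpus")
        self.n = len(corpus)
        self.sizes = [len(p) for p in corpus]
        self.positions: dict[str, dict[int, int]] = {}
        for i, presc in enumerate(corpus):
            for pos, herb in enumerate(presc.herbs):
                self.positions.setdefault(herb, {})[i] = pos

    @property
    def herbs(self) -> list[str]:
        return list(self.positions)

    def occurrence_count(self, herb: str) -> int:
        return len(self.positions.get(herb, {}))

    def cooccurrences(self, x: str, y: str) -> list[tuple[int, int, int]]:
        """(prescription index, pos(x), pos(y)) for every shared prescription."""
        px = self.positions.get(x, {})
        py = self.positions.get(y, {})
        if len(py) < len(px):
            px, py = py, px
            swapped = True
        else:
            swapped = False
        out = []
        for i, a in px.items():
            b = py.get(i)
            if b is not None:
                out.append((i, b, a) if swapped else (i, a, b))
        return out


def _as_index(corpus: Sequence[Prescription] | CorpusIndex) -> CorpusIndex:
    return corpus if isinstance(corpus, CorpusIndex) else CorpusIndex(corpus)


@dataclass(frozen=True)
class PairScore:
    """DMIM score of one herb pair; symmetric in (x, y).

    ``d`` is ``inf`` (and mi = score = 0) for pairs that never co-occur.
    """

    x: str
    y: str
    mi: float
    d: float
    score: float
    support: int  #: number of prescriptions containing both herbs


@dataclass(frozen=True)
class EdgeRule:
    """Edge-significance rule for core herb networks.

    An edge (x, y) is kept when score > ``score_threshold`` and the pair
    co-occurs in at least ``min_support`` prescriptions. ``quantile``, if
    set, additionally requires the score to reach that quantile of the
    positive candidate scores (a calibration knob for subnetwork sizes).
    """

    min_support: int = 5
    score_threshold: float = 0.0
    quantile: float | None = None
    clamp_negative_mi: bool = True
    log_base: float = 2.0
    normalize_distance: bool = False

    def passes(self, ps: PairScore, score_cut: float = -math.inf) -> bool:
        return (
            ps.score > self.score_threshold
            and ps.support >= self.min_support
            and ps.score >= score_cut
        )

    def quantile_cut(self, scores: Iterable[float]) -> float:
        if self.quantile is None:
            return -math.inf
        positive = [s for s in scores if s > self.score_threshold]
        if not positive:
            return -math.inf
        return float(np.quantile(positive, self.quantile))


def mutual_information(
    corpus: Sequence[Prescription] | CorpusIndex,
    x: str,
    y: str,
    *,
    clamp: bool = True,
    base: float = 2.0,
) -> float:
    """Prescription-level pointwise mutual information of two herbs, in bits.

    Returns 0 when the pair never co-occurs. Negative values (co-occurrence
    below independence) are clamped to 0 unless ``clamp=False``.
    """
    if x == y:
        raise ValueError("mutual information requires two distinct herbs")
    idx = _as_index(corpus)
    joint = len(idx.cooccurrences(x, y))
    if joint == 0:
        return 0.0
    pxy = joint / idx.n
    px = idx.occurrence_count(x) / idx.n
    py = idx.occurrence_count(y) / idx.n
    mi = pxy * math.log(pxy / (px * py), base)
    return max(0.0, mi) if clamp else mi


def between_herb_distance(
    corpus: Sequence[Prescription] | CorpusIndex,
    x: str,
    y: str,
    *,
    normalize: bool = False,
) -> float:
    """Mean absolute positional separation over co-occurring prescriptions.

    With ``normalize=True`` each gap is divided by (formula length - 1),
    giving a length-relative distance in (0, 1].
    """
    idx = _as_index(corpus)
    shared = idx.cooccurrences(x, y)
    if not shared:
        raise ValueError(f"herbs {x!r} and {y!r} never co-occur")
    if normalize:
        gaps = [abs(a - b) / (idx.sizes[i] - 1) for i, a, b in shared]
    else:
        gaps = [abs(a - b) for i, a, b in shared]
    return sum(gaps) / len(gaps)


def dmim_score(
    corpus: Sequence[Prescription] | CorpusIndex,
    x: str,
    y: str,
    *,
    rule: EdgeRule | None = None,
) -> PairScore:
    """DMIM pair score = MI / d; zero (with d = inf) when never co-occurring."""
    rule = rule or EdgeRule()
    idx = _as_index(corpus)
    support = len(idx.cooccurrences(x, y))
    if support == 0:
        return PairScore(x=x, y=y, mi=0.0, d=math.inf, score=0.0, support=0)
    mi = mutual_information(
        idx, x, y, clamp=rule.clamp_negative_mi, base=rule.log_base
    )
    d = between_herb_distance(idx, x, y, normalize=rule.normalize_distance)
    return PairScore(x=x, y=y, mi=mi, d=d, score=mi / d, support=support)


def pair_score_table(
    corpus: Sequence[Prescription] | CorpusIndex,
    herbs: Sequence[str],
    *,
    rule: EdgeRule | None = None,
) -> pd.DataFrame:
    """All-pairs DMIM scores over ``herbs`` as a long-format table."""
    idx = _as_index(corpus)
    rows = []
    for i, x in enumerate(herbs):
        for y in herbs[i + 1:]:
            ps = dmim_score(idx, x, y, rule=rule)
            rows.append((ps.x, ps.y, ps.mi, ps.d, ps.score, ps.support))
    return pd.DataFrame(
        rows, columns=["herb_x", "herb_y", "mi", "d", "score", "support"]
    )


def high_frequency_network(
    corpus: Sequence[Prescription] | CorpusIndex,
    top_herbs: Sequence[str],
    rule: EdgeRule | None = None,
) -> nx.Graph:
    """Network over the most frequent herbs; edges are significant co-occurrences."""
    if len(top_herbs) < 2:
        raise ValueError("need at least 2 top herbs")
    rule = rule or EdgeRule()
    idx = _as_index(corpus)
    missing = [h for h in top_herbs if h not in idx.positions]
    if missing:
        raise ValueError(f"herbs absent from corpus: {missing}")
    candidates = []
    for i, x in enumerate(top_herbs):
        for y in top_herbs[i + 1:]:
            candidates.append(dmim_score(idx, x, y, rule=rule))
    cut = rule.quantile_cut(ps.score for ps in candidates)
    g = nx.Graph()
    g.add_nodes_from(top_herbs)
    for ps in candidates:
        if rule.passes(ps, cut):
            g.add_edge(
                ps.x, ps.y, mi=ps.mi, d=ps.d, score=ps.score, support=ps.support
            )
    return g


def seed_subnetwork(
    corpus: Sequence[Prescription] | CorpusIndex,
    seed: str,
    rule: EdgeRule | None = None,
) -> nx.Graph:
    """The seed herb's neighborhood network under the edge rule.

    Members are the seed plus every herb whose pair score with the seed
    passes the rule; edges among members (including non-seed pairs) are kept
    only when they pass the rule themselves. The seed stays even if isolated.
    """
    rule = rule or EdgeRule()
    idx = _as_index(corpus)
    if seed not in idx.positions:
        raise ValueError(f"seed herb {seed!r} absent from corpus")
    # Herbs sharing at least one prescription with the seed:
    seed_prescs = set(idx.positions[seed])
    partners = {
        herb
        for herb, occ in idx.positions.items()
        if herb != seed and not seed_prescs.isdisjoint(occ)
    }
    seed_scores = {h: dmim_score(idx, seed, h, rule=rule) for h in sorted(partners)}
    cut = rule.quantile_cut(ps.score for ps in seed_scores.values())
    members = [seed] + [h for h, ps in seed_scores.items() if rule.passes(ps, cut)]
    g = nx.Graph()
    g.add_nodes_from(members)
    for i, x in enumerate(members):
        for y in members[i + 1:]:
            ps = seed_scores[y] if x == seed else dmim_score(idx, x, y, rule=rule)
            if rule.passes(ps, cut):
                g.add_edge(
                    ps.x, ps.y, mi=ps.mi, d=ps.d, score=ps.score,
                    support=ps.support,
                )
    return g


def intersect_subnetworks(nets: Sequence[nx.Graph]) -> nx.Graph:
    """Node-and-edge intersection of subnetworks (the core network).

    Associative and order-invariant; an empty intersection is returned as a
    valid empty graph with a warning.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to intersect")

    def _pair(a: nx.Graph, b: nx.Graph) -> nx.Graph:
        nodes = set(a.nodes) & set(b.nodes)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, data in a.edges(data=True):
            if u in nodes and v in nodes and b.has_edge(u, v):
                g.add_edge(u, v, **data)
        return g

    result = reduce(_pair, nets)
    if result.number_of_nodes() == 0:
        logger.warning("subnetwork intersection is empty")
    return result


def write_edge_tsv(g: nx.Graph, path: str | Path) -> None:
    rows = [
        (u, v, d.get("mi"), d.get("d"), d.get("score"), d.get("support"))
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(
        rows, columns=["herb_x", "herb_y", "mi", "d", "score", "support"]
    ).to_csv(path, sep="\t", index=False)


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    # GraphML rejects None attribute values
    clean = nx.Graph()
    for n, data in g.nodes(data=True):
        clean.add_node(n, **{k: v for k, v in data.items() if v is not None})
    for u, v, data in g.edges(data=True):
        clean.add_edge(u, v, **{k: v for k, v in data.items() if v is not None})
    nx.write_graphml(clean, path)
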
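"""Genome-wide target-profile prediction for herbal compounds.

The prediction follows the structure-network concordance idea: a compound
that is structurally similar to a set of reference drugs is likely to act
on proteins that lie close, in the protein-protein interaction (PPI)
network, to those drugs' known targets. Concretely, for a compound c and a
candidate protein p:

* the *structure similarity vector* s has one entry per reference drug,
  the Tanimoto coefficient between c's fingerprint and the drug's;
* the *closeness vector* z has one entry per reference drug, the mean of
  exp(-spl(p, t)) over the drug's targets t, with spl the unweighted
  shortest-path length in the PPI (disconnected pairs contribute 0);
* the concordance score of (c, p) is the Pearson correlation of s and z.

Ranking the whole proteome by concordance and truncating at K (default
100) yields the compound's target profile. Herb-level target sets are the
proteins hit by strictly more than ``min_support`` compound profiles
within the herb.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class CompoundRecord:
    """A (synthetic or real) herbal compound with a binary fingerprint."""

    id: str
    herb_ids: frozenset[str]
    fingerprint: np.ndarray

    def __post_init__(self) -> None:
        if not self.herb_ids:
            raise ValueError(f"compound {self.id!r} belongs to no herb")


@dataclass(frozen=True, eq=False)
class ReferenceDrug:
    """A reference drug with fingerprint, known target set, and class label."""

    id: str
    fingerprint: np.ndarray
    targets: frozenset[str]
    drug_class: str = "other"

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"drug {self.id!r} has no targets")


@dataclass(frozen=True)
class TargetProfile:
    """Top-K proteins by concordance for one compound, scores non-increasing."""

    compound_id: str
    ranked: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranked]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("profile scores must be non-increasing")
        proteins = [p for p, _ in self.ranked]
        if len(set(proteins)) != len(proteins):
            raise ValueError("profile proteins must be unique")

    @property
    def proteins(self) -> list[str]:
        return [p for p, _ in self.ranked]

    def __len__(self) -> int:
        return len(self.ranked)


@dataclass(frozen=True)
class HerbTargetSet:
    """Herb-level targets: proteins hit by > min_support compound profiles."""

    herb: str
    targets: frozenset[str]
    support: Mapping[str, int]


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) coefficient of two binary fingerprints.

    Defined as 0 when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def similarity_vector(
    fingerprint: np.ndarray, drugs: Sequence[ReferenceDrug]
) -> np.ndarray:
    """Tanimoto of a compound fingerprint against each reference drug."""
    return np.array([tanimoto(fingerprint, d.fingerprint) for d in drugs])


def closeness_matrix(
    proteins: Sequence[str],
    drugs: Sequence[ReferenceDrug],
    ppi: nx.Graph,
) -> np.ndarray:
    """Closeness of each protein to each drug's target set.

    Entry (i, j) = mean over targets t of drug j of exp(-spl(protein_i, t));
    targets disconnected from (or absent in) the PPI contribute 0. One BFS
    per distinct target makes this linear in the number of targets.
    """
    missing = [p for p in proteins if p not in ppi]
    if missing:
        raise ValueError(f"proteins absent from PPI: {missing[:5]}...")
    index = {p: i for i, p in enumerate(proteins)}
    all_targets = sorted({t for d in drugs for t in d.targets})
    decay: dict[str, np.ndarray] = {}
    for t in all_targets:
        col = np.zeros(len(proteins))
        if t in ppi:
            for node, dist in nx.single_source_shortest_path_length(ppi, t).items():
                i = index.get(node)
                if i is not None:
                    col[i] = math.exp(-dist)
        decay[t] = col
    out = np.zeros((len(proteins), len(drugs)))
    for j, drug in enumerate(drugs):
        out[:, j] = np.mean([decay[t] for t in sorted(drug.targets)], axis=0)
    return out


def closeness_vector(
    protein: str, drugs: Sequence[ReferenceDrug], ppi: nx.Graph
) -> np.ndarray:
    """One protein's closeness vector over the reference drugs."""
    return closeness_matrix([protein], drugs, ppi)[0]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        return 0.0  # zero-variance guard: degenerate vectors rank last
    return float(np.dot(a, b) / den)


def concordance(
    compound: CompoundRecord,
    protein: str,
    drugs: Sequence[ReferenceDrug],
    ppi: nx.Graph,
) -> float:
    """Pearson correlation of structure-similarity and target-closeness vectors."""
    if len(drugs) < 3:
        raise ValueError("concordance requires at least 3 reference drugs")
    s = similarity_vector(compound.fingerprint, drugs)
    z = closeness_vector(protein, drugs, ppi)
    return _pearson(s, z)


def predict_profile(
    compound: CompoundRecord,
    drugs: Sequence[ReferenceDrug],
    ppi: nx.Graph,
    k: int = 100,
    *,
    proteome: Sequence[str] | None = None,
    closeness: np.ndarray | None = None,
) -> TargetProfile:
    """Score the whole proteome by concordance and keep the top K.

    ``proteome`` defaults to all PPI nodes (sorted). A precomputed
    ``closeness`` matrix (from :func:`closeness_matrix` over the same
    proteome/drug ordering) can be supplied to amortize BFS work across
    compounds. Ties are broken by protein identifier.
    """
    if len(drugs) < 3:
        raise ValueError("concordance requires at least 3 reference drugs")
    if proteome is None:
        proteome = sorted(ppi.nodes)
    if closeness is None:
        closeness = closeness_matrix(proteome, drugs, ppi)
    s = similarity_vector(compound.fingerprint, drugs)
    sc = s - s.mean()
    s_norm = np.linalg.norm(sc)
    zc = closeness - closeness.mean(axis=1, keepdims=True)
    z_norm = np.linalg.norm(zc, axis=1)
    den = s_norm * z_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(den > 0, zc @ sc / np.where(den > 0, den, 1.0), 0.0)
    order = sorted(range(len(proteome)), key=lambda i: (-scores[i], proteome[i]))
    top = order[: min(k, len(proteome))]
    return TargetProfile(
        compound_id=compound.id,
        ranked=tuple((proteome[i], float(scores[i])) for i in top),
    )


def predict_profiles(
    compounds: Sequence[CompoundRecord],
    drugs: Sequence[ReferenceDrug],
    ppi: nx.Graph,
    k: int = 100,
) -> dict[str, TargetProfile]:
    """Batch profile prediction sharing one closeness matrix."""
    proteome = sorted(ppi.nodes)
    closeness = closeness_matrix(proteome, drugs, ppi)
    return {
        c.id: predict_profile(
            c, drugs, ppi, k, proteome=proteome, closeness=closeness
        )
        for c in compounds
    }


def herb_target_set(
    herb: str,
    profiles: Iterable[TargetProfile],
    min_support: int = 5,
) -> HerbTargetSet:
    """Proteins appearing in strictly more than ``min_support`` profiles.

    With the default of 5, a protein must be hit by at least 6 of the
    herb's compound profiles to count as a herb target.
    """
    support: dict[str, int] = {}
    n = 0
    for prof in profiles:
        n += 1
        for protein in prof.proteins:
            support[protein] = support.get(protein, 0) + 1
    if n == 0:
        logger.warning("herb %r has no compound profiles; empty target set", herb)
    targets = frozenset(p for p, c in support.items() if c > min_support)
    return HerbTargetSet(herb=herb, targets=targets, support=support)


# ---------------------------------------------------------------------------
# TSV interfaces


def read_ppi_tsv(path: str | Path) -> nx.Graph:
    """Undirected PPI edge list (2 columns, tab-separated, header row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    for a, b in df.itertuples(index=False):
        if a != b:
            g.add_edge(a, b)
    return g


def write_ppi_tsv(ppi: nx.Graph, path: str | Path) -> None:
    pd.DataFrame(sorted(ppi.edges), columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


def _fp_to_string(fp: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in np.asarray(fp, dtype=bool))


def _fp_from_string(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


def read_compounds_tsv(path: str | Path) -> list[CompoundRecord]:
    """Columns: compound_id, herb_ids (pipe-separated), fingerprint (bitstring)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CompoundRecord(
            id=row.compound_id,
            herb_ids=frozenset(row.herb_ids.split("|")),
            fingerprint=_fp_from_string(row.fingerprint),
        )
        for row in df.itertuples(index=False)
    ]


def write_compounds_tsv(
    compounds: Iterable[CompoundRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (c.id, "|".join(sorted(c.herb_ids)), _fp_to_string(c.fingerprint))
            for c in compounds
        ],
        columns=["compound_id", "herb_ids", "fingerprint"],
    ).to_csv(path, sep="\t", index=False)


def read_drugs_tsv(path: str | Path) -> list[ReferenceDrug]:
    """Columns: drug_id, class, fingerprint (bitstring), targets (pipe-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ReferenceDrug(
            id=row["drug_id"],
            drug_class=row["class"],
            fingerprint=_fp_from_string(row["fingerprint"]),
            targets=frozenset(row["targets"].split("|")),
        )
        for row in df.to_dict("records")
    ]


def write_drugs_tsv(drugs: Iterable[ReferenceDrug], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                d.id,
                d.drug_class,
                _fp_to_string(d.fingerprint),
                "|".join(sorted(d.targets)),
            )
            for d in drugs
        ],
        columns=["drug_id", "class", "fingerprint", "targets"],
    ).to_csv(path, sep="\t", index=False)


def write_profiles_tsv(
    profiles: Mapping[str, TargetProfile], path: str | Path
) -> None:
    rows = [
        (cid, rank + 1, protein, score)
        for cid, prof in sorted(profiles.items())
        for rank, (protein, score) in enumerate(prof.ranked)
    ]
    pd.DataFrame(rows, columns=["compound_id", "rank", "protein", "score"]).to_csv(
        path, sep="\t", index=False
    )
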
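"""Prescription corpus ingestion, herb-name normalization, and frequency tables.

A prescription corpus is a list of multi-herb formulae, each an ordered list
of herb names (the position encodes the traditional Jun-Chen-Zuo-Shi
Master/Adviser/Soldier/Guide hierarchy, with the principal herbs first).
Raw corpora mix polysemes, synonyms, and acronyms for the same herb;
normalization collapses every mention onto a standardized herb name using a
lexicon before any counting takes place.

Frequencies are presence-based: a herb's accumulated frequency AF is the
number of prescriptions containing it (herbs do not repeat within a
formula), and its normalized frequency NF = AF / sum of AF over all herbs.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: The five traditional herb properties.
HERB_PROPERTIES = ("Cold", "Hot", "Warm", "Cool", "Neutral")


@dataclass(frozen=True)
class HerbRecord:
    """One lexicon entry: a standardized herb name with its known aliases.

    Parameters
    ----------
    standard_name
        The canonical name every mention is normalized to.
    synonyms
        Alternative spellings / acronyms / polysemes for this herb. Must not
        contain the standard name itself, and synonym sets of distinct herbs
        must be disjoint across a lexicon.
    latin_name
        Optional botanical (Latin) name.
    property
        One of ``HERB_PROPERTIES`` (Cold/Hot/Warm/Cool/Neutral).
    """

    standard_name: str
    synonyms: frozenset[str] = frozenset()
    latin_name: str | None = None
    property: str = "Neutral"

    def __post_init__(self) -> None:
        if self.property not in HERB_PROPERTIES:
            raise ValueError(
                f"unknown herb property {self.property!r}; "
                f"expected one of {HERB_PROPERTIES}"
            )
        if self.standard_name in self.synonyms:
            raise ValueError(
                f"standard name {self.standard_name!r} listed among its own synonyms"
            )


@dataclass(frozen=True)
class Prescription:
    """An ordered multi-herb formula.

    ``herbs`` holds standardized names; index 0 is the leading (Jun) herb.
    A valid prescription has at least two distinct herbs and no duplicates.
    """

    id: str
    herbs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.herbs) < 2:
            raise ValueError(f"prescription {self.id!r} has fewer than 2 herbs")
        if len(set(self.herbs)) != len(self.herbs):
            raise ValueError(f"prescription {self.id!r} contains duplicate herbs")

    def __len__(self) -> int:
        return len(self.herbs)

    def position(self, herb: str) -> int:
        return self.herbs.index(herb)


def synonym_map(lexicon: Iterable[HerbRecord]) -> dict[str, str]:
    """Build a name -> standard_name map, validating lexicon invariants.

    Every standard name maps to itself. Raises ``ValueError`` if two herbs
    share a synonym or a synonym collides with another herb's standard name.
    """
    mapping: dict[str, str] = {}
    for rec in lexicon:
        for name in (rec.standard_name, *rec.synonyms):
            owner = mapping.get(name)
            if owner is not None and owner != rec.standard_name:
                raise ValueError(
                    f"name {name!r} is claimed by both {owner!r} and "
                    f"{rec.standard_name!r}"
                )
            mapping[name] = rec.standard_name
    return mapping


def normalize_names(
    names: Sequence[str],
    mapping: Mapping[str, str],
    *,
    on_unknown: str = "error",
    context: str = "",
) -> list[str]:
    """Map an ordered name list onto standard names, merging duplicates.

    Order is preserved; when two raw mentions collapse onto the same
    standard name the earliest position wins.
    """
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    seen: dict[str, None] = {}
    for name in names:
        std = mapping.get(name)
        if std is None:
            if on_unknown == "error":
                raise KeyError(
                    f"herb name {name!r}{context} not found in lexicon"
                )
            logger.warning("dropping unknown herb %r%s", name, context)
            continue
        seen.setdefault(std, None)
    return list(seen)


def normalize_corpus(
    raw: Iterable[tuple[str, Sequence[str]]],
    lexicon: Iterable[HerbRecord],
    *,
    on_unknown: str = "error",
) -> list[Prescription]:
    """Normalize free-text herb names to standard names.

    Parameters
    ----------
    raw
        Iterable of ``(prescription_id, ordered herb names)`` pairs.
    lexicon
        Herb records providing the synonym mapping.
    on_unknown
        ``"error"`` (default) raises on a name absent from the lexicon;
        ``"drop"`` removes the mention with a warning.

    Prescriptions left with fewer than two herbs (by synonym merging, or by
    dropped mentions under the ``"drop"`` policy) are discarded with a
    warning under ``"drop"``, and raise under ``"error"``.
    """
    mapping = synonym_map(lexicon)
    out: list[Prescription] = []
    for pid, names in raw:
        seen = normalize_names(
            names, mapping, on_unknown=on_unknown,
            context=f" in prescription {pid!r}",
        )
        if len(seen) < 2:
            if on_unknown == "error":
                raise ValueError(
                    f"prescription {pid!r} has fewer than 2 herbs after normalization"
                )
            logger.warning(
                "discarding prescription %r: fewer than 2 herbs after normalization",
                pid,
            )
            continue
        out.append(Prescription(id=pid, herbs=tuple(seen)))
    return out


@dataclass(frozen=True)
class FrequencyTable:
    """Accumulated (AF) and normalized (NF) herb frequencies.

    NF[h] = AF[h] / sum(AF), so NF sums to 1 over the herbs present.
    """

    af: Mapping[str, int]
    n_prescriptions: int = 0
    nf: Mapping[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.af:
            raise ValueError("empty frequency table")
        if any(v < 0 for v in self.af.values()):
            raise ValueError("negative accumulated frequency")
        total = sum(self.af.values())
        if total == 0:
            raise ValueError("all accumulated frequencies are zero")
        object.__setattr__(
            self, "nf", {h: v / total for h, v in self.af.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"herb": list(self.af), "af": list(self.af.values())}
        )
        df["nf"] = df["af"] / df["af"].sum()
        return df.sort_values(
            ["af", "herb"], ascending=[False, True], ignore_index=True
        )


def frequency_table(corpus: Sequence[Prescription]) -> FrequencyTable:
    """Count presence-based herb frequencies over a normalized corpus."""
    if not corpus:
        raise ValueError("empty corpus")
    af: dict[str, int] = {}
    for presc in corpus:
        for herb in presc.herbs:
            af[herb] = af.get(herb, 0) + 1
    return FrequencyTable(af=af, n_prescriptions=len(corpus))


def top_k_herbs(ft: FrequencyTable, k: int) -> list[str]:
    """The k most frequent herbs, AF descending, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(ft.af, key=lambda h: (-ft.af[h], h))
    if k > len(ranked):
        logger.warning(
            "requested top %d herbs but only %d are present", k, len(ranked)
        )
    return ranked[:k]


# ---------------------------------------------------------------------------
# TSV interfaces


def read_corpus_tsv(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a raw corpus: columns ``id``, ``herbs`` (pipe-separated, ordered)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        (row.id, [h for h in str(row.herbs).split("|") if h])
        for row in df.itertuples(index=False)
    ]


def write_corpus_tsv(
    raw: Iterable[tuple[str, Sequence[str]]], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(pid, "|".join(names)) for pid, names in raw], columns=["id", "herbs"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_lexicon_tsv(path: str | Path) -> list[HerbRecord]:
    """Read a lexicon: columns ``standard_name, latin_name, property, synonyms``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        syns = frozenset(s for s in str(row.synonyms).split("|") if s)
        records.append(
            HerbRecord(
                standard_name=row.standard_name,
                synonyms=syns,
                latin_name=row.latin_name or None,
                property=row.property,
            )
        )
    return records


def write_lexicon_tsv(lexicon: Iterable[HerbRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                rec.standard_name,
                rec.latin_name or "",
                rec.property,
                "|".join(sorted(rec.synonyms)),
            )
            for rec in lexicon
        ],
        columns=["standard_name", "latin_name", "property", "synonyms"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_frequency_tsv(ft: FrequencyTable, path: str | Path) -> None:
    ft.to_frame().to_csv(path, sep="\t", index=False)
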
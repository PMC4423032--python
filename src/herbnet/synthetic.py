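"""Synthetic data with planted ground truth for every pipeline stage.

The study's original inputs (the prescription corpus, the herbal-compound
chemistry, the interactome snapshot, the curated disease genes) are not
publicly deposited, so this module generates datasets carrying the same
statistical structure, with the planted signal recorded as ground truth:

* a prescription corpus (default 871 formulae over 343 herbs, sizes 15-29
  with mean 18, synonym noise) in which ten designated "top" herbs co-occur
  as a full clique in a configured fraction of formulae, together with four
  extra herbs forming a 14-herb core (the four emulate a known sub-formula
  that should survive the subnetwork intersection);
* per-herb compound libraries whose fingerprints are mutated copies of a
  parent reference drug's fingerprint, with the parent's known targets as
  the compound's true targets (the structure-target coupling the
  concordance predictor assumes), and a herb-property <-> drug-class
  coupling (Cold -> immunomodulatory, Hot -> hormone) for the bridge stage;
* a scale-free PPI (preferential attachment), disease genes sampled from
  one dense region, and flat annotation terms including planted terms
  enriched in both the disease genes and the drug-target pool.

Everything is deterministic given (config, seed): one seed sequence is
split per sub-generator so stages can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import reference
from .corpus import (
    HerbRecord,
    Prescription,
    read_corpus_tsv,
    read_lexicon_tsv,
    write_corpus_tsv,
    write_lexicon_tsv,
)
from .enrichment import (
    AnnotationSet,
    read_gene_list,
    read_gmt,
    write_gene_list,
    write_gmt,
)
from .targets import (
    CompoundRecord,
    ReferenceDrug,
    read_compounds_tsv,
    read_drugs_tsv,
    read_ppi_tsv,
    write_compounds_tsv,
    write_drugs_tsv,
    write_ppi_tsv,
)

logger = logging.getLogger(__name__)

_TOP10_PROPERTIES = (
    "Warm", "Neutral", "Warm", "Warm", "Neutral",
    "Neutral", "Cold", "Hot", "Warm", "Cold",
)
_QLY_PROPERTIES = ("Neutral", "Cold", "Cold", "Neutral")
_PROPERTY_CYCLE = ("Cold", "Hot", "Warm", "Cool", "Neutral")
_RARE_PROPERTY_P = (0.18, 0.08, 0.27, 0.12, 0.35)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic corpus and its annexes."""

    seed: int = 0
    # corpus
    n_prescriptions: int = 871
    n_herbs: int = 343
    min_size: int = 15
    max_size: int = 29
    mean_size: float = 18.0
    n_synonyms_per_herb: int = 2
    synonym_rate: float = 0.3
    # planted herb modules
    plant_modules: bool = True
    n_top: int = 10
    core_size: int = 14  # top herbs + the planted sub-formula
    module_rate: float = 0.8  # fraction of formulae carrying the full core
    top_solo_rate: float = 0.1  # independent top-herb inclusion elsewhere
    companion_share: float = 2 / 3  # non-module slots given to companion herbs
    background_zipf: float = 1.0
    # chemistry
    n_chem_herbs: int = 50
    compounds_per_herb: int = 8
    fingerprint_length: int = 128
    fingerprint_density: float = 0.3
    mutation_rate: float = 0.05
    drug_target_size: int = 8
    # interactome / disease / annotations
    ppi_nodes: int = 2000
    ppi_attachment: int = 3
    n_disease_genes: int = 129
    n_terms: int = 150
    term_size_range: tuple[int, int] = (10, 200)
    n_planted_terms: int = 9

    def __post_init__(self) -> None:
        if not (2 <= self.min_size <= self.max_size <= self.n_herbs):
            raise ValueError("invalid formula size range")
        if not (self.min_size <= self.mean_size <= self.max_size):
            raise ValueError("mean size outside size range")
        if self.plant_modules:
            if self.core_size >= self.min_size:
                raise ValueError(
                    "planted core must be smaller than the minimum formula size"
                )
            if self.n_top >= self.core_size:
                raise ValueError("core must extend beyond the top herbs")
        if self.n_chem_herbs > self.n_herbs:
            raise ValueError("more chemistry herbs than herbs")
        if self.n_disease_genes > self.ppi_nodes:
            raise ValueError("more disease genes than PPI nodes")

    @property
    def qly_size(self) -> int:
        return self.core_size - self.n_top


@dataclass
class GroundTruth:
    """Planted signal, sufficient to score recovery at every stage."""

    top_herbs: list[str]
    qly_herbs: list[str]
    core_herbs: list[str]
    herb_properties: dict[str, str]
    chem_herbs: list[str]
    herb_parent_drug: dict[str, str]
    compound_true_targets: dict[str, list[str]]
    disease_genes: list[str]
    planted_terms: list[str]
    property_drug_class: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass
class SyntheticDataset:
    """One generated dataset: inputs for every stage plus its ground truth."""

    config: GeneratorConfig
    raw_corpus: list[tuple[str, list[str]]]
    lexicon: list[HerbRecord]
    ppi: nx.Graph
    disease_genes: list[str]
    drugs: list[ReferenceDrug]
    compounds: list[CompoundRecord]
    annotations: list[AnnotationSet]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Corpus generation


def _herb_names(n: int) -> list[str]:
    return [f"herb{i:03d}" for i in range(n)]


def _formula_sizes(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Discretized Beta draw on [min_size, max_size] calibrated to mean_size.

    The Beta's first shape is fixed at 2 and the second solved from the
    target mean; a uniform draw on the printed range would overshoot the
    printed average, hence the low-mode shape.
    """
    span = cfg.max_size - cfg.min_size
    if span == 0:
        return np.full(cfg.n_prescriptions, cfg.min_size)
    m = (cfg.mean_size - cfg.min_size) / span
    m = min(max(m, 1e-6), 1 - 1e-6)
    a = 2.0
    b = a * (1 - m) / m
    x = rng.beta(a, b, cfg.n_prescriptions)
    return cfg.min_size + np.rint(x * span).astype(int)


def _weighted_sample(
    rng: np.random.Generator,
    pool: list[str],
    weights: np.ndarray,
    size: int,
    exclude: set[str],
) -> list[str]:
    mask = np.array([h not in exclude for h in pool])
    w = weights * mask
    total = w.sum()
    avail = int(mask.sum())
    if size > avail:
        raise ValueError("sampling pool exhausted")
    if size == 0:
        return []
    idx = rng.choice(len(pool), size=size, replace=False, p=w / total)
    return [pool[i] for i in idx]


def generate_corpus(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, list[str]]], list[HerbRecord], dict]:
    """Generate the raw corpus (with synonym noise), its lexicon, and plant info.

    Planted structure (when ``plant_modules``): a ``module_rate`` fraction
    of formulae opens with all ``core_size`` core herbs (the ten top herbs
    and the contiguous planted sub-formula) in shuffled order; top herbs
    additionally appear alone at ``top_solo_rate`` in the remaining
    formulae so their frequencies strictly dominate the core extras.
    Module-formula background slots are filled from a fixed companion pool
    (the next ``n_chem_herbs - core_size`` herbs) that is also strongly
    represented in non-module formulae — companions therefore co-occur with
    top herbs *below* independence and stay under the pair-score edge rule.
    The remaining (rare) herbs appear only in non-module formulae with
    Zipf-decaying weights; their co-occurrence support with any top herb
    stays under the default minimum support. Every herb appears at least
    once (coverage pre-assignment).
    """
    names = _herb_names(cfg.n_herbs)
    top = names[: cfg.n_top] if cfg.plant_modules else []
    qly = names[cfg.n_top: cfg.core_size] if cfg.plant_modules else []
    core = top + qly
    sizes = _formula_sizes(cfg, rng)
    n = cfg.n_prescriptions

    if cfg.plant_modules:
        companions = names[cfg.core_size: cfg.n_chem_herbs]
        rare = names[cfg.n_chem_herbs:]
        is_module = rng.random(n) < cfg.module_rate
    else:
        companions, rare = [], names[:]
        is_module = np.zeros(n, dtype=bool)

    fronts: list[list[str]] = []
    for i in range(n):
        if is_module[i]:
            tokens: list[object] = [*top, tuple(rng.permutation(qly))]
            order = rng.permutation(len(tokens))
            front: list[str] = []
            for j in order:
                tok = tokens[j]
                front.extend(tok) if isinstance(tok, tuple) else front.append(tok)
        else:
            front = [h for h in top if rng.random() < cfg.top_solo_rate]
            front = list(rng.permutation(front)) if front else []
        fronts.append(front)

    # background capacity per formula, split companion/rare for non-module
    comp_slots = np.zeros(n, dtype=int)
    rare_slots = np.zeros(n, dtype=int)
    for i in range(n):
        bg = int(sizes[i]) - len(fronts[i])
        if bg < 0:
            raise ValueError("formula size smaller than its planted front")
        if is_module[i]:
            comp_slots[i] = min(bg, len(companions))
            rare_slots[i] = bg - comp_slots[i]
        else:
            want_comp = int(round(bg * cfg.companion_share)) if companions else 0
            comp_slots[i] = min(want_comp, len(companions))
            rare_slots[i] = bg - comp_slots[i]
    if rare and rare_slots.sum() < len(rare):
        raise ValueError(
            "not enough background slots to cover the rare herb pool; "
            "increase n_prescriptions or formula sizes"
        )

    # coverage pre-assignment
    preassigned: list[list[str]] = [[] for _ in range(n)]
    if companions:
        module_ids = [i for i in range(n) if is_module[i] and comp_slots[i] > 0]
        other_ids = [i for i in range(n) if not is_module[i] and comp_slots[i] > 0]
        hosts = list(rng.permutation(module_ids)) + list(rng.permutation(other_ids))
        if len(hosts) < len(companions):
            raise ValueError("not enough formulae to cover the companion pool")
        for herb, i in zip(companions, hosts):
            preassigned[i].append(herb)
    if rare:
        capacity = rare_slots.copy()
        hosts = [i for i in rng.permutation(n) if capacity[i] > 0]
        cursor = 0
        for herb in rare:
            while capacity[hosts[cursor % len(hosts)]] == 0:
                cursor += 1
            i = hosts[cursor % len(hosts)]
            preassigned[i].append(herb)
            capacity[i] -= 1
            cursor += 1

    comp_weights = np.ones(len(companions)) if companions else np.array([])
    rare_weights = (
        1.0 / np.arange(1, len(rare) + 1) ** cfg.background_zipf
        if rare
        else np.array([])
    )

    formulae: list[list[str]] = []
    for i in range(n):
        present = set(fronts[i]) | set(preassigned[i])
        pre_comp = [h for h in preassigned[i] if h in set(companions)]
        pre_rare = [h for h in preassigned[i] if h not in set(companions)]
        extra_comp = _weighted_sample(
            rng, companions, comp_weights,
            max(0, comp_slots[i] - len(pre_comp)), present,
        ) if companions else []
        present.update(extra_comp)
        extra_rare = _weighted_sample(
            rng, rare, rare_weights,
            max(0, rare_slots[i] - len(pre_rare)), present,
        ) if rare else []
        bg = pre_comp + pre_rare + extra_comp + extra_rare
        bg = list(rng.permutation(bg)) if bg else []
        formulae.append(fronts[i] + bg)

    # properties and lexicon
    props: dict[str, str] = {}
    for h, p in zip(top, _TOP10_PROPERTIES):
        props[h] = p
    for h, p in zip(qly, _QLY_PROPERTIES):
        props[h] = p
    for j, h in enumerate(companions):
        props[h] = _PROPERTY_CYCLE[j % len(_PROPERTY_CYCLE)]
    remaining = [h for h in names if h not in props]
    drawn = rng.choice(len(_PROPERTY_CYCLE), size=len(remaining), p=_RARE_PROPERTY_P)
    for h, j in zip(remaining, drawn):
        props[h] = _PROPERTY_CYCLE[j]
    lexicon = [
        HerbRecord(
            standard_name=h,
            synonyms=frozenset(
                f"{h}-syn{j + 1}" for j in range(cfg.n_synonyms_per_herb)
            ),
            latin_name=f"Synthetica {h}",
            property=props[h],
        )
        for h in names
    ]
    syn_lists = {h: sorted(rec.synonyms) for h, rec in zip(names, lexicon)}

    raw: list[tuple[str, list[str]]] = []
    for i, formula in enumerate(formulae):
        mentions = [
            (
                syn_lists[h][rng.integers(len(syn_lists[h]))]
                if syn_lists[h] and rng.random() < cfg.synonym_rate
                else h
            )
            for h in formula
        ]
        raw.append((f"Rx{i + 1:04d}", mentions))

    plant = {
        "top_herbs": top,
        "qly_herbs": qly,
        "core_herbs": core,
        "herb_properties": props,
        "companions": companions,
    }
    return raw, lexicon, plant


# ---------------------------------------------------------------------------
# Interactome, disease genes, annotations


def generate_ppi(cfg: GeneratorConfig, rng: np.random.Generator) -> nx.Graph:
    """Scale-free undirected PPI by preferential attachment."""
    g = nx.barabasi_albert_graph(cfg.ppi_nodes, cfg.ppi_attachment, seed=rng)
    return nx.relabel_nodes(g, {i: f"G{i:04d}" for i in g.nodes})


def sample_disease_genes(
    ppi: nx.Graph, n_genes: int, rng: np.random.Generator
) -> list[str]:
    """Disease genes drawn preferentially from one dense network region."""
    hub = max(sorted(ppi.nodes), key=lambda v: ppi.degree[v])
    dist = nx.single_source_shortest_path_length(ppi, hub)
    nodes = sorted(ppi.nodes)
    w = np.array([np.exp(-dist.get(v, np.inf)) for v in nodes])
    if w.sum() == 0:
        raise ValueError("disconnected hub region")
    idx = rng.choice(len(nodes), size=n_genes, replace=False, p=w / w.sum())
    return sorted(nodes[i] for i in idx)


def generate_annotations(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    ppi: nx.Graph,
    disease_genes: list[str],
    target_pool: list[str],
) -> tuple[list[AnnotationSet], list[str]]:
    """Flat annotation terms; the first ``n_planted_terms`` are planted.

    A planted term is a network-localized gene module: a shortest-path
    ball around an anchor drawn from the drug-target pool, topped up with
    a few disease genes. Because drug targets sit in the disease-gene
    region and predicted compound profiles concentrate around them, such
    terms are enriched in *both* the disease genes and the herb targets —
    the shared-signal structure the overlap analysis should recover.
    Non-planted terms are uniform draws (null terms).
    """
    universe = sorted(ppi.nodes)
    lo, hi = cfg.term_size_range
    hi = min(hi, len(universe))
    terms: list[AnnotationSet] = []
    planted: list[str] = []
    pool = sorted(set(target_pool) & set(universe))
    for t in range(cfg.n_planted_terms):
        tid = f"T{t:04d}"
        anchor = pool[int(rng.integers(len(pool)))]
        ball_size = int(rng.integers(35, 56))
        genes = set(_target_ball(ppi, anchor, ball_size))
        n_dis = min(10, len(disease_genes))
        genes |= set(rng.choice(disease_genes, size=n_dis, replace=False))
        terms.append(
            AnnotationSet(tid, f"planted term {t}", frozenset(genes))
        )
        planted.append(tid)
    for t in range(cfg.n_planted_terms, cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        terms.append(
            AnnotationSet(f"T{t:04d}", f"random term {t}", frozenset(genes))
        )
    return terms, planted


# ---------------------------------------------------------------------------
# Chemistry


def _random_fingerprint(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(cfg.fingerprint_length) < cfg.fingerprint_density).astype(
        np.uint8
    )


def mutate_fingerprint(
    fp: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    flips = rng.random(len(fp)) < rate
    return np.where(flips, 1 - fp, fp).astype(np.uint8)


def _target_ball(
    ppi: nx.Graph, anchor: str, size: int
) -> frozenset[str]:
    """The ``size`` nodes nearest the anchor (BFS order, ties by node id)."""
    dist = nx.single_source_shortest_path_length(ppi, anchor)
    ranked = sorted(dist, key=lambda v: (dist[v], v))
    return frozenset(ranked[:size])


def generate_chem(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    chem_herbs: list[str],
    herb_properties: dict[str, str],
    ppi: nx.Graph,
    disease_genes: list[str],
) -> tuple[list[ReferenceDrug], list[CompoundRecord], dict]:
    """Reference drugs with localized targets, and parent-derived compounds.

    Immunomodulatory drug targets are anchored near one disease-gene
    region, hormone targets near a distant one. Each herb is assigned a
    primary parent drug through the property/class coupling (Cold ->
    immunomodulatory, Hot -> hormone, Warm -> either, otherwise any); all
    of the herb's compounds are fingerprint mutations of that parent, and
    their true targets are the parent's target set.
    """
    # two separated anchor regions among the disease genes
    center_a = max(disease_genes, key=lambda v: (ppi.degree[v], v))
    dist_a = nx.single_source_shortest_path_length(ppi, center_a)
    center_b = max(disease_genes, key=lambda v: (dist_a.get(v, -1), v))
    dist_b = nx.single_source_shortest_path_length(ppi, center_b)

    def anchors_near(center_dist: dict, k: int) -> list[str]:
        ranked = sorted(
            disease_genes, key=lambda v: (center_dist.get(v, np.inf), v)
        )
        pool = ranked[: max(k * 3, k)]
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in idx]

    drugs: list[ReferenceDrug] = []
    imm = list(reference.IMMUNOMODULATORY_DRUGS)
    hor = list(reference.HORMONE_DRUGS)
    for name, anchor in zip(imm, anchors_near(dist_a, len(imm))):
        drugs.append(
            ReferenceDrug(
                id=name,
                fingerprint=_random_fingerprint(cfg, rng),
                targets=_target_ball(ppi, anchor, cfg.drug_target_size),
                drug_class="immunomodulatory",
            )
        )
    for name, anchor in zip(hor, anchors_near(dist_b, len(hor))):
        drugs.append(
            ReferenceDrug(
                id=name,
                fingerprint=_random_fingerprint(cfg, rng),
                targets=_target_ball(ppi, anchor, cfg.drug_target_size),
                drug_class="hormone",
            )
        )
    by_class = {
        "immunomodulatory": [d for d in drugs if d.drug_class == "immunomodulatory"],
        "hormone": [d for d in drugs if d.drug_class == "hormone"],
    }

    def parent_for(prop: str) -> ReferenceDrug:
        if prop == "Cold":
            pool = by_class["immunomodulatory"]
        elif prop == "Hot":
            pool = by_class["hormone"]
        elif prop == "Warm":
            pool = by_class[
                ("immunomodulatory", "hormone")[int(rng.integers(2))]
            ]
        else:
            pool = drugs
        return pool[int(rng.integers(len(pool)))]

    compounds: list[CompoundRecord] = []
    herb_parent: dict[str, str] = {}
    true_targets: dict[str, list[str]] = {}
    for herb in chem_herbs:
        parent = parent_for(herb_properties.get(herb, "Neutral"))
        herb_parent[herb] = parent.id
        for j in range(cfg.compounds_per_herb):
            cid = f"{herb}:c{j:02d}"
            compounds.append(
                CompoundRecord(
                    id=cid,
                    herb_ids=frozenset([herb]),
                    fingerprint=mutate_fingerprint(
                        parent.fingerprint, cfg.mutation_rate, rng
                    ),
                )
            )
            true_targets[cid] = sorted(parent.targets)
    chem = {
        "herb_parent_drug": herb_parent,
        "compound_true_targets": true_targets,
        "property_drug_class": {"Cold": "immunomodulatory", "Hot": "hormone"},
    }
    return drugs, compounds, chem


# ---------------------------------------------------------------------------
# Whole datasets


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate one full dataset; deterministic given config (incl. seed)."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_corpus, rng_ppi, rng_chem, rng_ann = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    raw, lexicon, plant = generate_corpus(cfg, rng_corpus)
    ppi = generate_ppi(cfg, rng_ppi)
    disease_genes = sample_disease_genes(ppi, cfg.n_disease_genes, rng_ppi)
    chem_herbs = _herb_names(cfg.n_herbs)[: cfg.n_chem_herbs]
    drugs, compounds, chem = generate_chem(
        cfg, rng_chem, chem_herbs, plant["herb_properties"], ppi, disease_genes
    )
    target_pool = sorted({t for d in drugs for t in d.targets})
    annotations, planted_terms = generate_annotations(
        cfg, rng_ann, ppi, disease_genes, target_pool
    )
    gt = GroundTruth(
        top_herbs=plant["top_herbs"],
        qly_herbs=plant["qly_herbs"],
        core_herbs=plant["core_herbs"],
        herb_properties=plant["herb_properties"],
        chem_herbs=chem_herbs,
        herb_parent_drug=chem["herb_parent_drug"],
        compound_true_targets=chem["compound_true_targets"],
        disease_genes=disease_genes,
        planted_terms=planted_terms,
        property_drug_class=chem["property_drug_class"],
    )
    return SyntheticDataset(
        config=cfg,
        raw_corpus=raw,
        lexicon=lexicon,
        ppi=ppi,
        disease_genes=disease_genes,
        drugs=drugs,
        compounds=compounds,
        annotations=annotations,
        ground_truth=gt,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_corpus_tsv(ds.raw_corpus, out / "corpus.tsv")
    write_lexicon_tsv(ds.lexicon, out / "lexicon.tsv")
    write_ppi_tsv(ds.ppi, out / "ppi.tsv")
    write_gene_list(ds.disease_genes, out / "disease_genes.txt")
    write_drugs_tsv(ds.drugs, out / "drugs.tsv")
    write_compounds_tsv(ds.compounds, out / "compounds.tsv")
    write_gmt(ds.annotations, out / "annotations.gmt")
    (out / "ground_truth.json").write_text(
        json.dumps(ds.ground_truth.to_dict(), indent=1, sort_keys=True)
    )
    (out / "manifest.json").write_text(
        json.dumps({"config": dataclasses.asdict(ds.config)}, indent=1, sort_keys=True)
    )


def load_dataset(indir: str | Path) -> SyntheticDataset:
    ind = Path(indir)
    manifest = json.loads((ind / "manifest.json").read_text())
    cfg_dict = manifest["config"]
    cfg_dict["term_size_range"] = tuple(cfg_dict["term_size_range"])
    cfg = GeneratorConfig(**cfg_dict)
    return SyntheticDataset(
        config=cfg,
        raw_corpus=read_corpus_tsv(ind / "corpus.tsv"),
        lexicon=read_lexicon_tsv(ind / "lexicon.tsv"),
        ppi=read_ppi_tsv(ind / "ppi.tsv"),
        disease_genes=read_gene_list(ind / "disease_genes.txt"),
        drugs=read_drugs_tsv(ind / "drugs.tsv"),
        compounds=read_compounds_tsv(ind / "compounds.tsv"),
        annotations=read_gmt(ind / "annotations.gmt"),
        ground_truth=GroundTruth.from_dict(
            json.loads((ind / "ground_truth.json").read_text())
        ),
    )


# ---------------------------------------------------------------------------
# Small planted scenarios for stage-level recovery experiments


def generate_pair_recovery_corpus(
    rng: np.random.Generator,
    n_formulae: int = 100,
    n_herbs: int = 30,
    size: int = 10,
    pair_rate: float = 0.8,
    solo_rate: float = 0.2,
) -> tuple[list[Prescription], tuple[str, str]]:
    """Corpus with one herb pair planted adjacently against an independent
    background; the pair should attain the top pair score."""
    names = _herb_names(n_herbs)
    x, y = names[0], names[1]
    background = names[2:]
    corpus = []
    for i in range(n_formulae):
        if rng.random() < pair_rate:
            others = list(
                rng.choice(background, size=size - 2, replace=False)
            )
            offset = int(rng.integers(0, size - 1))
            herbs = others[:offset] + [x, y] + others[offset:]
        else:
            herbs = list(rng.choice(background, size=size, replace=False))
            for member in (x, y):
                if rng.random() < solo_rate:
                    herbs[int(rng.integers(len(herbs)))] = member
            if herbs.count(x) > 1 or herbs.count(y) > 1:  # cannot happen; guard
                herbs = list(dict.fromkeys(herbs))
        corpus.append(Prescription(id=f"Rx{i:04d}", herbs=tuple(herbs)))
    return corpus, (x, y)


def generate_target_recovery_instance(
    rng: np.random.Generator,
    n_nodes: int = 2000,
    attachment: int = 3,
    n_drugs: int = 16,
    drug_target_size: int = 8,
    n_compounds: int = 10,
    fingerprint_length: int = 128,
    fingerprint_density: float = 0.3,
    mutation_rate: float = 0.05,
) -> tuple[nx.Graph, list[ReferenceDrug], list[CompoundRecord], dict[str, list[str]]]:
    """Benchmark instance: compounds are near-copies of a parent drug and
    inherit its targets; the profile predictor should recover them."""
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=rng)
    ppi = nx.relabel_nodes(g, {i: f"G{i:04d}" for i in g.nodes})
    nodes = sorted(ppi.nodes)
    drugs = []
    for j in range(n_drugs):
        anchor = nodes[int(rng.integers(len(nodes)))]
        drugs.append(
            ReferenceDrug(
                id=f"drug{j:02d}",
                fingerprint=(
                    rng.random(fingerprint_length) < fingerprint_density
                ).astype(np.uint8),
                targets=_target_ball(ppi, anchor, drug_target_size),
                drug_class="other",
            )
        )
    compounds, truth = [], {}
    for j in range(n_compounds):
        parent = drugs[int(rng.integers(len(drugs)))]
        cid = f"cmp{j:02d}"
        compounds.append(
            CompoundRecord(
                id=cid,
                herb_ids=frozenset(["herb000"]),
                fingerprint=mutate_fingerprint(
                    parent.fingerprint, mutation_rate, rng
                ),
            )
        )
        truth[cid] = sorted(parent.targets)
    return ppi, drugs, compounds, truth


def generate_synergy_scenario(
    rng: np.random.Generator,
    n_nodes: int = 150,
    attachment: int = 2,
    n_background_herbs: int = 4,
    targets_per_herb: int = 4,
) -> tuple[nx.Graph, dict[str, list[str]], dict[str, str], tuple[str, str]]:
    """Background network with one planted synergistic herb pair.

    The pair's target sets live inside the hub's dense neighborhood and
    interlock there (they share the hub and one neighbor — compounds
    acting on the same network module); background herbs get mutually
    disjoint target sets drawn from nodes at distance >= 2 from the hub.
    Returns (background, target_sets, herb_of, planted_pair).
    """
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=rng)
    bg = nx.relabel_nodes(g, {i: f"G{i:04d}" for i in g.nodes})
    nodes = sorted(bg.nodes)
    hub = max(nodes, key=lambda v: bg.degree[v])
    neigh = sorted(bg.neighbors(hub))
    need = 2 * targets_per_herb - 3  # shared neighbor + exclusive members
    if len(neigh) < need:
        raise ValueError("hub neighborhood too small for the planted pair")
    shared = [hub, neigh[0]]
    rest = neigh[1:need]
    half = targets_per_herb - 2
    t_a = shared + rest[:half]
    t_b = shared + rest[half: 2 * half]
    target_sets = {"plantA:c00": t_a, "plantB:c00": t_b}
    herb_of = {"plantA:c00": "plantA", "plantB:c00": "plantB"}
    near_hub = set(neigh) | {hub}
    pool = [v for v in nodes if v not in near_hub]
    picks = rng.choice(
        len(pool), size=n_background_herbs * targets_per_herb, replace=False
    )
    for j in range(n_background_herbs):
        cid = f"bg{j}:c00"
        chunk = picks[j * targets_per_herb: (j + 1) * targets_per_herb]
        target_sets[cid] = [pool[i] for i in chunk]
        herb_of[cid] = f"bg{j}"
    return bg, target_sets, herb_of, ("plantA", "plantB")


def generate_bridge_scenario(
    rng: np.random.Generator,
    module_size: int = 140,
    attachment: int = 2,
    n_cold: int = 8,
    n_hot: int = 8,
    n_other: int = 8,
    compounds_per_herb: int = 3,
    n_immuno: int = 4,
    n_hormone: int = 3,
    drug_target_size: int = 8,
    ball_size: int = 12,
) -> tuple[
    nx.Graph, dict[str, list[str]], dict[str, str], dict[str, str],
    list[ReferenceDrug],
]:
    """Planted Cold<->immunomodulatory association on a two-module background.

    The background is two preferential-attachment modules joined by a
    two-node path, so immunomodulatory drug targets (inside module A) and
    hormone drug targets (module B) can neither overlap nor be adjacent.
    Cold herbs' compounds inherit immunomodulatory parents, Hot herbs'
    compounds hormone parents, the remaining herbs choose a class at
    random. Returns (background, compound_targets, compound_herb,
    herb_properties, drugs).
    """
    ga = nx.relabel_nodes(
        nx.barabasi_albert_graph(module_size, attachment, seed=rng),
        {i: f"A{i:04d}" for i in range(module_size)},
    )
    gb = nx.relabel_nodes(
        nx.barabasi_albert_graph(module_size, attachment, seed=rng),
        {i: f"B{i:04d}" for i in range(module_size)},
    )
    bg = nx.union(ga, gb)
    bg.add_edges_from([("A0000", "J0"), ("J0", "J1"), ("J1", "B0000")])

    def class_drugs(g: nx.Graph, prefix: str, k: int, cls: str) -> list[ReferenceDrug]:
        nodes = sorted(g.nodes)
        anchor = max(nodes, key=lambda v: g.degree[v])
        ball = sorted(_target_ball(g, anchor, ball_size))
        out = []
        for j in range(k):
            idx = rng.choice(len(ball), size=drug_target_size, replace=False)
            out.append(
                ReferenceDrug(
                    id=f"{prefix}{j}",
                    fingerprint=(rng.random(16) < 0.5).astype(np.uint8),
                    targets=frozenset(ball[i] for i in idx),
                    drug_class=cls,
                )
            )
        return out

    immuno = class_drugs(ga, "immuno", n_immuno, "immunomodulatory")
    hormone = class_drugs(gb, "hormone", n_hormone, "hormone")
    herb_properties: dict[str, str] = {}
    compound_targets: dict[str, list[str]] = {}
    compound_herb: dict[str, str] = {}
    specs = (
        [("Cold", "immunomodulatory")] * n_cold
        + [("Hot", "hormone")] * n_hot
        + [
            ("Warm" if j % 2 == 0 else "Neutral", None)
            for j in range(n_other)
        ]
    )
    for h, (prop, cls) in enumerate(specs):
        herb = f"bherb{h:02d}"
        herb_properties[herb] = prop
        if cls is None:
            cls = ("immunomodulatory", "hormone")[int(rng.integers(2))]
        pool = immuno if cls == "immunomodulatory" else hormone
        parent = pool[int(rng.integers(len(pool)))]
        for j in range(compounds_per_herb):
            cid = f"{herb}:c{j:02d}"
            tgt = sorted(parent.targets)
            idx = rng.choice(len(tgt), size=min(5, len(tgt)), replace=False)
            compound_targets[cid] = [tgt[i] for i in idx]
            compound_herb[cid] = herb
    return bg, compound_targets, compound_herb, herb_properties, immuno + hormone
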
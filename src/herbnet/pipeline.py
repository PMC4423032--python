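"""End-to-end orchestration: corpus -> core networks -> targets -> {synergy,
enrichment, bridge}, with per-stage outputs and a JSON run report.

Stages run in dependency order; each stage writes its outputs before the
next starts, so a failed run keeps everything produced so far. All
numeric knobs surface on :class:`RunConfig` with the defaults used
throughout the library.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import bridge as bridge_mod
from . import corpus as corpus_mod
from . import dmim as dmim_mod
from . import enrichment as enrich_mod
from . import synergy as synergy_mod
from . import targets as targets_mod
from .synthetic import (
    GeneratorConfig,
    SyntheticDataset,
    generate_dataset,
    load_dataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("corpus", "dmim", "targets", "synergy", "enrichment", "bridge")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "herbnet_run"
    seed: int = 0
    data_dir: str | None = None  # load a dataset directory instead of generating
    save_dataset: bool = False
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # dmim
    dmim_min_support: int = 5
    dmim_score_threshold: float = 0.0
    dmim_quantile: float | None = None
    dmim_clamp_negative_mi: bool = True
    dmim_log_base: float = 2.0
    dmim_normalize_distance: bool = False
    n_top_herbs: int = 10
    # targets
    profile_k: int = 100
    herb_target_min_support: int = 5
    # synergy
    nims_damping: float = 0.85
    nims_decay: str = "exp"
    nims_background: str = "disease_induced"  # or "full_ppi"
    make_plots: bool = False
    # enrichment
    n_enrichment_herbs: int = 15
    alpha: float = 0.05
    correction: str = "bh"
    # bridge
    bridge_top_n_herbs: int = 50
    bridge_per_drug_class: bool = True
    bridge_clustering: str = "components"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @property
    def edge_rule(self) -> dmim_mod.EdgeRule:
        return dmim_mod.EdgeRule(
            min_support=self.dmim_min_support,
            score_threshold=self.dmim_score_threshold,
            quantile=self.dmim_quantile,
            clamp_negative_mi=self.dmim_clamp_negative_mi,
            log_base=self.dmim_log_base,
            normalize_distance=self.dmim_normalize_distance,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            if "term_size_range" in gen:
                gen["term_size_range"] = tuple(gen["term_size_range"])
            cfg.generator = GeneratorConfig(**gen)
        if "seed" not in (gen or {}):
            cfg.generator = dataclasses.replace(cfg.generator, seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _acquire_dataset(cfg: RunConfig) -> SyntheticDataset:
    if cfg.data_dir is not None:
        return load_dataset(cfg.data_dir)
    gen = cfg.generator
    if gen.seed != cfg.seed:
        gen = dataclasses.replace(gen, seed=cfg.seed)
    return generate_dataset(gen)


# ---------------------------------------------------------------------------
# Stage functions (each returns its results plus a summary dict)


def stage_corpus(ds: SyntheticDataset, cfg: RunConfig, out: Path):
    corpus = corpus_mod.normalize_corpus(ds.raw_corpus, ds.lexicon)
    ft = corpus_mod.frequency_table(corpus)
    corpus_mod.write_frequency_tsv(ft, out / "frequency.tsv")
    summary = {
        "n_prescriptions": len(corpus),
        "n_herbs": len(ft.af),
        "mean_formula_size": sum(len(p) for p in corpus) / len(corpus),
        "top_herbs": corpus_mod.top_k_herbs(ft, cfg.n_top_herbs),
    }
    return corpus, ft, summary


def stage_dmim(corpus, ft, cfg: RunConfig, out: Path):
    rule = cfg.edge_rule
    index = dmim_mod.CorpusIndex(corpus)
    top = corpus_mod.top_k_herbs(ft, cfg.n_top_herbs)
    hfn = dmim_mod.high_frequency_network(index, top, rule)
    subnets = {seed: dmim_mod.seed_subnetwork(index, seed, rule) for seed in top}
    core = dmim_mod.intersect_subnetworks(list(subnets.values()))
    dmim_mod.write_edge_tsv(hfn, out / "high_frequency_network.tsv")
    dmim_mod.write_graphml(hfn, out / "high_frequency_network.graphml")
    dmim_mod.write_edge_tsv(core, out / "core_network.tsv")
    dmim_mod.write_graphml(core, out / "core_network.graphml")
    summary = {
        "high_frequency": {
            "n_nodes": hfn.number_of_nodes(),
            "n_edges": hfn.number_of_edges(),
        },
        "subnetworks": {
            s: {"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
            for s, g in subnets.items()
        },
        "core": {
            "n_nodes": core.number_of_nodes(),
            "n_edges": core.number_of_edges(),
        },
    }
    return hfn, subnets, core, summary


def stage_targets(ds: SyntheticDataset, cfg: RunConfig, out: Path):
    profiles = targets_mod.predict_profiles(
        ds.compounds, ds.drugs, ds.ppi, cfg.profile_k
    )
    herb_compounds: dict[str, list[str]] = {}
    for c in ds.compounds:
        for herb in sorted(c.herb_ids):
            herb_compounds.setdefault(herb, []).append(c.id)
    herb_sets = {
        herb: targets_mod.herb_target_set(
            herb,
            [profiles[cid] for cid in cids],
            cfg.herb_target_min_support,
        )
        for herb, cids in sorted(herb_compounds.items())
    }
    targets_mod.write_profiles_tsv(profiles, out / "target_profiles.tsv")
    with (out / "herb_targets.tsv").open("w") as fh:
        fh.write("herb\tn_targets\ttargets\n")
        for herb, hts in herb_sets.items():
            fh.write(f"{herb}\t{len(hts.targets)}\t{'|'.join(sorted(hts.targets))}\n")
    summary = {
        "n_profiles": len(profiles),
        "profile_k": cfg.profile_k,
        "herb_target_sizes": {h: len(s.targets) for h, s in herb_sets.items()},
    }
    return profiles, herb_sets, summary


def _background(ds: SyntheticDataset, cfg: RunConfig):
    if cfg.nims_background == "full_ppi":
        return ds.ppi
    return bridge_mod.restrict_background(ds.ppi, ds.disease_genes)


def stage_synergy(ds, cfg: RunConfig, core, profiles, out: Path):
    background = _background(ds, cfg)
    core_herbs = sorted(core.nodes) if core is not None else []
    target_sets, herb_of = {}, {}
    for c in ds.compounds:
        herb = sorted(c.herb_ids)[0]
        if core_herbs and herb not in core_herbs:
            continue
        if c.id in profiles:
            target_sets[c.id] = set(profiles[c.id].proteins)
            herb_of[c.id] = herb
    matrix = synergy_mod.synergy_matrix(
        target_sets, herb_of, background,
        damping=cfg.nims_damping, decay=cfg.nims_decay,
    )
    synergy_mod.write_synergy_tsv(matrix, out / "synergy_pairs.tsv")
    synergy_mod.write_herb_summary_tsv(matrix, out / "synergy_herb_pairs.tsv")
    if cfg.make_plots:
        synergy_mod.plot_heatmap(matrix, out / "synergy_heatmap.png")
    top_pairs = [
        {"herb_a": r.herb_a, "herb_b": r.herb_b, "mean_total": float(r.mean_total)}
        for r in matrix.herb_summary.head(5).itertuples(index=False)
    ]
    summary = {
        "n_compounds": len(matrix.compounds),
        "n_excluded": len(matrix.excluded),
        "background_nodes": background.number_of_nodes(),
        "top_herb_pairs": top_pairs,
    }
    return matrix, summary


def stage_enrichment(ds, cfg: RunConfig, ft, herb_sets, out: Path):
    universe = set(ds.ppi.nodes)
    top_herbs = corpus_mod.top_k_herbs(ft, cfg.n_enrichment_herbs)
    herb_query = set()
    for herb in top_herbs:
        if herb in herb_sets:
            herb_query |= set(herb_sets[herb].targets)
    herb_query &= universe
    disease_query = set(ds.disease_genes) & universe
    if not herb_query:
        raise ValueError("no herb targets available for enrichment")
    herb_res = enrich_mod.hypergeometric_enrichment(
        herb_query, ds.annotations, universe, method=cfg.correction
    )
    disease_res = enrich_mod.hypergeometric_enrichment(
        disease_query, ds.annotations, universe, method=cfg.correction
    )
    herb_terms = enrich_mod.enriched_terms(herb_res, cfg.alpha)
    disease_terms = enrich_mod.enriched_terms(disease_res, cfg.alpha)
    overlap = enrich_mod.overlap_analysis(herb_terms, disease_terms)
    herb_res.to_csv(out / "enrichment_herb_targets.tsv", sep="\t", index=False)
    disease_res.to_csv(out / "enrichment_disease_genes.tsv", sep="\t", index=False)
    enrich_mod.write_overlap_json(overlap, out / "enrichment_overlap.json")
    summary = {
        "n_herb_targets": len(herb_query),
        "n_disease_genes": len(disease_query),
        "n_enriched_herb_terms": len(herb_terms),
        "n_enriched_disease_terms": len(disease_terms),
        "n_shared_terms": len(overlap["shared"]),
    }
    return overlap, summary


def stage_bridge(ds, cfg: RunConfig, ft, profiles, out: Path):
    background = bridge_mod.restrict_background(ds.ppi, ds.disease_genes)
    top_herbs = set(corpus_mod.top_k_herbs(ft, cfg.bridge_top_n_herbs))
    compound_targets, compound_herb = {}, {}
    for c in ds.compounds:
        herb = sorted(c.herb_ids)[0]
        if herb in top_herbs and c.id in profiles:
            compound_targets[c.id] = set(profiles[c.id].proteins)
            compound_herb[c.id] = herb
    herb_props = {rec.standard_name: rec.property for rec in ds.lexicon}
    classes = sorted({d.drug_class for d in ds.drugs})
    groups = (
        [(cls, [d for d in ds.drugs if d.drug_class == cls]) for cls in classes]
        if cfg.bridge_per_drug_class
        else [("all", list(ds.drugs))]
    )
    summary: dict = {}
    results = {}
    for label, drugs in groups:
        net = bridge_mod.build_bridge_network(
            compound_targets, compound_herb, herb_props, drugs, background,
            clustering=cfg.bridge_clustering,
        )
        enr = bridge_mod.property_enrichment(net, herb_props)
        bridge_mod.write_bridge_graphml(net, out / f"bridge_{label}.graphml")
        bridge_mod.write_cluster_tsv(net, out / f"bridge_{label}_clusters.tsv")
        bridge_mod.write_enrichment_tsv(
            enr, out / f"bridge_{label}_property_enrichment.tsv"
        )
        sig = enr[enr["p_adj"] < cfg.alpha] if len(enr) else enr
        summary[label] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "n_clusters": len(set(net.clusters.values())),
            "significant_property_associations": [
                {
                    "cluster": int(r.cluster),
                    "property": r.property,
                    "odds_ratio": float(r.odds_ratio),
                    "p_adj": float(r.p_adj),
                }
                for r in sig.itertuples(index=False)
            ],
        }
        results[label] = (net, enr)
    return results, summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages in order and write ``run_report.json``.

    Returns the report: per-stage summaries keyed by stage name, plus the
    echoed configuration. Stage failures abort the run with the failing
    stage named; outputs of completed stages are retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": cfg.to_dict(),
        "stages": {},
        "skipped": [s for s in ALL_STAGES if s not in cfg.stages],
    }
    ds = _acquire_dataset(cfg)
    if cfg.save_dataset and cfg.data_dir is None:
        write_dataset(ds, out / "dataset")

    corpus = ft = core = profiles = herb_sets = None
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.monotonic()
        try:
            if stage == "corpus":
                corpus, ft, summary = stage_corpus(ds, cfg, out)
            elif stage == "dmim":
                if corpus is None:
                    corpus, ft, _ = stage_corpus(ds, cfg, out)
                _, _, core, summary = stage_dmim(corpus, ft, cfg, out)
            elif stage == "targets":
                profiles, herb_sets, summary = stage_targets(ds, cfg, out)
            elif stage == "synergy":
                if core is None:
                    if corpus is None:
                        corpus, ft, _ = stage_corpus(ds, cfg, out)
                    _, _, core, _ = stage_dmim(corpus, ft, cfg, out)
                if profiles is None:
                    profiles, herb_sets, _ = stage_targets(ds, cfg, out)
                _, summary = stage_synergy(ds, cfg, core, profiles, out)
            elif stage == "enrichment":
                if ft is None:
                    corpus, ft, _ = stage_corpus(ds, cfg, out)
                if herb_sets is None:
                    profiles, herb_sets, _ = stage_targets(ds, cfg, out)
                _, summary = stage_enrichment(ds, cfg, ft, herb_sets, out)
            elif stage == "bridge":
                if ft is None:
                    corpus, ft, _ = stage_corpus(ds, cfg, out)
                if profiles is None:
                    profiles, herb_sets, _ = stage_targets(ds, cfg, out)
                _, summary = stage_bridge(ds, cfg, ft, profiles, out)
        except Exception as exc:
            logger.error("stage %r failed: %s", stage, exc)
            report["failed_stage"] = stage
            (out / "run_report.json").write_text(
                json.dumps(report, indent=1, sort_keys=True, default=str)
            )
            raise
        summary["elapsed_s"] = round(time.monotonic() - t0, 3)
        report["stages"][stage] = summary
        logger.info("stage %s done in %.2fs", stage, summary["elapsed_s"])
    (out / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str)
    )
    return report
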
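"""End-to-end orchestration: parse -> cluster -> subdivide -> variants ->
structure -> paralogs -> trees, with TSV outputs and a run report.

The pipeline is a pure function of (inputs, config); repeated runs with
the same inputs produce identical outputs.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import core_io, homology, paralogs, phylo, structure, variants
from .core_io import (
    HairpinRecord,
    MatureRecord,
    PredictionFilter,
    RegionScheme,
    read_fasta,
    write_tsv,
)
from .synthetic_data import DEFAULT_CLADE_MAP

logger = logging.getLogger(__name__)

#: lineage assignment for the species named in the packaged variant table
TABLE1_CLADE_MAP = {
    "human": "ape", "chimpanzee": "ape", "bonobo": "ape", "gorilla": "ape",
    "orangutan": "ape", "gibbon": "ape",
    "macaque": "Old World monkey", "baboon": "Old World monkey",
    "marmoset": "New World monkey", "squirrel monkey": "New World monkey",
    "mouse lemur": "Strepsirrhine", "aye-aye": "Strepsirrhine",
    "galago": "Strepsirrhine",
}


@dataclass
class PipelineConfig:
    predictions: Optional[str] = None  # prediction table TSV
    genome_dir: Optional[str] = None  # per-species genome FASTAs for the paralog stage
    out_dir: str = "mirevol_out"
    min_score: float = 0.0
    min_depth: int = 3
    min_identity: float = 0.70
    min_length: int = 18
    subdivision_identity: float = 0.85
    min_species_variants: int = 3
    min_species_structure: int = 5
    n_shuffles: int = 50
    rng_seed: int = 0
    paralog_min_identity: float = 0.70
    paralog_min_length: int = 300
    paralog_pre_len: int = 83  # pre-miRNA length within centred locus windows
    paralog_reference: str = "human"  # species whose loci seed paralog queries
    paralog_queries: str = ""  # comma-separated paralog ids; empty = skip stage
    clade_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLADE_MAP))
    run_structure: bool = True
    run_trees: bool = True


@dataclass
class PipelineReport:
    n_matures: int = 0
    n_homology_groups: int = 0
    n_singletons: int = 0
    n_ortholog_groups: int = 0
    n_groups_structure: int = 0
    n_variants: int = 0
    n_variant_pairs: int = 0
    n_mirnas_with_variants: int = 0
    region_counts: dict = field(default_factory=dict)
    n_presence_calls: int = 0
    n_trees: int = 0
    config: dict = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    """Flat key=value config file; unknown keys are rejected."""
    cfg = PipelineConfig()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            setattr(cfg, key, value.lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, key, int(value))
        elif isinstance(current, float):
            setattr(cfg, key, float(value))
        elif isinstance(current, dict):
            setattr(cfg, key, json.loads(value))
        else:
            setattr(cfg, key, value)
    return cfg


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config={k: v for k, v in asdict(config).items()})

    # stage: parse
    hairpins: list[HairpinRecord] = []
    if config.predictions:
        hairpins = core_io.parse_prediction_table(
            config.predictions,
            PredictionFilter(min_score=config.min_score, min_depth=config.min_depth),
        )
    matures = core_io.matures_from_hairpins(hairpins)
    report.n_matures = len(matures)
    logger.info("parse: %d matures retained", len(matures))
    if not matures:
        write_tsv(out / "groups.tsv", ["group", "member", "species"], [])
        write_tsv(out / "variants.tsv",
                  ["microRNA", "variant", "position", "species"], [])
        (out / "report.json").write_text(json.dumps(asdict(report), indent=2))
        return report

    # stage: cluster
    filt = homology.MatchFilter(config.min_identity, config.min_length)
    hits = homology.all_vs_all(matures, filt)
    by_id = {m.id: m for m in matures}
    groups, singletons = homology.cluster_homologs(hits, by_id)
    report.n_homology_groups = len(groups)
    report.n_singletons = len(singletons)
    write_tsv(
        out / "groups.tsv",
        ["group", "member", "species"],
        [[g.id, m, by_id[m].species] for g in groups for m in g.members]
        + [["singleton", s, by_id[s].species] for s in singletons],
    )
    logger.info("cluster: %d groups, %d singletons", len(groups), len(singletons))

    # stage: subdivide
    ortholog_groups = []
    for g in groups:
        ortholog_groups.extend(
            homology.subdivide_orthologs(
                g, by_id, config.subdivision_identity,
                min_species=config.min_species_variants,
            )
        )
    report.n_ortholog_groups = len(ortholog_groups)
    write_tsv(
        out / "ortholog_groups.tsv",
        ["group", "parent", "member", "species"],
        [[og.id, og.parent, m.id, m.species]
         for og in ortholog_groups for m in og.members],
    )

    # stage: variants
    scheme = RegionScheme()
    all_variants = []
    for og in ortholog_groups:
        aln = {m.species: og.alignment[m.id] for m in og.members}
        calls = variants.call_variants(aln, scheme, mirna=og.id)
        all_variants.extend(calls.variants)
    summary = variants.summarize_variants(all_variants, config.clade_map)
    report.n_variants = summary.n_variants
    report.n_variant_pairs = summary.n_pairs
    report.n_mirnas_with_variants = summary.n_mirnas
    report.region_counts = summary.region_counts
    write_tsv(
        out / "variants.tsv",
        ["microRNA", "variant", "position", "species"],
        [[v.mirna, f"{v.ref_base} > {v.alt_base}", v.position, ", ".join(v.species)]
         for v in all_variants],
    )
    write_tsv(
        out / "variant_positions.tsv",
        ["position", "count"],
        sorted(summary.position_counts.items()),
    )
    write_tsv(
        out / "variant_summary.tsv",
        ["statistic", "value"],
        [["n_variants", summary.n_variants],
         ["n_variant_species_pairs", summary.n_pairs],
         ["n_mirnas_with_variants", summary.n_mirnas]]
        + [[f"region_{r}", c] for r, c in summary.region_counts.items()]
        + [[f"lineage_{l}", c] for l, c in sorted(summary.lineage_pair_counts.items())],
    )
    logger.info("variants: %d variants in %d miRNAs",
                summary.n_variants, summary.n_mirnas)

    # stage: structure
    if config.run_structure:
        hairpin_by_id = {h.id: h for h in hairpins}
        rows = []
        n_structural = 0
        for og in ortholog_groups:
            members = [m for m in og.members if m.id in hairpin_by_id]
            if len({m.species for m in members}) < config.min_species_structure:
                continue
            n_structural += 1
            pres = {m.species: hairpin_by_id[m.id].premirna for m in members}
            from .align import center_star_msa

            aln = center_star_msa(pres)
            cons = structure.sci(list(aln.values()))
            zs = [
                structure.z_score(
                    seq, config.n_shuffles,
                    rng_seed=(config.rng_seed + i) % (2**31),
                ).z
                for i, seq in enumerate(pres.values())
            ]
            rows.append([
                og.id, len(pres),
                f"{cons.mean_pairwise_identity:.4f}",
                f"{sum(zs) / len(zs):.3f}",
                f"{cons.sci:.4f}" if cons.defined else "NA",
                f"{cons.covariance_contribution:.3f}",
            ])
        report.n_groups_structure = n_structural
        write_tsv(
            out / "structure.tsv",
            ["group", "n_species", "mean_pairwise_identity", "mean_z", "sci",
             "covariance_contribution"],
            rows,
        )
        logger.info("structure: %d groups analyzed", n_structural)

    # stage: paralogs (optional; needs genomes and explicit queries)
    if config.genome_dir and config.paralog_queries:
        genome_dir = Path(config.genome_dir)
        genomes = {
            p.stem: dict(read_fasta(p)) for p in sorted(genome_dir.glob("*.fasta"))
        }
        ref = genomes.get(config.paralog_reference, {})
        thresholds = paralogs.ScanThresholds(
            min_identity=config.paralog_min_identity,
            min_length=config.paralog_min_length,
        )
        calls = []
        for pid in config.paralog_queries.split(","):
            pid = pid.strip()
            contig = f"{pid}_locus"
            if contig not in ref:
                logger.error("paralogs: query %s not in reference genome", pid)
                continue
            window = ref[contig]
            # reference pre-miRNA span: flanks are equal-length by construction
            query = paralogs.LocusQuery(
                pid, window, _centre_span(window, config.paralog_pre_len)
            )
            for sp, genome in genomes.items():
                ms = paralogs.scan_genome(query, genome, thresholds)
                ms = paralogs.filter_repetitive(ms, len(window))
                calls.append(paralogs.call_presence(query, ms, genome, species=sp))
        report.n_presence_calls = len(calls)
        write_tsv(
            out / "presence.tsv",
            ["paralog", "species", "status", "identity", "aligned_length"],
            [[c.paralog_id, c.species, c.status,
              f"{c.best_match.identity:.3f}" if c.best_match else "NA",
              c.best_match.aligned_length if c.best_match else "NA"]
             for c in calls],
        )
        logger.info("paralogs: %d presence calls", len(calls))

    # stage: trees
    if config.run_trees:
        tree_rows = []
        for og in ortholog_groups:
            aln = {m.species: og.alignment[m.id] for m in og.members}
            if len(aln) < 3:
                continue
            dm = phylo.p_distance_matrix(aln)
            tree_rows.append([og.id, phylo.nj_tree(dm).newick])
        report.n_trees = len(tree_rows)
        write_tsv(out / "trees.tsv", ["group", "newick"], tree_rows)
        logger.info("trees: %d trees built", len(tree_rows))

    (out / "report.json").write_text(json.dumps(asdict(report), indent=2))
    return report


def _centre_span(window: str, pre_len: int) -> tuple[int, int]:
    """Pre-miRNA span of a locus window with equal-length flanks."""
    a = (len(window) - pre_len) // 2
    return (a, a + pre_len)


def table1_check(fixture_path=None) -> variants.VariantSummary:
    """Recompute the summary statistics of the packaged mature-variant
    table (the printed study table transcribed to TSV)."""
    if fixture_path is None:
        fixture_path = importlib.resources.files("mirevol") / "data" / "table1_variants.tsv"
    scheme = RegionScheme()
    vs = []
    with open(fixture_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            ref, _, alt = row["variant"].partition(">")
            pos = int(row["position"])
            vs.append(
                variants.Variant(
                    mirna=row["microRNA"],
                    position=pos,
                    ref_base=ref.strip(),
                    alt_base=alt.strip(),
                    species=tuple(s.strip() for s in row["species"].split(",")),
                    region=scheme.classify(pos),
                )
            )
    return variants.summarize_variants(vs, TABLE1_CLADE_MAP)
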
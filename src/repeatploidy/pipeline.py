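"""End-to-end orchestration: simulate -> cluster -> abundance -> pairs ->
similarity -> report.

A single RunConfig drives the whole analysis on a simulated progenitor/
allopolyploid trio (or on user-supplied read files), producing a
Table-1-style genome-proportion report with parental-additivity and deficit
columns, a pair-classification summary, and a similarity comparison. All
randomness funnels through one seed; a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, cluster, pairs, similarity, simulate
from . import io as rio

log = logging.getLogger("repeatploidy")


@dataclass
class Thresholds:
    cluster_min_identity: float = 0.90
    cluster_min_overlap_frac: float = 0.55
    map_min_identity: float = 0.80
    map_min_read_frac: float = 0.50
    pair_min_identity: float = 0.90
    pair_min_read_frac: float = 0.55
    similarity_min_overlap: int = 100
    long_k: int = 13
    short_k: int = 11
    max_neighbors: int = 30


@dataclass
class RunConfig:
    seed: int = 0
    genome_length: int = 2_000_000
    tandem_elimination_fraction: float = 0.9
    whole_locus_losses: int = 0
    homogenisation_sweeps: int = 2
    coverage_long: float = 5.0
    coverage_paired: float = 2.0
    cluster_coverage: float = 0.5  # effective coverage used for clustering
    long_read_length: int = 360
    short_read_length: int = 100
    insert_size_mean: int = 300
    insert_size_sd: int = 30
    error_rate: float = 0.0
    n_rate: float = 0.0
    thresholds: Thresholds = field(default_factory=Thresholds)
    # optional pre-existing inputs; when unset the trio is simulated
    read_files: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


@dataclass
class RunResult:
    config: RunConfig
    genomes: dict
    readsets_long: dict
    readsets_paired: dict
    clusters: list
    contigs: list
    monomer: tuple | None
    gp_tables: dict
    additivity_table: pd.DataFrame
    pair_classifications: dict
    solo_profiles: dict
    similarity_distributions: dict
    similarity_comparison: similarity.LocationComparison | None
    report_text: str


def _child_seeds(seed: int, n: int):
    return [int(x) for x in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_trio(config: RunConfig):
    """Build the maternal/paternal/allopolyploid genomes and their read sets
    under the configured study conditions."""
    m_spec, p_spec, a_spec = simulate.default_trio(
        seed=config.seed, genome_length=config.genome_length,
        tandem_elimination_fraction=config.tandem_elimination_fraction,
        homogenisation_sweeps=config.homogenisation_sweeps,
        whole_locus_losses=config.whole_locus_losses,
    )
    genomes = {
        "maternal": simulate.build_genome(m_spec),
        "paternal": simulate.build_genome(p_spec),
        "allopolyploid": simulate.build_allopolyploid(a_spec),
    }
    seeds = _child_seeds(config.seed + 1, 6)
    readsets_long, readsets_paired = {}, {}
    for i, (sid, genome) in enumerate(sorted(genomes.items())):
        readsets_long[sid] = simulate.simulate_reads(genome, simulate.ReadSimParams(
            mode="long_single", read_length=config.long_read_length,
            coverage=config.coverage_long, error_rate=config.error_rate,
            n_rate=config.n_rate, seed=seeds[i]))
    for i, sid in enumerate(("paternal", "allopolyploid")):
        readsets_paired[sid] = simulate.simulate_reads(genomes[sid], simulate.ReadSimParams(
            mode="short_paired", read_length=config.short_read_length,
            insert_size_mean=config.insert_size_mean,
            insert_size_sd=config.insert_size_sd,
            coverage=config.coverage_paired, error_rate=config.error_rate,
            n_rate=config.n_rate, seed=seeds[3 + i]))
    return genomes, readsets_long, readsets_paired


def cluster_stage(readsets_long: dict, thr: Thresholds, min_cluster_reads: int = 15,
                  max_clusters: int = 4, subsample_fraction: float = 1.0):
    """Cluster the combined long-read dataset and assemble the top clusters.

    Repeat identification by mutual-similarity clustering presumes low-pass
    data: unique (single-copy) sequence must be sampled sparsely enough that
    its reads rarely overlap, while repeats — present in many copies — still
    pile up. ``subsample_fraction`` restores that regime when the read sets
    were sequenced deeper (reads are uniform and unordered, so a
    deterministic prefix subsample is unbiased); abundance estimation
    downstream still maps every read.
    """
    combined = {}
    for sid in sorted(readsets_long):
        reads = readsets_long[sid].reads
        n = int(round(subsample_fraction * len(reads)))
        combined.update({f"{sid}:{r.id}": r.seq for r in reads[:n]})
    min_ov = int(round(thr.cluster_min_overlap_frac *
                       np.median([len(s) for s in combined.values()])))
    graph = cluster.build_graph(combined, thr.cluster_min_identity, min_ov,
                                k=thr.long_k, max_neighbors=thr.max_neighbors)
    clusters = cluster.cluster_graph(graph)
    kept = [c for c in clusters if c.n_reads >= min_cluster_reads][:max_clusters]
    contigs = []
    for cl in kept:
        contigs.extend(cluster.assemble_contigs(cl, combined,
                                                thr.cluster_min_identity,
                                                min_overlap=40, k=thr.long_k))
    return kept, contigs


def run_all(config: RunConfig, outdir=None) -> RunResult:
    """Execute every stage and (optionally) write the report bundle."""
    t0 = time.time()
    thr = config.thresholds
    log.info("stage=simulate seed=%d genome=%d bp", config.seed, config.genome_length)
    genomes, readsets_long, readsets_paired = simulate_trio(config)

    log.info("stage=cluster reads=%d", sum(len(r.reads) for r in readsets_long.values()))
    frac = min(1.0, config.cluster_coverage / config.coverage_long)
    clusters, contigs = cluster_stage(readsets_long, thr, subsample_fraction=frac)
    if not clusters:
        raise RuntimeError("no repeat clusters found")
    # the analysis focuses on the tandem satellite: take the largest cluster
    # whose main contig shows a tandem period (dispersed families and
    # background chains have none)
    top, monomer = None, None
    for cl in clusters:
        if cl.contigs:
            mono = cluster.detect_monomer(cl.contigs[0])
            if mono is not None:
                top, monomer = cl, mono
                break
    if top is None:
        top = clusters[0]
    main_contig = top.contigs[0]
    log.info("stage=cluster clusters=%d main_contig=%s len=%d monomer=%s",
             len(clusters), main_contig.contig_id, main_contig.length,
             monomer[0] if monomer else None)

    log.info("stage=abundance")
    gp_tables = {}
    family_reads = {}
    for sid, rs in sorted(readsets_long.items()):
        reads = rs.as_dict()
        mappings = abundance.map_reads(reads, contigs, thr.map_min_identity,
                                       thr.map_min_read_frac, k=thr.long_k)
        gp_tables[sid] = abundance.compute_gp(mappings, contigs, rs.total_bases,
                                              clusters=clusters)
        top_ids = {c.contig_id for c in top.contigs}
        family_reads[sid] = {m.read_id: reads[m.read_id] for m in mappings
                             if m.contig_id in top_ids}

    rows = []
    for cl in clusters:
        gp_m = gp_tables["maternal"].cluster_gp(cl.cluster_id)
        gp_p = gp_tables["paternal"].cluster_gp(cl.cluster_id)
        gp_o = gp_tables["allopolyploid"].cluster_gp(cl.cluster_id)
        exp = abundance.additivity(gp_m, gp_p)
        rows.append({
            "cluster_id": cl.cluster_id,
            "most_abundant_contig": cl.contigs[0].contig_id if cl.contigs else "",
            "contig_length": cl.contigs[0].length if cl.contigs else 0,
            "gp_maternal": gp_m, "gp_paternal": gp_p,
            "gp_expected": exp, "gp_observed": gp_o,
            "deficit_ratio": abundance.deficit(gp_o, exp),
        })
    additivity_table = pd.DataFrame(rows).set_index("cluster_id")

    log.info("stage=pairs")
    pair_cls, profiles = {}, {}
    for sid, rs in sorted(readsets_paired.items()):
        qc = pairs.qc_filter(list(rs.pairs()),
                             min_length=min(95, config.short_read_length),
                             trim_to=min(95, config.short_read_length))
        pc = pairs.classify_pairs(qc, main_contig, top.contigs,
                                  thr.pair_min_identity, thr.pair_min_read_frac,
                                  k=thr.short_k)
        pair_cls[sid] = pc
        if monomer:
            profiles[sid] = pairs.solo_profile(pc, main_contig.monomer[0], monomer[0])

    log.info("stage=similarity")
    sim_dists = {}
    for sid in sorted(family_reads):
        sim_dists[sid] = similarity.pairwise_similarity(
            family_reads[sid], sample_id=sid,
            min_overlap=thr.similarity_min_overlap, k=thr.long_k)
    comparison = None
    if (sim_dists.get("paternal") is not None and sim_dists.get("allopolyploid") is not None
            and sim_dists["paternal"].scores.size and sim_dists["allopolyploid"].scores.size):
        comparison = similarity.compare_locations(sim_dists["paternal"],
                                                  sim_dists["allopolyploid"])

    report = report_table(additivity_table)
    result = RunResult(config, genomes, readsets_long, readsets_paired, clusters,
                       contigs, monomer, gp_tables, additivity_table, pair_cls,
                       profiles, sim_dists, comparison, report)
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    log.info("stage=done wall=%.1fs", time.time() - t0)
    return result


def report_table(additivity_table: pd.DataFrame) -> str:
    """Formatted per-cluster abundance table: cluster, most abundant contig
    (length), parental GPs, parental additivity, observed GP. Values to two
    decimals, below-detection as "<0.01", missing samples as "NA"."""
    fmt = abundance.format_gp
    header = (f"{'cluster':<10}{'most abundant contig (bp)':<28}"
              f"{'maternal':>10}{'paternal':>10}{'additivity':>12}{'observed':>10}")
    lines = [header, "-" * len(header)]
    for cid, row in additivity_table.iterrows():
        contig = f"{row['most_abundant_contig']}({int(row['contig_length'])})"
        lines.append(
            f"{cid:<10}{contig:<28}"
            f"{fmt(row['gp_maternal']):>10}{fmt(row['gp_paternal']):>10}"
            f"{fmt(row['gp_expected']):>12}{fmt(row['gp_observed']):>10}"
        )
    return "\n".join(lines)


def summary_dict(result: RunResult) -> dict:
    """Flat JSON-ready summary of the run's headline numbers."""
    top = result.clusters[0].cluster_id
    at = result.additivity_table
    out = {
        "seed": result.config.seed,
        "genome_length": result.config.genome_length,
        "monomer_length": result.monomer[0] if result.monomer else None,
        "clusters": {cid: {k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                           for k, v in row.items() if k != "most_abundant_contig"}
                     for cid, row in at.iterrows()},
        "solo_fractions": {sid: pc.solo_fraction
                           for sid, pc in result.pair_classifications.items()},
        "similarity_means": {sid: d.mean for sid, d in
                             result.similarity_distributions.items() if d.scores.size},
    }
    if result.similarity_comparison is not None:
        c = result.similarity_comparison
        out["similarity_test"] = {"mean_a": c.mean_a, "mean_b": c.mean_b,
                                  "statistic": c.statistic, "p": c.pvalue,
                                  "method": c.method, "note": c.note}
    out["top_cluster"] = top
    return out


def _write_bundle(result: RunResult, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, genome in result.genomes.items():
        rio.write_genome(genome, outdir / "genomes")
    for sid, rs in result.readsets_long.items():
        rio.write_fastq(rs, outdir / f"{sid}.long.fastq")
    for sid, rs in result.readsets_paired.items():
        rio.write_fastq(rs, outdir / f"{sid}.paired.fastq")
    rio.write_fasta({c.contig_id: c.sequence for c in result.contigs},
                    outdir / "contigs.fasta")
    if result.monomer:
        rio.write_fasta({"monomer": result.monomer[1]}, outdir / "monomer.fasta")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("read_id\tcluster_id\n")
        for cl in result.clusters:
            for rid in cl.reads:
                fh.write(f"{rid}\t{cl.cluster_id}\n")
    result.additivity_table.to_csv(outdir / "gp_table.tsv", sep="\t")
    for sid, prof in result.solo_profiles.items():
        pd.DataFrame({"monomer_pos": np.arange(prof.monomer_length),
                      "solo_prop": prof.proportion,
                      "coverage": prof.total_coverage}).to_csv(
            outdir / f"{sid}.solo_profile.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary_dict(result), fh, indent=2, default=float)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(result.report_text + "\n")
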
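"""End-to-end pipeline: indices -> matrices -> tree -> decisions.

Stages run in dependency order with per-stage caching keyed by the config
hash; rerunning with an identical config loads every stage from cache.  A
manifest records the config hash, package version and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import indices as ix
from . import phylo, taxonomy
from .io import (GeneSet, GenomeRecord, Proteome, RunConfig, SeqEntry,
                 format_value, read_clades_tsv, read_fasta, write_tsv,
                 INDEX_DECIMALS)

logger = logging.getLogger("gbtax")


@dataclass
class PipelineResult:
    matrices: dict[str, ix.IndexMatrix] = field(default_factory=dict)
    decisions: list[taxonomy.TaxonomicDecision] = field(default_factory=list)
    scan: taxonomy.BoundaryScanResult | None = None
    tree: object = None
    manifest: dict = field(default_factory=dict)
    cache_hits: list[str] = field(default_factory=list)


def _matrix_tsv(matrix: ix.IndexMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(matrix.genome_ids) + "\n")
        for i, g in enumerate(matrix.genome_ids):
            vals = [format_value(None if np.isnan(v) else float(v))
                    for v in matrix.values[i]]
            fh.write(g + "\t" + "\t".join(vals) + "\n")


def read_matrix_tsv(path: str | Path, index_name: str) -> ix.IndexMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")[1:]
            rows.append([np.nan if p == "NA" else float(p) for p in parts])
    return ix.IndexMatrix(genome_ids=header, values=np.array(rows),
                          index_name=index_name)


def _load_inputs(cfg: RunConfig):
    genomes, proteomes, genesets, rrnas = {}, {}, {}, {}
    for g in cfg.genomes:
        gid = g.genome_id
        genomes[gid] = (GenomeRecord(gid, tuple(read_fasta(g.genome_fasta, "dna")))
                        if g.genome_fasta else None)
        proteomes[gid] = (Proteome(gid, tuple(read_fasta(g.proteome_fasta, "protein")))
                          if g.proteome_fasta else None)
        genesets[gid] = (GeneSet(gid, tuple(read_fasta(g.cds_fasta, "dna")))
                         if g.cds_fasta else None)
        if g.rrna_fasta:
            recs = read_fasta(g.rrna_fasta, "dna")
            rrnas[gid] = SeqEntry(gid, recs[0].seq) if recs else None
        else:
            rrnas[gid] = None
    return genomes, proteomes, genesets, rrnas


_INPUT_KIND = {"AAI": "proteome", "POCP": "proteome", "ANI": "genome",
               "dDDH_f2": "genome", "gANI": "geneset", "AF": "geneset",
               "SSU_identity": "rrna"}


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the configured stages; see module docstring."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(cfg.out_dir)
    cache = out / "cache"
    cache.mkdir(parents=True, exist_ok=True)
    h = cfg.content_hash()
    result = PipelineResult()
    genomes, proteomes, genesets, rrnas = _load_inputs(cfg)
    pools = {"genome": genomes, "proteome": proteomes,
             "geneset": genesets, "rrna": rrnas}

    for index_name in cfg.indices:
        t0 = time.time()
        cache_file = cache / f"{index_name}-{h}.tsv"
        if cache_file.exists():
            matrix = read_matrix_tsv(cache_file, index_name)
            result.cache_hits.append(index_name)
            logger.info("%s: cache hit (%s)", index_name, cache_file.name)
        else:
            pool = pools[_INPUT_KIND[index_name]]
            try:
                matrix = ix.build_index_matrix(pool, index_name,
                                               **cfg.params.get(index_name, {}))
            except Exception as err:
                raise RuntimeError(f"stage {index_name!r} failed: {err}") from err
            _matrix_tsv(matrix, cache_file)
            n_pairs = len(matrix.genome_ids) * (len(matrix.genome_ids) - 1) // 2
            logger.info("%s: %d pairs in %.1fs", index_name, n_pairs,
                        time.time() - t0)
        result.matrices[index_name] = matrix
        _matrix_tsv(matrix, out / f"{index_name}.matrix.tsv")
        write_tsv(matrix.to_long_rows(), out / f"{index_name}.long.tsv",
                  columns=["genome_a", "genome_b", "index", "value"])
        if matrix.skipped:
            write_tsv([{"genome_id": g, "reason": r} for g, r in matrix.skipped],
                      out / f"{index_name}.skipped.tsv",
                      columns=["genome_id", "reason"])

    # pairwise decisions from whatever matrices were computed
    ids = sorted({g.genome_id for g in cfg.genomes})
    decision_rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            values = {}
            for name, m in result.matrices.items():
                if a in m.genome_ids and b in m.genome_ids:
                    v = m.value(a, b)
                    values[name] = None if np.isnan(v) else v
            if not any(v is not None for v in values.values()):
                continue
            d = taxonomy.classify_pair(values, genome_a=a, genome_b=b)
            result.decisions.append(d)
            decision_rows.append({
                "genome_a": a, "genome_b": b, "consensus": d.consensus,
                "exception_flag": d.exception_flag,
                "votes": ";".join(f"{k}={v}" for k, v in sorted(d.votes.items())),
            })
    if decision_rows:
        write_tsv(decision_rows, out / "decisions.tsv",
                  columns=["genome_a", "genome_b", "consensus",
                           "exception_flag", "votes"])

    # clade boundary scan on the AAI matrix
    if cfg.clades_tsv and "AAI" in result.matrices:
        clades = read_clades_tsv(cfg.clades_tsv)
        result.scan = taxonomy.boundary_scan(result.matrices["AAI"], clades)
        if result.scan.band:
            write_tsv([{
                "min_intra": result.scan.min_intra[0],
                "min_intra_pair": "|".join(result.scan.min_intra[1]),
                "max_inter": result.scan.max_inter[0],
                "max_inter_pair": "|".join(result.scan.max_inter[1]),
            }], out / "boundary_scan.tsv",
                columns=["min_intra", "min_intra_pair", "max_inter",
                         "max_inter_pair"])

    # marker phylogeny (protein markers, NJ + bootstrap)
    if cfg.marker_fasta:
        seeds = read_fasta(cfg.marker_fasta, "protein")
        marker_set = phylo.MarkerSet.from_seed_entries("markers", seeds)
        per_marker: dict[str, dict[str, SeqEntry]] = {m: {} for m in marker_set.marker_ids}
        for gid, prot in proteomes.items():
            if prot is None:
                continue
            ext = phylo.extract_markers(prot, marker_set)
            for mid, entry in ext.found.items():
                per_marker[mid][gid] = entry
        msas = {}
        for mid, by_taxon in per_marker.items():
            if len(by_taxon) < 2:
                continue
            entries = [SeqEntry(gid, e.seq) for gid, e in sorted(by_taxon.items())]
            msas[mid] = phylo.align_marker(entries)
        if msas:
            taxa = sorted(gid for gid, p in proteomes.items() if p is not None)
            cat = phylo.concatenate(msas, taxa)
            if len(taxa) >= 4:
                tree, supports = phylo.bootstrap_support(
                    cat, cfg.bootstrap_replicates, seed=cfg.seed)
            else:
                tree = phylo.nj_tree(phylo.distance_matrix(cat))
            result.tree = tree
            phylo.write_newick(tree, out / "markers.nj.nwk")
            phylo.write_partitions(cat, out / "markers.partitions.txt")

    result.manifest = {"config_hash": h, "version": __version__,
                       "seed": cfg.seed, "indices": cfg.indices,
                       "cache_hits": result.cache_hits}
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return result
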
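"""Genome-based taxonomic decision layer.

Three operations sit on top of the relatedness indices:

* a clade-resolved AAI boundary scan - the minimum intra-clade and maximum
  inter-clade AAI over a labeled genome set, which brackets the AAI band
  usable as a genus demarcation for the group under study;
* a multi-index threshold classifier for a genome pair, combining species
  proxies (dDDH >= 70, ANI >= 95), the AAI genus band, supportive genus
  indices (POCP, gANI/AF) and a 16S rRNA identity veto: inter-genus 16S
  identity below 94.5% overrides genome-index evidence of congenericity
  (the discordance observed in several thermophilic families), and the
  conflict is flagged rather than averaged away;
* approximate ortholog clustering (reciprocal-best-hit graph components)
  giving core / shared / singleton counts for small genome panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from . import align as ak
from .indices import IndexMatrix
from .io import Proteome

RANK_ORDER = {"different_genus": 0, "uncertain": 1, "same_genus": 2,
              "same_species": 3}


@dataclass(frozen=True)
class ThresholdConfig:
    """Index thresholds used by the classifier (all in index units).

    Defaults follow the values commonly applied in genome-based prokaryote
    taxonomy: 70% dDDH / 95% ANI for species circumscription, a refined
    60-62% AAI genus band (within the broader 60-80% literature band),
    POCP >= 50%, the published gANI/AF genus-level means and medians, and
    the 94.5% 16S rRNA gene identity genus cutoff.
    """

    species_ddh: float = 70.0
    species_ani: float = 95.0
    genus_aai_band: tuple[float, float] = (60.0, 62.0)
    genus_aai_literature_band: tuple[float, float] = (60.0, 80.0)
    genus_gani_mean: float = 73.98
    genus_gani_median: float = 73.11
    genus_af_mean: float = 0.33
    genus_af_median: float = 0.345
    genus_pocp: float = 50.0
    genus_ssu: float = 94.5

    def __post_init__(self):
        lo, hi = self.genus_aai_band
        if lo > hi:
            raise ValueError("genus AAI band low must not exceed high")


@dataclass
class TaxonomicDecision:
    """Per-index votes, consensus rank call and conflict flags for a pair."""

    genome_a: str
    genome_b: str
    votes: dict[str, str]                   # index -> vote
    consensus: str
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    exception_flag: bool = False            # 16S veto overrode genome indices


def classify_pair(index_values: Mapping[str, float],
                  thresholds: ThresholdConfig = ThresholdConfig(),
                  genome_a: str = "A", genome_b: str = "B"
                  ) -> TaxonomicDecision:
    """Threshold classification of one genome pair.

    Votes: dDDH >= 70 or ANI >= 95 vote same_species; AAI votes same_genus
    above the band, different_genus below it, and abstains inside it
    (deferring to phylogeny); POCP and gANI/AF above their thresholds are
    supportive same_genus votes, never vetoes; 16S identity below the genus
    cutoff is a different_genus veto that overrides genome-index same_genus
    evidence and raises the exception flag.
    """
    v = {k: index_values[k] for k in index_values if index_values[k] is not None}
    if not v:
        raise ValueError("at least one index value is required")
    t = thresholds
    votes: dict[str, str] = {}
    if "dDDH_f2" in v:
        votes["dDDH_f2"] = "same_species" if v["dDDH_f2"] >= t.species_ddh else "abstain"
    if "ANI" in v:
        votes["ANI"] = "same_species" if v["ANI"] >= t.species_ani else "abstain"
    if "AAI" in v:
        lo, hi = t.genus_aai_band
        if v["AAI"] > hi:
            votes["AAI"] = "same_genus"
        elif v["AAI"] < lo:
            votes["AAI"] = "different_genus"
        else:
            votes["AAI"] = "abstain"
    if "POCP" in v:
        votes["POCP"] = "same_genus" if v["POCP"] >= t.genus_pocp else "abstain"
    if "gANI" in v:
        votes["gANI"] = ("same_genus"
                         if v["gANI"] > t.genus_gani_mean and v["gANI"] > t.genus_gani_median
                         else "abstain")
    if "AF" in v:
        votes["AF"] = ("same_genus"
                       if v["AF"] > t.genus_af_mean and v["AF"] > t.genus_af_median
                       else "abstain")
    if "SSU_identity" in v:
        votes["SSU_identity"] = ("different_genus"
                                 if v["SSU_identity"] < t.genus_ssu else "abstain")

    ssu_veto = votes.get("SSU_identity") == "different_genus"
    genus_for = [k for k, x in votes.items() if x == "same_genus"]
    genus_against = [k for k, x in votes.items() if x == "different_genus"]
    species_for = [k for k, x in votes.items() if x == "same_species"]

    conflicts: list[tuple[str, str]] = []
    exception_flag = False
    if genus_for and genus_against:
        for k in genus_against:
            conflicts.append((k, f"votes different_genus against {'/'.join(genus_for)}"))
    if ssu_veto and (genus_for or species_for):
        exception_flag = True

    # the 16S veto overrides genome-index *genus* evidence; a species-level
    # call (dDDH/ANI above threshold) stands, with the discordance flagged
    if species_for:
        consensus = "same_species"
    elif ssu_veto:
        consensus = "different_genus"
    elif genus_for and not genus_against:
        consensus = "same_genus"
    elif genus_against and not genus_for:
        consensus = "different_genus"
    elif len(genus_for) > len(genus_against):
        consensus = "same_genus"
    elif len(genus_against) > len(genus_for):
        consensus = "different_genus"
    else:
        consensus = "uncertain"
    return TaxonomicDecision(genome_a=genome_a, genome_b=genome_b, votes=votes,
                             consensus=consensus, conflicts=conflicts,
                             exception_flag=exception_flag)


# ---------------------------------------------------------------------------
# Boundary scan
# ---------------------------------------------------------------------------


@dataclass
class BoundaryScanResult:
    """Minimum intra-clade and maximum inter-clade index values."""

    min_intra: tuple[float, tuple[str, str]] | None
    max_inter: tuple[float, tuple[str, str]] | None
    band: tuple[float, float] | None            # (min_intra, max_inter)
    rounded_band: tuple[int, int] | None        # nearest-integer context
    intra_by_clade: dict[str, list[float]] = field(default_factory=dict)
    excluded_clades: list[tuple[str, str]] = field(default_factory=list)


def boundary_scan(matrix: IndexMatrix, clades: Mapping[str, str],
                  exclusions: Sequence[str] = ()) -> BoundaryScanResult:
    """Scan an all-vs-all matrix for the intra/inter clade value boundary.

    ``clades`` labels every genome in the matrix (unlabeled genomes are an
    error); genomes of excluded clades are dropped from the scan entirely
    (mirroring the exclusion of families whose 16S signal contradicts the
    genome indices).  Single-member clades contribute no intra pairs.
    """
    ids = matrix.genome_ids
    unlabeled = [g for g in ids if g not in clades]
    if unlabeled:
        raise ValueError(f"unlabeled genomes: {unlabeled}")
    excluded = [(c, "excluded by caller") for c in exclusions]
    keep = [g for g in ids if clades[g] not in set(exclusions)]
    min_intra = max_inter = None
    intra_by_clade: dict[str, list[float]] = {}
    for ii, a in enumerate(keep):
        for b in keep[ii + 1:]:
            val = matrix.value(a, b)
            if np.isnan(val):
                continue
            if clades[a] == clades[b]:
                intra_by_clade.setdefault(clades[a], []).append(val)
                if min_intra is None or val < min_intra[0]:
                    min_intra = (val, (a, b))
            else:
                if max_inter is None or val > max_inter[0]:
                    max_inter = (val, (a, b))
    band = (min_intra[0], max_inter[0]) if (min_intra and max_inter) else None
    rounded = ((round(band[0]), round(band[1])) if band else None)
    return BoundaryScanResult(min_intra=min_intra, max_inter=max_inter,
                              band=band, rounded_band=rounded,
                              intra_by_clade=intra_by_clade,
                              excluded_clades=excluded)


# ---------------------------------------------------------------------------
# Consensus report
# ---------------------------------------------------------------------------


@dataclass
class ConsensusReport:
    query: str
    decisions: list[TaxonomicDecision]          # sorted by AAI desc
    best_same_species: str | None
    best_same_genus: str | None
    conclusion: str
    text: str


def consensus_report(query_id: str,
                     reference_values: Mapping[str, Mapping[str, float]],
                     thresholds: ThresholdConfig = ThresholdConfig()
                     ) -> ConsensusReport:
    """Rank references against a query and draw the placement conclusion.

    ``reference_values`` maps reference genome id to its index values
    against the query.  References are sorted by AAI (descending; absent
    AAI sorts last).  The conclusion names the best same-species or
    same-genus candidate, or calls a novel species/genus.
    """
    if not reference_values:
        raise ValueError("empty reference set")
    order = sorted(reference_values,
                   key=lambda r: (-(reference_values[r].get("AAI") or -1), r))
    decisions = [classify_pair(reference_values[r], thresholds,
                               genome_a=query_id, genome_b=r) for r in order]
    best_sp = next((d.genome_b for d in decisions if d.consensus == "same_species"), None)
    best_gen = next((d.genome_b for d in decisions if d.consensus
                     in ("same_species", "same_genus")), None)
    if best_sp:
        conclusion = f"{query_id} is conspecific with {best_sp}"
    elif best_gen:
        conclusion = (f"{query_id} is a novel species within the genus of {best_gen}")
    elif any(d.consensus == "uncertain" for d in decisions):
        conclusion = (f"{query_id}: uncertain - phylogeny required")
    else:
        conclusion = (f"{query_id} represents a novel genus")
    lines = [f"Taxonomic placement of {query_id}",
             f"{'reference':<24}{'AAI':>8}  consensus"]
    for d in decisions:
        aai = reference_values[d.genome_b].get("AAI")
        lines.append(f"{d.genome_b:<24}{(f'{aai:.2f}' if aai is not None else 'NA'):>8}"
                     f"  {d.consensus}" + ("  [16S veto]" if d.exception_flag else ""))
    lines.append(f"Conclusion: {conclusion}")
    return ConsensusReport(query=query_id, decisions=decisions,
                           best_same_species=best_sp, best_same_genus=best_gen,
                           conclusion=conclusion, text="\n".join(lines))


# ---------------------------------------------------------------------------
# Ortholog clusters (approximate Venn counts)
# ---------------------------------------------------------------------------


@dataclass
class OrthologClusters:
    """Connected-component protein clusters over the RBH graph.

    Counts are approximate relative to dedicated orthology pipelines and
    are labeled as such in reports.
    """

    clusters: list[list[tuple[str, str]]]       # [(genome, protein_id), ...]
    core_clusters: int
    singletons_by_genome: dict[str, int]
    n_genomes: int


def ortholog_clusters(proteomes: Sequence[Proteome],
                      min_identity: float = 20.0, min_coverage: float = 0.7
                      ) -> OrthologClusters:
    """Cluster proteins of >= 2 genomes by reciprocal best hits.

    Edges are RBH pairs passing the AAI-style cutoffs; clusters are the
    connected components; a core cluster contains at least one protein from
    every genome; a singleton is a protein with no edge at all.  The result
    is invariant to the order of the input proteomes.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 proteomes")
    order = sorted(range(len(proteomes)), key=lambda i: proteomes[i].genome_id)
    proteomes = [proteomes[i] for i in order]
    g = nx.Graph()
    for p in proteomes:
        for prot in p.proteins:
            g.add_node((p.genome_id, prot.id))
    indexes = {p.genome_id: ak.ProteomeKmerIndex(p) for p in proteomes}
    for i, pa in enumerate(proteomes):
        for pb in proteomes[i + 1:]:
            hits_ab = ak.search(pa, pb, index=indexes[pb.genome_id])
            hits_ba = ak.search(pb, pa, index=indexes[pa.genome_id])
            for pair in ak.reciprocal_best_hits(hits_ab, hits_ba):
                if (min(pair.hit_ab.percent_identity,
                        pair.hit_ba.percent_identity) < min_identity
                        or min(pair.hit_ab.query_coverage,
                               pair.hit_ba.query_coverage) < min_coverage):
                    continue
                g.add_edge((pa.genome_id, pair.gene_a), (pb.genome_id, pair.gene_b))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort()
    genome_ids = [p.genome_id for p in proteomes]
    core = sum(1 for c in comps
               if {gid for gid, _ in c} == set(genome_ids))
    singles = {gid: 0 for gid in genome_ids}
    for c in comps:
        if len(c) == 1:
            singles[c[0][0]] += 1
    return OrthologClusters(clusters=comps, core_clusters=core,
                            singletons_by_genome=singles,
                            n_genomes=len(genome_ids))
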
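"""Comparative genomics: all-vs-all protein similarity, AAI, POCP, gene ANI,
orthologue clustering, core/pan-genome curves, dereplication, SCG selection.

Conventions follow the genus/species-delimitation literature: POCP =
(C1 + C2) / (T1 + T2) x 100 with conserved proteins requiring identity and
coverage strictly over 50%; AAI is the mean identity of reciprocal best hits
(coverage >= 50%, identity >= 30%), with ~65% marking a genus boundary; gene ANI
is the mean identity of reciprocal-best gene pairs under global alignment, with
~95% marking a species boundary. An orthologue cluster is a connected component
over hits with at least 50% identity and 50% query coverage (inclusive).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import global_align_nuc, kmer_set, local_align

HIT_COLUMNS = ["query_id", "query_genome", "subject_id", "subject_genome",
               "identity", "query_coverage", "subject_coverage", "score"]

ORTHOLOGUE_MIN_IDENTITY = 50.0   # inclusive ("at least")
ORTHOLOGUE_MIN_COVERAGE = 50.0   # inclusive
POCP_MIN_IDENTITY = 50.0         # strict ("over")
POCP_MIN_COVERAGE = 50.0         # strict
AAI_MIN_COVERAGE = 50.0
AAI_MIN_IDENTITY = 30.0
DEREP_ANI = 99.0                 # strict ">99%"
GENUS_AAI = 65.0
SPECIES_ANI = 95.0

Proteome = Sequence[Tuple[str, str]]  # (protein_id, sequence)


class UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)

    def components(self) -> List[List[str]]:
        groups: Dict[str, List[str]] = {}
        for item in self.parent:
            groups.setdefault(self.find(item), []).append(item)
        return sorted([sorted(g) for g in groups.values()])


def all_vs_all(proteomes: Dict[str, Proteome], prefilter: bool = True,
               kmer_size: int = 4, min_shared_kmers: int = 3) -> pd.DataFrame:
    """Every ordered cross-genome protein pair with a positive local alignment.

    Alignments are computed once per unordered pair and reported in both
    directions (coverage is direction-specific, identity and score are not).
    A shared-k-mer seed prefilter skips hopeless pairs; disable it when exact
    behaviour on arbitrary low-identity pairs is required.
    """
    if len(proteomes) < 2:
        raise ValueError("all_vs_all needs at least two proteomes")
    entries = [(gid, pid, seq) for gid in sorted(proteomes)
               for pid, seq in proteomes[gid]]
    kmers = [kmer_set(seq, kmer_size) if prefilter else None
             for _, _, seq in entries]
    rows = []
    for i in range(len(entries)):
        gi, pi, si = entries[i]
        for j in range(i + 1, len(entries)):
            gj, pj, sj = entries[j]
            if gi == gj:
                continue
            if prefilter and len(kmers[i] & kmers[j]) < min_shared_kmers:
                continue
            res = local_align(si, sj)
            if res.score <= 0:
                continue
            rows.append((pi, gi, pj, gj, res.identity, res.query_coverage,
                         res.subject_coverage, res.score))
            rows.append((pj, gj, pi, gi, res.identity, res.subject_coverage,
                         res.query_coverage, res.score))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def compute_pocp(proteome_a: Proteome, proteome_b: Proteome,
                 hits: Optional[pd.DataFrame] = None,
                 min_identity: float = POCP_MIN_IDENTITY,
                 min_coverage: float = POCP_MIN_COVERAGE,
                 inclusive: bool = False) -> float:
    """Percentage of conserved proteins between two proteomes.

    C_i counts proteins of one proteome with at least one hit to the other at
    identity and query coverage strictly over the thresholds (set
    ``inclusive=True`` for the >= variant used by some POCP definitions).
    """
    if not len(proteome_a) or not len(proteome_b):
        raise ValueError("POCP is undefined for an empty proteome")
    if hits is None:
        hits = all_vs_all({"A": proteome_a, "B": proteome_b})
    ids_a = {pid for pid, _ in proteome_a}
    ids_b = {pid for pid, _ in proteome_b}
    if inclusive:
        good = hits[(hits.identity >= min_identity) & (hits.query_coverage >= min_coverage)]
    else:
        good = hits[(hits.identity > min_identity) & (hits.query_coverage > min_coverage)]
    conserved = set(good.query_id)
    c1 = len(conserved & ids_a)
    c2 = len(conserved & ids_b)
    return 100.0 * (c1 + c2) / (len(proteome_a) + len(proteome_b))


def _reciprocal_best(hits: pd.DataFrame) -> pd.DataFrame:
    """Mutual best hits by score (ties broken by subject id), one row per pair."""
    best = (hits.sort_values(["query_id", "score", "subject_id"],
                             ascending=[True, False, True])
            .groupby("query_id", as_index=False).first())
    forward = {(r.query_id, r.subject_id) for r in best.itertuples()}
    keep = best[[(r.subject_id, r.query_id) in forward for r in best.itertuples()]]
    # one row per unordered pair
    keep = keep[keep.query_id < keep.subject_id]
    return keep


def compute_aai(proteome_a: Proteome, proteome_b: Proteome,
                hits: Optional[pd.DataFrame] = None,
                min_coverage: float = AAI_MIN_COVERAGE,
                min_identity: float = AAI_MIN_IDENTITY) -> Optional[float]:
    """Average amino-acid identity over reciprocal best hits.

    Hits must pass coverage >= 50 (on the query side of each direction) and
    identity >= 30 before the mutual-best search; returns None when no
    reciprocal pair survives (AAI undefined).
    """
    if hits is None:
        hits = all_vs_all({"A": proteome_a, "B": proteome_b})
    if hits.empty:
        return None
    good = hits[(hits.query_coverage >= min_coverage) & (hits.identity >= min_identity)]
    rbh = _reciprocal_best(good)
    if rbh.empty:
        return None
    return float(rbh.identity.mean())


def compute_gene_ani(genes_a: Proteome, genes_b: Proteome,
                     prefilter: bool = True, kmer_size: int = 12,
                     min_shared_kmers: int = 5) -> Optional[float]:
    """Gene-wise average nucleotide identity over reciprocal-best gene pairs.

    Every cross-set gene pair passing a shared-k-mer prefilter is globally
    aligned; reciprocal best pairs by score are averaged by identity. A
    gene-level stand-in for whole-genome fragment ANI, adequate for the
    dereplication and species-boundary reports.
    """
    rows = []
    kma = [kmer_set(s, kmer_size) for _, s in genes_a]
    kmb = [kmer_set(s, kmer_size) for _, s in genes_b]
    for i, (ida, sa) in enumerate(genes_a):
        for j, (idb, sb) in enumerate(genes_b):
            if prefilter and len(kma[i] & kmb[j]) < min_shared_kmers:
                continue
            res = global_align_nuc(sa, sb)
            rows.append((f"A:{ida}", "A", f"B:{idb}", "B", res.identity,
                         res.query_coverage, res.subject_coverage, res.score))
            rows.append((f"B:{idb}", "B", f"A:{ida}", "A", res.identity,
                         res.subject_coverage, res.query_coverage, res.score))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if hits.empty:
        return None
    rbh = _reciprocal_best(hits)
    if rbh.empty:
        return None
    return float(rbh.identity.mean())


def cluster_orthologues(hits: pd.DataFrame, protein_ids: Iterable[str],
                        min_identity: float = ORTHOLOGUE_MIN_IDENTITY,
                        min_coverage: float = ORTHOLOGUE_MIN_COVERAGE
                        ) -> List[List[str]]:
    """Single-linkage orthologue clusters.

    An undirected edge joins two proteins when any hit between them reaches at
    least 50% identity and 50% query coverage; clusters are the connected
    components, and proteins without qualifying hits become singletons.
    """
    uf = UnionFind(protein_ids)
    if not hits.empty:
        good = hits[(hits.identity >= min_identity) & (hits.query_coverage >= min_coverage)]
        for r in good.itertuples():
            uf.union(r.query_id, r.subject_id)
    return uf.components()


def pangenome_matrix(clusters: List[List[str]],
                     protein_genome: Dict[str, str]) -> pd.DataFrame:
    """Cluster x genome copy-count matrix (clusters indexed by first member)."""
    genomes = sorted(set(protein_genome.values()))
    data = []
    index = []
    for members in clusters:
        counts = {g: 0 for g in genomes}
        for pid in members:
            counts[protein_genome[pid]] += 1
        index.append(members[0])
        data.append(counts)
    return pd.DataFrame(data, index=index, columns=genomes)


def core_pan_curves(matrix: pd.DataFrame, n_permutations: int = 100,
                    seed: int = 0) -> pd.DataFrame:
    """Core- and pan-genome sizes versus number of genomes sampled.

    For each k over seeded permutations of genome order: pan = clusters present
    in >= 1 of the first k genomes, core = clusters present in all of them.
    """
    if matrix.shape[1] < 2:
        raise ValueError("core/pan curves need >= 2 genomes")
    rng = np.random.default_rng(seed)
    present = (matrix.values > 0)
    n_genomes = present.shape[1]
    pans = np.zeros((n_permutations, n_genomes), dtype=int)
    cores = np.zeros((n_permutations, n_genomes), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(n_genomes)
        cum_any = np.logical_or.accumulate(present[:, order], axis=1)
        cum_all = np.logical_and.accumulate(present[:, order], axis=1)
        pans[p] = cum_any.sum(axis=0)
        cores[p] = cum_all.sum(axis=0)
    return pd.DataFrame({
        "k": np.arange(1, n_genomes + 1),
        "pan_mean": pans.mean(axis=0), "pan_sd": pans.std(axis=0),
        "core_mean": cores.mean(axis=0), "core_sd": cores.std(axis=0),
    })


def dereplicate(stats: pd.DataFrame, ani: pd.DataFrame,
                threshold: float = DEREP_ANI) -> List[str]:
    """Pick one representative per single-linkage ANI cluster (> 99, strict).

    ``stats`` columns: genome_id, completeness, contamination, length.
    Representative = highest completeness - 5 x contamination score; ties go to
    the longest assembly, then lexicographic id.
    """
    ids = list(stats["genome_id"])
    uf = UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if float(ani.loc[a, b]) > threshold:
                uf.union(a, b)
    by_id = stats.set_index("genome_id")
    reps = []
    for cluster in uf.components():
        def keyfun(g):
            row = by_id.loc[g]
            return (-(row["completeness"] - 5.0 * row["contamination"]),
                    -row["length"], g)
        reps.append(min(cluster, key=keyfun))
    return sorted(reps)


def select_scgs(counts: pd.DataFrame) -> List[str]:
    """Marker families with copy count exactly 1 in every genome.

    ``counts``: marker-family (rows) x genome (columns) copy numbers. These are
    the single-copy genes common to every MAG, suitable for concatenated
    phylogenomics.
    """
    if counts.empty:
        raise ValueError("empty marker count matrix")
    mask = (counts == 1).all(axis=1)
    return sorted(counts.index[mask])
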
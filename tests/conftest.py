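"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from streamscan import binqc
from streamscan.align import _BLOSUM62X


def sw_oracle_score(query: str, subject: str, open_cost: float = 12.0,
                    ext_cost: float = 1.0) -> float:
    """Brute-force Gotoh affine-gap Smith-Waterman score.

    Independent of the production aligner: a plain three-matrix dynamic
    programme over BLOSUM62 (X scored 0), gap of length k costing
    open_cost + (k - 1) * ext_cost.
    """
    n, m = len(query), len(subject)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = _BLOSUM62X[query[i - 1], subject[j - 1]]
            M[i, j] = max(0.0, max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                                   Iy[i - 1, j - 1]) + sub)
            Ix[i, j] = max(M[i - 1, j] - open_cost, Ix[i - 1, j] - ext_cost)
            Iy[i, j] = max(M[i, j - 1] - open_cost, Iy[i, j - 1] - ext_cost)
            best = max(best, M[i, j])
    return best


def transitive_closure_clusters(edges, nodes):
    """Brute-force connected components by repeated set merging."""
    clusters = [{n} for n in nodes]
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            ca = next(c for c in clusters if a in c)
            cb = next(c for c in clusters if b in c)
            if ca is not cb:
                ca |= cb
                clusters.remove(cb)
                changed = True
    return sorted(sorted(c) for c in clusters)


def make_bin(contig_genes, completeness=95.0, contamination=1.0,
             contig_length=10_000, bin_id="bin01"):
    """Bin with hand-specified gene taxonomies.

    ``contig_genes``: dict contig_id -> list of (taxon or None, viral_flag).
    Gene coordinates are tiled; sequences are uniform A-runs (content-neutral).
    """
    contigs = [(cid, "A" * contig_length) for cid in contig_genes]
    rows = []
    k = 0
    for cid, genes in contig_genes.items():
        pos = 1
        for taxon, viral in genes:
            rows.append((f"g{k:04d}", cid, pos, pos + 89, "+", taxon, viral))
            pos += 100
            k += 1
    genes_df = pd.DataFrame(rows, columns=binqc.GENE_COLUMNS)
    return binqc.Bin(bin_id, contigs, genes_df, completeness, contamination)


@pytest.fixture
def hit():
    """Factory for gene-taxonomy hits with passing defaults."""
    def _make(taxon="taxA", e_value=1e-6, similarity=60.0, coverage=80.0,
              bitscore=200.0, subject_id=""):
        return binqc.GeneTaxonomyHit("g1", taxon, e_value, similarity,
                                     coverage, bitscore, subject_id or taxon)
    return _make
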
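"""Contig-level decontamination, viral filtering and streamlining statistics for MAGs.

Metagenome-assembled genomes (MAGs) routinely carry contigs that were mis-binned
from co-occurring taxa or from phages. This module implements a gene-taxonomy
voting scheme: every predicted gene carries the taxonomy of its best database hit,
each bin is assigned a dominant taxon by majority vote, and contigs whose genes
disagree with that vote (or that look predominantly viral) are discarded. It also
computes the genome-streamlining statistics (GC, coding density, estimated genome
size, N50) used to characterise small free-living freshwater genomes, the
completeness/contamination QC gate, and a whole-genome taxonomy-composition screen
for recent horizontal gene transfer.

Threshold semantics follow the strict inequalities of the source protocol:
a contig is a contaminant iff strictly fewer than 30% of its taxonomically
assigned genes match the bin's dominant taxon; a contig is viral iff strictly
more than 25% of its genes are viral; a bin passes QC iff completeness > 70
and contamination < 5; the HGT flag is raised iff the self-taxon fraction is
not strictly above 0.90.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

GENE_COLUMNS = ["gene_id", "contig_id", "start", "end", "strand", "taxon", "viral_flag"]

# strict thresholds, as worded in the protocol
CONTAMINANT_DOMINANT_FRACTION = 0.30   # removed iff fraction < this
VIRAL_GENE_FRACTION = 0.25             # removed iff fraction > this
QC_MIN_COMPLETENESS = 70.0             # pass iff completeness > this
QC_MAX_CONTAMINATION = 5.0             # pass iff contamination < this
HGT_SELF_FRACTION = 0.90               # flag iff self fraction <= this


@dataclass(frozen=True)
class GeneTaxonomyHit:
    """One gene-vs-database alignment used for taxonomy voting."""

    gene_id: str
    subject_taxon: str
    e_value: float
    similarity: float  # percent
    coverage: float    # percent of query
    bitscore: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value for {self.gene_id}: {self.e_value}")
        if not (0 <= self.similarity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("similarity and coverage must be percentages in [0, 100]")


@dataclass
class Bin:
    """A candidate MAG: contigs, per-gene calls, and quality metadata.

    ``genes`` is a DataFrame with columns ``gene_id, contig_id, start, end,
    strand, taxon, viral_flag`` (1-based inclusive coordinates; ``taxon`` may be
    None for unassigned genes).
    """

    bin_id: str
    contigs: list  # list of (contig_id, sequence)
    genes: pd.DataFrame
    completeness: float = 100.0
    contamination: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100 and 0 <= self.contamination <= 100):
            raise ValueError("completeness/contamination must be in [0, 100]")
        lengths = {cid: len(seq) for cid, seq in self.contigs}
        for row in self.genes.itertuples():
            if row.contig_id not in lengths:
                raise ValueError(f"gene {row.gene_id} references unknown contig {row.contig_id}")
            if not (1 <= row.start <= row.end <= lengths[row.contig_id]):
                raise ValueError(f"gene {row.gene_id} out of contig bounds")

    @property
    def contig_ids(self) -> list:
        return [cid for cid, _ in self.contigs]

    def subset(self, keep_contigs: Iterable[str]) -> "Bin":
        keep = set(keep_contigs)
        return Bin(
            bin_id=self.bin_id,
            contigs=[(cid, seq) for cid, seq in self.contigs if cid in keep],
            genes=self.genes[self.genes["contig_id"].isin(keep)].reset_index(drop=True),
            completeness=self.completeness,
            contamination=self.contamination,
        )


@dataclass
class ContigFilterResult:
    kept: list
    removed: list
    reasons: dict = field(default_factory=dict)  # contig_id -> reason string

    def __iter__(self):
        return iter((self.kept, self.removed))


@dataclass
class BinQCReport:
    bin_id: str
    dominant_taxon: Optional[str]
    dominant_tie: bool
    kept_contigs: list
    removed_contigs: list
    removal_reasons: dict
    gc: float
    coding_density: float
    assembly_length: int
    estimated_genome_size: float
    n50: int
    qc_pass: bool
    taxon_composition: dict
    self_fraction: Optional[float] = None
    hgt_flag: Optional[bool] = None


def assign_gene_taxonomy(hits: Sequence[GeneTaxonomyHit]) -> Optional[str]:
    """Pick the taxon of the best hit passing all acceptance thresholds.

    A hit survives iff e-value < 1e-3, similarity > 10, coverage > 10 and
    bitscore > 50 (all strict). Among survivors the best hit wins: highest
    bitscore, ties broken by lowest e-value, then lexicographic subject id.
    Returns None when no hit survives.
    """
    survivors = [
        h for h in hits
        if h.e_value < 1e-3 and h.similarity > 10 and h.coverage > 10 and h.bitscore > 50
    ]
    if not survivors:
        return None
    best = min(survivors, key=lambda h: (-h.bitscore, h.e_value, h.subject_id or h.subject_taxon))
    return best.subject_taxon


def _assigned_genes(bin_: Bin) -> pd.DataFrame:
    return bin_.genes[bin_.genes["taxon"].notna()]


def dominant_taxonomy(bin_: Bin) -> tuple:
    """Modal assigned taxon over all genes in the bin.

    Returns ``(taxon, tied)`` where ``tied`` indicates a tie at the top that was
    broken lexicographically (reported in :class:`BinQCReport`).
    """
    assigned = _assigned_genes(bin_)
    if assigned.empty:
        raise ValueError(f"no taxonomic evidence in bin {bin_.bin_id}")
    counts = Counter(assigned["taxon"])
    top = max(counts.values())
    leaders = sorted(t for t, c in counts.items() if c == top)
    return leaders[0], len(leaders) > 1


def filter_contaminant_contigs(bin_: Bin, dominant: Optional[str] = None) -> ContigFilterResult:
    """Remove contigs with < 30% of assigned genes matching the dominant taxon.

    The denominator is the count of genes on the contig that carry any taxon
    assignment; contigs without assigned genes are kept and flagged.
    """
    if dominant is None:
        dominant, _ = dominant_taxonomy(bin_)
    kept, removed, reasons = [], [], {}
    assigned = _assigned_genes(bin_)
    per_contig_total = assigned.groupby("contig_id").size()
    per_contig_dom = assigned[assigned["taxon"] == dominant].groupby("contig_id").size()
    for cid in bin_.contig_ids:
        total = int(per_contig_total.get(cid, 0))
        if total == 0:
            kept.append(cid)
            reasons[cid] = "kept: no taxonomic evidence"
            continue
        frac = int(per_contig_dom.get(cid, 0)) / total
        if frac < CONTAMINANT_DOMINANT_FRACTION:
            removed.append(cid)
            reasons[cid] = f"removed: {frac:.3f} of assigned genes match dominant taxon"
        else:
            kept.append(cid)
    return ContigFilterResult(kept, removed, reasons)


def filter_viral_contigs(bin_: Bin) -> ContigFilterResult:
    """Remove contigs where > 25% of genes carry a viral flag."""
    kept, removed, reasons = [], [], {}
    genes = bin_.genes
    per_contig_total = genes.groupby("contig_id").size()
    per_contig_viral = genes[genes["viral_flag"].astype(bool)].groupby("contig_id").size()
    for cid in bin_.contig_ids:
        total = int(per_contig_total.get(cid, 0))
        if total == 0:
            kept.append(cid)
            reasons[cid] = "kept: no genes"
            continue
        frac = int(per_contig_viral.get(cid, 0)) / total
        if frac > VIRAL_GENE_FRACTION:
            removed.append(cid)
            reasons[cid] = f"removed: {frac:.3f} viral genes"
        else:
            kept.append(cid)
    return ContigFilterResult(kept, removed, reasons)


def _merged_interval_length(intervals: list) -> int:
    """Total length covered by a union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    covered = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end + 1:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start + 1
    return covered


def gc_content(sequences: Iterable[str]) -> float:
    """GC percent over unambiguous bases (A/C/G/T only) of all sequences."""
    gc = at = 0
    for seq in sequences:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    if gc + at == 0:
        return 0.0
    return 100.0 * gc / (gc + at)


def n50(lengths: Sequence[int]) -> int:
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc * 2 >= total:
            return length
    return 0


def genome_stats(bin_: Bin) -> dict:
    """Streamlining statistics: GC, coding density, sizes, N50.

    Coding density counts each base once even where gene intervals overlap.
    Estimated genome size applies the standard completeness correction
    ``assembly_length / (completeness / 100)``.
    """
    if bin_.completeness <= 0:
        raise ValueError("completeness must be > 0 to estimate genome size")
    assembly_length = sum(len(seq) for _, seq in bin_.contigs)
    coding = 0
    for cid, group in bin_.genes.groupby("contig_id"):
        coding += _merged_interval_length(list(zip(group["start"], group["end"])))
    return {
        "gc": gc_content(seq for _, seq in bin_.contigs),
        "coding_density": 100.0 * coding / assembly_length if assembly_length else 0.0,
        "assembly_length": assembly_length,
        "estimated_genome_size": assembly_length / (bin_.completeness / 100.0),
        "n50": n50([len(seq) for _, seq in bin_.contigs]),
    }


def qc_gate(completeness: float, contamination: float) -> bool:
    """MAG selection gate: completeness > 70 and contamination < 5 (strict)."""
    if not (0 <= completeness <= 100) or not (0 <= contamination <= 100):
        raise ValueError("completeness and contamination must be in [0, 100]")
    return completeness > QC_MIN_COMPLETENESS and contamination < QC_MAX_CONTAMINATION


def taxonomy_composition(bin_: Bin, self_taxon: str) -> tuple:
    """Per-taxon gene fractions plus an HGT flag.

    Fractions are over taxonomically assigned genes. The flag is raised when
    the self-taxon fraction fails the strict > 0.90 screen used to rule out
    recent horizontal gene transfer.
    """
    assigned = _assigned_genes(bin_)
    if assigned.empty:
        raise ValueError(f"no taxonomic evidence in bin {bin_.bin_id}")
    counts = assigned["taxon"].value_counts()
    total = int(counts.sum())
    fractions = {taxon: c / total for taxon, c in counts.items()}
    self_fraction = fractions.get(self_taxon, 0.0)
    return fractions, self_fraction, self_fraction <= HGT_SELF_FRACTION


def run_bin_qc(bin_: Bin, self_taxon: Optional[str] = None) -> BinQCReport:
    """Full per-bin QC: contaminant filter, then viral filter, then statistics.

    Statistics and composition are computed on the filtered bin. ``self_taxon``
    defaults to the dominant taxon.
    """
    dominant, tie = dominant_taxonomy(bin_)
    contam = filter_contaminant_contigs(bin_, dominant)
    after_contam = bin_.subset(contam.kept)
    viral = filter_viral_contigs(after_contam)
    clean = after_contam.subset(viral.kept)
    reasons = dict(contam.reasons)
    reasons.update({cid: r for cid, r in viral.reasons.items() if "removed" in r})
    stats = genome_stats(clean)
    self_taxon = self_taxon if self_taxon is not None else dominant
    fractions, self_fraction, hgt_flag = taxonomy_composition(clean, self_taxon)
    return BinQCReport(
        bin_id=bin_.bin_id,
        dominant_taxon=dominant,
        dominant_tie=tie,
        kept_contigs=viral.kept,
        removed_contigs=contam.removed + viral.removed,
        removal_reasons=reasons,
        gc=stats["gc"],
        coding_density=stats["coding_density"],
        assembly_length=stats["assembly_length"],
        estimated_genome_size=stats["estimated_genome_size"],
        n50=stats["n50"],
        qc_pass=qc_gate(bin_.completeness, bin_.contamination),
        taxon_composition=fractions,
        self_fraction=self_fraction,
        hgt_flag=hgt_flag,
    )
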
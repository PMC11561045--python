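"""Synthetic data with known ground truth for every pipeline stage.

Every generator in this module emulates one class of input the analysis
consumes — genome bins with planted foreign/viral contigs, metagenomic reads
sampled at known depth with an optional ori->ter replication gradient, families
of proteomes with planted core/accessory orthology at a controlled divergence,
7-transmembrane-helix rhodopsin-like proteins with planted retinal-binding and
proton-transfer motifs, and per-genome annotation hit tables with planted
pathway completeness — and returns, alongside the artifact, a truth table
against which the downstream module can be scored exactly.

All randomness flows from one ``numpy.random.default_rng(seed)`` per call, so
identical seeds yield byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import binqc

DNA = np.frombuffer(b"ACGT", dtype="S1")
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Hydrophobic alphabets for planted transmembrane helices. A (KD 1.8) is kept
# out of the sampled set so that every in-helix hydropathy window clears the
# scanner threshold even when polar motif residues (D/T/E/K/Q) are planted;
# the scanner itself still recognises A as hydrophobic.
HELIX_ALPHABET = "LIVFM"
MOTIF_HELIX_ALPHABET = "LIV"
# Strongly polar linker alphabet (KD <= -3.5). With linkers >= 7 aa this makes
# every scan window centred >= 7 residues from a helix centre fail the 1.6
# hydropathy threshold for any residue draw (max helix KD 4.5, max linker KD
# -3.5), so the planted helix count is a construction invariant, not a
# probabilistic outcome. D/S/K are excluded so no accidental DxxxK/SxxxK motif
# can arise in the +-5 flank scanned around helix 7.
LINKER_ALPHABET = "NQER"

DOMINANT_TAXON = "tax_dominant"
FOREIGN_TAXON = "tax_foreign"


# ---------------------------------------------------------------------------
# genomes and bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome.

    Defaults mirror a genome-streamlined freshwater MAG: ~1.2 Mb genomes are
    scaled to desk size, GC 46% and coding density 93% sit mid-range of the
    44.3-48.7% GC / 92.2-95.3% coding-density envelope such genomes occupy.
    """

    total_length: int
    n_contigs: int = 5
    gc: float = 0.46
    gene_density: float = 0.93
    mean_gene_length: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.total_length < self.n_contigs * 1000:
            raise ValueError("total_length must be >= n_contigs x 1 kb")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")
        if not (0 <= self.gene_density <= 1):
            raise ValueError("gene_density must be in [0, 1]")
        if self.mean_gene_length <= 0:
            raise ValueError("mean_gene_length must be positive")


@dataclass
class SyntheticGenome:
    genome_id: str
    contigs: List[Tuple[str, str]]
    genes: pd.DataFrame  # binqc.GENE_COLUMNS
    spec: SyntheticGenomeSpec

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    @property
    def sequence(self) -> str:
        """Contigs concatenated in order (replication coordinate system)."""
        return "".join(s for _, s in self.contigs)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(DNA, size=length, p=p).tobytes().decode()


def generate_genome(spec: SyntheticGenomeSpec, genome_id: str = "genome",
                    taxon: str = DOMINANT_TAXON) -> SyntheticGenome:
    """Generate contig sequences plus a non-overlapping gene coordinate table.

    Genes are tiled along each contig with exponential intergenic gaps sized so
    the realised coding fraction approximates ``spec.gene_density``; coordinates
    are 1-based inclusive and never overlap within a contig.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.total_length // spec.n_contigs
    lengths = [base] * spec.n_contigs
    lengths[0] += spec.total_length - base * spec.n_contigs
    contigs = [(f"{genome_id}_c{i:03d}", _random_dna(rng, lengths[i], spec.gc))
               for i in range(spec.n_contigs)]

    rows = []
    gene_no = 0
    if spec.gene_density > 0:
        gap_mean = spec.mean_gene_length * (1 - spec.gene_density) / spec.gene_density
        for cid, seq in contigs:
            cursor = int(rng.integers(0, max(1, int(gap_mean) + 1)))
            while True:
                glen = int(np.clip(rng.normal(spec.mean_gene_length,
                                              spec.mean_gene_length * 0.15), 60, None))
                if cursor + glen > len(seq):
                    break
                rows.append((f"{genome_id}_g{gene_no:05d}", cid, cursor + 1,
                             cursor + glen, "+" if rng.random() < 0.5 else "-",
                             taxon, False))
                gene_no += 1
                gap = int(rng.exponential(gap_mean)) if gap_mean > 0 else 0
                cursor += glen + gap
    genes = pd.DataFrame(rows, columns=binqc.GENE_COLUMNS)
    return SyntheticGenome(genome_id, contigs, genes, spec)


def as_bin(genome: SyntheticGenome, completeness: float = 95.0,
           contamination: float = 1.0) -> binqc.Bin:
    return binqc.Bin(bin_id=genome.genome_id, contigs=list(genome.contigs),
                     genes=genome.genes.copy(), completeness=completeness,
                     contamination=contamination)


def _relabel_fraction(genes: pd.DataFrame, contig_id: str, fraction: float,
                      rng: np.random.Generator, column: str, value) -> pd.DataFrame:
    idx = genes.index[genes["contig_id"] == contig_id]
    k = int(math.floor(fraction * len(idx) + 0.5))
    chosen = rng.choice(idx.to_numpy(), size=k, replace=False) if k else []
    genes.loc[chosen, column] = value
    return genes


def plant_foreign_content(bin_: binqc.Bin, n_foreign_contigs: int,
                          foreign_gene_fraction: float,
                          foreign_taxon: str = FOREIGN_TAXON,
                          seed: int = 0) -> Tuple[binqc.Bin, pd.DataFrame]:
    """Relabel genes on selected contigs to a foreign taxon.

    On each of ``n_foreign_contigs`` randomly chosen contigs, exactly
    ``round(fraction x n_genes)`` genes are reassigned to ``foreign_taxon``.
    Returns the contaminated bin plus a truth table (contig_id, is_contaminant).
    """
    if not (0 <= foreign_gene_fraction <= 1):
        raise ValueError("foreign_gene_fraction must be in [0, 1]")
    if len(bin_.contigs) < n_foreign_contigs + 1:
        raise ValueError("bin must have at least n_foreign_contigs + 1 contigs")
    rng = np.random.default_rng(seed)
    genes = bin_.genes.copy()
    cids = bin_.contig_ids
    chosen = sorted(rng.choice(len(cids), size=n_foreign_contigs, replace=False).tolist())
    foreign = {cids[i] for i in chosen}
    for cid in sorted(foreign):
        genes = _relabel_fraction(genes, cid, foreign_gene_fraction, rng,
                                  "taxon", foreign_taxon)
    truth = pd.DataFrame({"contig_id": cids,
                          "is_contaminant": [c in foreign for c in cids]})
    out = binqc.Bin(bin_.bin_id, list(bin_.contigs), genes,
                    bin_.completeness, bin_.contamination)
    return out, truth


def plant_viral_content(bin_: binqc.Bin, n_viral_contigs: int,
                        viral_gene_fraction: float,
                        seed: int = 0) -> Tuple[binqc.Bin, pd.DataFrame]:
    """Flag a fraction of genes as viral on randomly chosen contigs."""
    if not (0 <= viral_gene_fraction <= 1):
        raise ValueError("viral_gene_fraction must be in [0, 1]")
    if len(bin_.contigs) < n_viral_contigs + 1:
        raise ValueError("bin must have at least n_viral_contigs + 1 contigs")
    rng = np.random.default_rng(seed)
    genes = bin_.genes.copy()
    cids = bin_.contig_ids
    chosen = sorted(rng.choice(len(cids), size=n_viral_contigs, replace=False).tolist())
    viral = {cids[i] for i in chosen}
    for cid in sorted(viral):
        genes = _relabel_fraction(genes, cid, viral_gene_fraction, rng,
                                  "viral_flag", True)
    truth = pd.DataFrame({"contig_id": cids,
                          "is_viral": [c in viral for c in cids]})
    out = binqc.Bin(bin_.bin_id, list(bin_.contigs), genes,
                    bin_.completeness, bin_.contamination)
    return out, truth


# ---------------------------------------------------------------------------
# metagenomic reads
# ---------------------------------------------------------------------------

def _position_weights(genome_length: int, n_positions: int, ori_ter_ratio: float) -> np.ndarray:
    """Linear ori->ter sampling density over read start positions.

    The origin sits at coordinate 0, the terminus at genome_length / 2; density
    declines linearly from ``ratio`` at the origin to 1 at the terminus and
    rises back symmetrically (a linear peak-to-trough replication profile).
    """
    x = np.arange(n_positions, dtype=float)
    t = np.minimum(x, genome_length - x) / (genome_length / 2.0)  # 0 at ori, 1 at ter
    w = ori_ter_ratio - (ori_ter_ratio - 1.0) * t
    return w / w.sum()


def simulate_read_positions(genome_length: int, depth: float, read_length: int,
                            ori_ter_ratio: float = 1.0,
                            seed: int = 0) -> np.ndarray:
    """Sample 0-based read start positions; Poisson read count at the target depth."""
    if read_length >= genome_length:
        raise ValueError("read_length must be < genome length")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if ori_ter_ratio < 1:
        raise ValueError("ori_ter_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    n_reads = int(rng.poisson(depth * genome_length / read_length))
    n_positions = genome_length - read_length + 1
    if ori_ter_ratio == 1.0:
        return rng.integers(0, n_positions, size=n_reads)
    p = _position_weights(genome_length, n_positions, ori_ter_ratio)
    return rng.choice(n_positions, size=n_reads, p=p)


def simulate_reads(sequence: str, depth: float, read_length: int,
                   subst_rate: float = 0.0, ori_ter_ratio: float = 1.0,
                   seed: int = 0) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Sample reads uniformly (or with a linear ori->ter gradient) with replacement.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)`` and the
    truth table records the 1-based origin interval of every read. Substitutions
    are i.i.d. draws to one of the three alternative bases; no quality model.
    """
    if not (0 <= subst_rate < 1):
        raise ValueError("subst_rate must be in [0, 1)")
    starts = simulate_read_positions(len(sequence), depth, read_length,
                                     ori_ter_ratio, seed)
    rng = np.random.default_rng(seed + 1)
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    reads, rows = [], []
    for i, s in enumerate(starts):
        chunk = arr[s:s + read_length].copy()
        if subst_rate > 0:
            n_sub = rng.binomial(read_length, subst_rate)
            if n_sub:
                pos = rng.choice(read_length, size=n_sub, replace=False)
                for p in pos:
                    alts = [b for b in b"ACGT" if bytes([b]) != chunk[p]]
                    chunk[p] = alts[rng.integers(0, 3)]
        rid = f"read_{i:07d}"
        reads.append((rid, chunk.tobytes().decode()))
        rows.append((rid, int(s) + 1, int(s) + read_length))
    truth = pd.DataFrame(rows, columns=["read_id", "start", "end"])
    return reads, truth


# ---------------------------------------------------------------------------
# proteome families
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))

def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        alternatives = AA20.replace(out[i], "")
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def generate_proteome_family(n_genomes: int, core_size: int, accessory_size: int,
                             mean_identity: float, seed: int = 0,
                             protein_length: int = 150
                             ) -> Tuple[Dict[str, List[Tuple[str, str]]], pd.DataFrame]:
    """Proteomes with planted core/accessory orthologue families.

    Each family descends from a random ancestor; members are mutated i.i.d.
    at per-site rate ``1 - sqrt(mean_identity)`` so that the expected pairwise
    identity between any two members is ``mean_identity`` (no indels). Core
    families appear in every genome; each accessory family in a random proper
    non-empty subset. Truth maps every protein to its family.
    """
    if not (0 < mean_identity <= 1):
        raise ValueError("mean_identity must be in (0, 1]")
    if core_size + accessory_size == 0:
        raise ValueError("core_size + accessory_size must be positive")
    if accessory_size > 0 and n_genomes < 2:
        raise ValueError("accessory families need >= 2 genomes")
    rng = np.random.default_rng(seed)
    rate = 1.0 - math.sqrt(mean_identity)
    genome_ids = [f"G{i:02d}" for i in range(n_genomes)]
    proteomes: Dict[str, List[Tuple[str, str]]] = {g: [] for g in genome_ids}
    rows = []
    for fam in range(core_size + accessory_size):
        fam_id = f"fam{fam:04d}"
        is_core = fam < core_size
        ancestor = _random_protein(rng, protein_length)
        if is_core:
            members = genome_ids
        else:
            k = int(rng.integers(1, n_genomes))  # proper non-empty subset
            members = sorted(rng.choice(genome_ids, size=k, replace=False).tolist())
        for gid in members:
            pid = f"{gid}|{fam_id}"
            proteomes[gid].append((pid, _mutate_protein(ancestor, rate, rng)))
        rows.extend((gid, f"{gid}|{fam_id}", fam_id, is_core) for gid in members)
    truth = pd.DataFrame(rows, columns=["genome_id", "protein_id", "family_id", "is_core"])
    return proteomes, truth


# ---------------------------------------------------------------------------
# rhodopsin-like transmembrane proteins
# ---------------------------------------------------------------------------

HELIX_LENGTH = 19
MIN_LINKER = 7

# planted offsets within the helix-C (3rd) and helix-7 (last) 19-aa helices
HELIXC_D_OFFSET = 5
HELIXC_T_OFFSET = 9
HELIXC_TUNING_OFFSET = 12
HELIXC_E_OFFSET = 16
HELIX7_MOTIF_START = 14  # D/S at this offset, K at +4


@dataclass
class TMProteinTruth:
    rh_class: Optional[str]
    helices: List[Tuple[int, int]]  # 1-based inclusive
    helix7_motif: Optional[str] = None
    helixC_triplet: Optional[str] = None
    tuning_residue: Optional[str] = None
    retinal_lysine_pos: Optional[int] = None  # 1-based


def _layout(n_helices: int, length: int) -> Tuple[int, List[int], List[int], int]:
    """(leader, helix starts (0-based), linker lengths, tail) for the construct."""
    minimum = n_helices * HELIX_LENGTH + (n_helices - 1) * MIN_LINKER + 1
    if length < minimum:
        raise ValueError(
            f"length {length} too short to fit {n_helices} helices (need >= {minimum})")
    extra = length - minimum
    per = extra // (n_helices + 1)
    linkers = [MIN_LINKER + per] * (n_helices - 1)
    leader = 1 + per
    tail = extra - per * n_helices  # remainder
    starts = []
    cursor = leader
    for i in range(n_helices):
        starts.append(cursor)
        cursor += HELIX_LENGTH + (linkers[i] if i < n_helices - 1 else 0)
    return leader, starts, linkers, tail


def generate_tm_protein(n_helices: int, length: int, seed: int = 0,
                        plants: Optional[Dict[int, Dict[int, str]]] = None,
                        motif_helices: Sequence[int] = ()
                        ) -> Tuple[str, List[Tuple[int, int]]]:
    """A polytopic membrane protein: ``n_helices`` hydrophobic stretches.

    ``plants`` maps helix index -> {offset within helix: residue}. Helices in
    ``motif_helices`` are drawn from the strongly hydrophobic {L,I,V} alphabet
    so planted polar residues cannot sink a hydropathy window below threshold.
    Returns the sequence and the 1-based helix intervals.
    """
    rng = np.random.default_rng(seed)
    plants = plants or {}
    leader, starts, linkers, tail = _layout(n_helices, length)
    seq = list(rng.choice(list(LINKER_ALPHABET), size=length))
    helices = []
    for i, s in enumerate(starts):
        alphabet = MOTIF_HELIX_ALPHABET if i in motif_helices else HELIX_ALPHABET
        helix = list(rng.choice(list(alphabet), size=HELIX_LENGTH))
        for off, res in plants.get(i, {}).items():
            helix[off] = res
        seq[s:s + HELIX_LENGTH] = helix
        helices.append((s + 1, s + HELIX_LENGTH))
    return "".join(seq), helices


RHODOPSIN_CLASSES = ("type1_DTE", "heliorhodopsin", "non_canonical")


def generate_rhodopsin(rh_class: str, length: int = 220, seed: int = 0,
                       helixC_triplet: Optional[str] = None,
                       tuning_residue: Optional[str] = None
                       ) -> Tuple[str, TMProteinTruth]:
    """A 7-TM rhodopsin-like sequence with planted class-defining motifs.

    ``type1_DTE`` plants D-x-x-x-K at the end of helix 7, a D/T/E proton-transfer
    triplet in helix C (3rd helix) and an L at the spectral-tuning offset;
    ``heliorhodopsin`` plants S-x-x-x-K in helix 7; ``non_canonical`` plants
    neither. ``helixC_triplet``/``tuning_residue`` override the planted helix-C
    residues (e.g. "DTD", "Q") for variant fixtures.
    """
    if rh_class not in RHODOPSIN_CLASSES:
        raise ValueError(f"unknown rhodopsin class {rh_class!r}")
    n = 7
    plants: Dict[int, Dict[int, str]] = {}
    motif_helices: List[int] = []
    truth = TMProteinTruth(rh_class=rh_class, helices=[])

    if rh_class in ("type1_DTE", "heliorhodopsin"):
        first = "D" if rh_class == "type1_DTE" else "S"
        plants[n - 1] = {HELIX7_MOTIF_START: first, HELIX7_MOTIF_START + 4: "K"}
        motif_helices.append(n - 1)
        truth.helix7_motif = "DxxxK" if first == "D" else "SxxxK"

    if rh_class == "type1_DTE" or helixC_triplet is not None or tuning_residue is not None:
        triplet = helixC_triplet if helixC_triplet is not None else "DTE"
        tuning = tuning_residue if tuning_residue is not None else "L"
        plants.setdefault(2, {})
        plants[2].update({HELIXC_D_OFFSET: triplet[0], HELIXC_T_OFFSET: triplet[1],
                          HELIXC_TUNING_OFFSET: tuning, HELIXC_E_OFFSET: triplet[2]})
        motif_helices.append(2)
        truth.helixC_triplet = triplet
        truth.tuning_residue = tuning

    seq, helices = generate_tm_protein(n, length, seed, plants, motif_helices)
    truth.helices = helices
    if truth.helix7_motif is not None:
        truth.retinal_lysine_pos = helices[-1][0] + HELIX7_MOTIF_START + 4
    return seq, truth


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def generate_annotation_table(genome_ids: Sequence[str], pathway_defs: dict,
                              completeness_plan: Dict[str, Dict[str, float]],
                              seed: int = 0) -> pd.DataFrame:
    """Annotation hits realising a planted per-genome pathway-completeness plan.

    For each (genome, pathway) with planned fraction f, exactly
    ``round(f x n_steps)`` randomly chosen steps receive one accepted-quality
    hit (e-value 1e-10, model coverage 90%); all other steps receive none.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gene_no = 0
    for gid in genome_ids:
        plan = completeness_plan.get(gid, {})
        for pwy_id in sorted(plan):
            if pwy_id not in pathway_defs:
                raise KeyError(f"unknown pathway id {pwy_id!r}")
            frac = plan[pwy_id]
            if not (0 <= frac <= 1):
                raise ValueError(f"plan fraction {frac} outside [0, 1]")
            steps = pathway_defs[pwy_id].steps
            k = int(math.floor(frac * len(steps) + 0.5))
            chosen = sorted(rng.choice(len(steps), size=k, replace=False).tolist())
            for si in chosen:
                model = sorted(steps[si])[0]
                rows.append((gid, f"{gid}_g{gene_no:05d}", model, 1e-10, 90.0))
                gene_no += 1
    return pd.DataFrame(rows, columns=["genome_id", "gene_id", "model_id",
                                       "e_value", "model_coverage"])
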
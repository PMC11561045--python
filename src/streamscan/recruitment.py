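"""Fragment recruitment: alignment filtering, coverage-per-Gb, replication index.

Read-vs-genome alignment records (BLAST outfmt6-like TSV or produced in-memory)
are filtered at the recruitment thresholds — minimum alignment identity 95%,
minimum read coverage 90%, minimum alignment length 50% of the read (inclusive,
as "minimum" implies) — keeping one best hit per read. Kept hits are summed into
aligned-base genome coverage and normalised by metagenome size to coverage per
gigabase, a cross-sample abundance measure; metagenomes whose mean coverage per
Gb is not strictly above 0.1 are excluded. rRNA loci can be masked beforehand to
avoid conserved-region recruitment bias.

A replication index (ori:ter peak-to-trough coverage ratio, >1 during active
replication) is estimated from a windowed coverage profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MIN_IDENTITY = 95.0       # percent, inclusive
MIN_READ_COVERAGE = 0.90  # fraction of read aligned, inclusive
MIN_ALN_FRACTION = 0.50   # fraction of read, inclusive (subsumed; kept for audit)
INCLUSION_MEAN_COV_PER_GB = 0.1  # strictly greater-than gate


class InsufficientCoverageError(ValueError):
    pass


@dataclass(frozen=True)
class ReadAlignment:
    """One read-vs-genome alignment record."""

    read_id: str
    read_length: int
    genome_id: str
    target_start: int  # 1-based inclusive
    target_end: int
    aligned_length: int
    identity: float  # percent
    metagenome_id: str

    def __post_init__(self) -> None:
        if not (1 <= self.target_start <= self.target_end):
            raise ValueError("invalid target interval")
        if self.aligned_length > self.read_length:
            raise ValueError("aligned_length exceeds read_length")
        if not (0 <= self.identity <= 100):
            raise ValueError("identity must be a percentage")


def merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of 1-based inclusive intervals, sorted and merged."""
    if not intervals:
        return []
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def mask_intervals(sequence: str, intervals: Sequence[Tuple[int, int]]) -> str:
    """Replace the given 1-based inclusive ranges with N; length is preserved."""
    for s, e in intervals:
        if not (1 <= s <= e <= len(sequence)):
            raise ValueError(f"interval ({s}, {e}) out of bounds for length {len(sequence)}")
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    for s, e in merge_intervals(intervals):
        arr[s - 1:e] = b"N"
    return arr.tobytes().decode()


def filter_read_hits(hits: Iterable[ReadAlignment],
                     min_identity: float = MIN_IDENTITY,
                     min_read_coverage: float = MIN_READ_COVERAGE,
                     min_aln_fraction: float = MIN_ALN_FRACTION) -> List[ReadAlignment]:
    """Apply the recruitment thresholds and keep one best hit per read.

    Best = highest identity, ties broken by longest alignment, then by
    lexicographic genome id.
    """
    best: Dict[str, ReadAlignment] = {}
    for h in hits:
        frac = h.aligned_length / h.read_length
        if h.identity < min_identity or frac < min_read_coverage or frac < min_aln_fraction:
            continue
        cur = best.get(h.read_id)
        if cur is None or (-h.identity, -h.aligned_length, h.genome_id) < (
                -cur.identity, -cur.aligned_length, cur.genome_id):
            best[h.read_id] = h
    return [best[k] for k in sorted(best)]


def coverage_per_gb(kept_hits: Iterable[ReadAlignment], genome_length: int,
                    metagenome_total_bases: int, mode: str = "bases") -> float:
    """Normalised abundance of one genome in one metagenome.

    ``mode="bases"`` (default): coverage = sum of aligned bases / genome length.
    ``mode="counts"``: hit count x read length stands in for aligned bases.
    The coverage is divided by the metagenome size in Gb.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if metagenome_total_bases <= 0:
        raise ValueError("metagenome_total_bases must be positive")
    if mode == "bases":
        total = sum(h.aligned_length for h in kept_hits)
    elif mode == "counts":
        total = sum(h.read_length for h in kept_hits)
    else:
        raise ValueError("mode must be 'bases' or 'counts'")
    coverage = total / genome_length
    return coverage / (metagenome_total_bases / 1e9)


def recruitment_table(kept_hits: Iterable[ReadAlignment],
                      genome_lengths: Dict[str, int],
                      metagenome_sizes: Dict[str, int],
                      mode: str = "bases") -> pd.DataFrame:
    """Genome x metagenome coverage-per-Gb matrix from filtered hits."""
    groups: Dict[Tuple[str, str], list] = {}
    for h in kept_hits:
        groups.setdefault((h.genome_id, h.metagenome_id), []).append(h)
    table = pd.DataFrame(0.0, index=sorted(genome_lengths),
                         columns=sorted(metagenome_sizes))
    for (gid, mid), hs in groups.items():
        table.loc[gid, mid] = coverage_per_gb(hs, genome_lengths[gid],
                                              metagenome_sizes[mid], mode)
    return table


def inclusion_filter(table: pd.DataFrame,
                     min_mean: float = INCLUSION_MEAN_COV_PER_GB) -> List[str]:
    """Metagenomes whose mean coverage per Gb across genomes is strictly > 0.1."""
    if table.empty:
        raise ValueError("recruitment table is empty")
    means = table.mean(axis=0)
    return sorted(c for c in table.columns if means[c] > min_mean)


def default_window(genome_length: int) -> int:
    return max(1000, genome_length // 100)


def coverage_profile(starts: Sequence[int], read_length: int, genome_length: int,
                     window_size: Optional[int] = None) -> np.ndarray:
    """Per-window mean depth from 0-based read start positions.

    Windows tile the genome (last window may be short); depth in a window is
    aligned bases falling in the window divided by window width.
    """
    window_size = window_size or default_window(genome_length)
    edges = np.arange(0, genome_length + window_size, window_size)
    edges[-1] = min(edges[-1], genome_length)
    if edges[-1] != genome_length:
        edges = np.append(edges, genome_length)
    base_cov = np.zeros(genome_length + 1)
    starts = np.asarray(starts, dtype=int)
    np.add.at(base_cov, starts, 1)
    np.add.at(base_cov, np.minimum(starts + read_length, genome_length), -1)
    depth = np.cumsum(base_cov[:-1])
    widths = np.diff(edges)
    sums = np.add.reduceat(depth, edges[:-1])
    return sums / widths


def profile_from_alignments(hits: Iterable[ReadAlignment], genome_length: int,
                            window_size: Optional[int] = None) -> np.ndarray:
    starts = [h.target_start - 1 for h in hits]
    lengths = {h.aligned_length for h in hits}
    rl = max(lengths) if lengths else 0
    return coverage_profile(starts, rl, genome_length, window_size)


def replication_index(window_depths: Sequence[float], method: str = "fit",
                      outlier_fold: float = 8.0, min_windows: int = 20) -> float:
    """Peak-to-trough coverage ratio from a windowed depth profile (>= 1).

    Windows deviating more than ``outlier_fold`` x median are discarded to
    suppress mobile-element spikes. ``method="fit"`` (default) least-squares
    fits depth against folded circular distance from a searched origin window
    and reports fitted(ori)/fitted(ter); ``method="decile"`` reports the mean
    of the top depth decile over the mean of the bottom decile. Estimates below
    1 are floored at 1.0 (no sub-replication signal).
    """
    depths = np.asarray(window_depths, dtype=float)
    med = np.median(depths)
    if len(depths) < min_windows or med <= 0:
        raise InsufficientCoverageError(
            f"insufficient coverage: {len(depths)} windows, median depth {med}")
    keep = depths <= outlier_fold * med
    kept_idx = np.flatnonzero(keep)
    y = depths[keep]
    n_total = len(depths)
    if len(y) < min_windows:
        raise InsufficientCoverageError("insufficient coverage after outlier removal")

    if method == "decile":
        k = max(1, len(y) // 10)
        s = np.sort(y)
        ratio = s[-k:].mean() / max(s[:k].mean(), 1e-12)
    elif method == "fit":
        ratio = _fit_ori_ter_ratio(kept_idx, y, n_total)
    else:
        raise ValueError("method must be 'fit' or 'decile'")
    return max(1.0, float(ratio))


def _fit_ori_ter_ratio(idx: np.ndarray, y: np.ndarray, n_windows: int) -> float:
    """Search the origin window; fit depth ~ folded circular distance from it.

    For each candidate origin the folded distance d in [0, 1] (0 at the origin,
    1 at the opposite window) is regressed against depth; the candidate with the
    lowest residual sum of squares wins and the ratio is fitted(0)/fitted(1).
    """
    best = None
    half = n_windows / 2.0
    for ori in range(n_windows):
        raw = np.abs(idx - ori)
        d = np.minimum(raw, n_windows - raw) / half
        A = np.vstack([d, np.ones_like(d)]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = res[0] if len(res) else float(((A @ coef - y) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, coef)
    slope, intercept = best[1]
    ends = (intercept, intercept + slope)  # fitted depth at the search anchor / opposite
    # the anchor minimising SSE may sit at either the origin or the terminus
    # (the folded-distance model is symmetric); report peak over trough
    peak, trough = max(ends), min(ends)
    if trough <= 0:
        return 1.0
    return peak / trough


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = ["read_id", "genome_id", "identity", "aligned_length",
                   "read_length", "target_start", "target_end", "metagenome_id"]


def read_alignments_tsv(path) -> List[ReadAlignment]:
    """Load BLAST outfmt6-like records (qseqid sseqid pident length qlen sstart
    send metagenome_id)."""
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return [ReadAlignment(r.read_id, int(r.read_length), r.genome_id,
                          int(r.target_start), int(r.target_end),
                          int(r.aligned_length), float(r.identity),
                          str(r.metagenome_id))
            for r in df.itertuples()]


def write_alignments_tsv(hits: Iterable[ReadAlignment], path) -> None:
    rows = [(h.read_id, h.genome_id, h.identity, h.aligned_length, h.read_length,
             h.target_start, h.target_end, h.metagenome_id) for h in hits]
    pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(path, sep="\t",
                                                       header=False, index=False)


def alignments_from_truth(truth: pd.DataFrame, read_length: int, genome_id: str,
                          metagenome_id: str, identity: float = 100.0
                          ) -> List[ReadAlignment]:
    """Perfect full-length alignments from a read-simulation truth table.

    Stands in for a mapping engine when recruiting error-free synthetic reads:
    each read aligns exactly at its known origin.
    """
    return [ReadAlignment(r.read_id, read_length, genome_id, int(r.start),
                          int(r.end), read_length, identity, metagenome_id)
            for r in truth.itertuples()]
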
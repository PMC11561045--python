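"""Rhodopsin candidate screening and classification.

Candidate proteins (e.g. HMM hits against bacterial-rhodopsin or heliorhodopsin
models) are screened on length and significance, their transmembrane topology is
predicted with a Kyte-Doolittle hydropathy scanner, and canonical 7-helix
candidates are typed by the retinal-binding motif in helix 7: D-x-x-x-K marks a
Type I (proton-pumping) rhodopsin, S-x-x-x-K a heliorhodopsin. For Type I calls
the helix-C proton-transfer triplet (DTE = proton-pumping proteorhodopsin
configuration) and the spectral-tuning residue (L = green-absorbing,
Q = blue-absorbing) are read off at positions mapped through a global alignment
to a packaged reference segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

SCREEN_MIN_LENGTH = 150   # kept iff length >= 150
SCREEN_MAX_PVALUE = 1e-2  # discarded iff p strictly > 1e-2

# Kyte-Doolittle hydropathy
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}

TM_WINDOW = 19
TM_THRESHOLD = 1.6
TM_MERGE_GAP = 5
TM_MIN_HELIX = 15
TM_MAX_HELIX = 25
MOTIF_FLANK = 5  # residues scanned either side of predicted helix 7


@dataclass(frozen=True)
class RhodopsinCandidate:
    protein_id: str
    sequence: str
    screen_p_value: Optional[float] = None


@dataclass(frozen=True)
class TMTopology:
    helices: Tuple[Tuple[int, int], ...]  # 1-based inclusive, sorted, disjoint

    @property
    def n_helices(self) -> int:
        return len(self.helices)


@dataclass
class RhodopsinCall:
    protein_id: str
    rh_class: str  # type1 | heliorhodopsin | non_canonical
    n_helices: int
    helix7_motif: str = ""
    retinal_lysine: bool = False
    helixC_triplet: str = "unknown"
    tuning_residue: str = ""
    tuning_color: str = "unknown"


def screen_candidates(candidates: Sequence[RhodopsinCandidate]
                      ) -> List[RhodopsinCandidate]:
    """Keep candidates >= 150 aa whose screen p-value, if any, is <= 1e-2.

    A missing p-value passes (candidates may enter without an external HMM
    score). Pure filter: output is a subset of the input and the operation is
    idempotent.
    """
    return [c for c in candidates
            if len(c.sequence) >= SCREEN_MIN_LENGTH
            and (c.screen_p_value is None or c.screen_p_value <= SCREEN_MAX_PVALUE)]


def hydropathy_profile(sequence: str, window: int = TM_WINDOW) -> np.ndarray:
    """Mean Kyte-Doolittle hydropathy per window; entry i is the window
    centred at residue i + window // 2 (0-based)."""
    if len(sequence) < window:
        raise ValueError(f"sequence shorter than hydropathy window ({window})")
    vals = np.array([KD.get(c, 0.0) for c in sequence])
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


def predict_tm(sequence: str, window: int = TM_WINDOW,
               threshold: float = TM_THRESHOLD, merge_gap: int = TM_MERGE_GAP,
               min_helix: int = TM_MIN_HELIX, max_helix: int = TM_MAX_HELIX
               ) -> TMTopology:
    """Transmembrane helices from a sliding hydropathy scan.

    Contiguous runs of window centres with mean hydropathy >= threshold become
    helices; runs separated by fewer than ``merge_gap`` residues are merged;
    each helix is expanded by half a window on both sides, discarded when
    shorter than ``min_helix``, capped at ``max_helix`` residues around its
    peak, and overlaps between consecutive helices are split at the midpoint.
    """
    profile = hydropathy_profile(sequence, window)
    half = window // 2
    centers = np.flatnonzero(profile >= threshold) + half  # 0-based residue idx
    if centers.size == 0:
        return TMTopology(helices=())
    runs: List[List[int]] = [[int(centers[0]), int(centers[0])]]
    for c in centers[1:]:
        if c - runs[-1][1] - 1 < merge_gap:
            runs[-1][1] = int(c)
        else:
            runs.append([int(c), int(c)])
    helices = []
    for start_c, end_c in runs:
        s = max(0, start_c - half)
        e = min(len(sequence) - 1, end_c + half)
        if e - s + 1 < min_helix:
            continue
        if e - s + 1 > max_helix:
            seg = profile[start_c - half:end_c - half + 1]
            peak = start_c + int(np.argmax(seg))
            s = max(0, peak - max_helix // 2)
            e = min(len(sequence) - 1, s + max_helix - 1)
        helices.append([s, e])
    # split any residual overlaps between consecutive helices at the midpoint
    for i in range(1, len(helices)):
        if helices[i][0] <= helices[i - 1][1]:
            mid = (helices[i][0] + helices[i - 1][1]) // 2
            helices[i - 1][1] = mid
            helices[i][0] = mid + 1
    return TMTopology(helices=tuple((s + 1, e + 1) for s, e in helices))


def _scan_motif(segment: str) -> Tuple[Optional[str], Optional[int]]:
    """First D-x-x-x-K (priority) or S-x-x-x-K in the segment.

    Returns (motif string, index of the K within the segment)."""
    for first, name in (("D", "DxxxK"), ("S", "SxxxK")):
        for i in range(len(segment) - 4):
            if segment[i] == first and segment[i + 4] == "K":
                return name, i + 4
    return None, None


def classify_rhodopsin(sequence: str, topology: TMTopology,
                       protein_id: str = "") -> RhodopsinCall:
    """Type a candidate by topology and the helix-7 retinal-binding motif.

    A canonical call requires exactly seven predicted helices; helix 7 plus a
    +-5 residue flank is scanned for D-x-x-x-K (Type I) or S-x-x-x-K
    (heliorhodopsin), whose lysine is the retinal-binding residue. Anything
    else is non-canonical.
    """
    call = RhodopsinCall(protein_id=protein_id, rh_class="non_canonical",
                        n_helices=topology.n_helices)
    if topology.n_helices != 7:
        return call
    s, e = topology.helices[-1]
    lo = max(0, s - 1 - MOTIF_FLANK)
    hi = min(len(sequence), e + MOTIF_FLANK)
    motif, _k = _scan_motif(sequence[lo:hi])
    if motif == "DxxxK":
        call.rh_class = "type1"
    elif motif == "SxxxK":
        call.rh_class = "heliorhodopsin"
    if motif is not None:
        call.helix7_motif = motif
        call.retinal_lysine = True
    return call


# ---------------------------------------------------------------------------
# helix-C reference mapping
# ---------------------------------------------------------------------------

def _load_reference() -> dict:
    with resources.files("streamscan.data").joinpath(
            "rhodopsin_reference.synthetic.json").open() as fh:
        return json.load(fh)


_REFERENCE = None

def reference() -> dict:
    """Packaged synthetic helix-C reference segment with motif offsets."""
    global _REFERENCE
    if _REFERENCE is None:
        _REFERENCE = _load_reference()
    return _REFERENCE


def _ref_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    # free end gaps: the reference segment floats inside the query region
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = None

def _map_reference_offsets(query_region: str, offsets: List[int]
                           ) -> List[Optional[int]]:
    """Map reference-segment offsets to query-region indices via alignment."""
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _ref_aligner()
    ref = reference()["segment"]
    alignment = _ALIGNER.align(ref, query_region)[0]
    ref_blocks, q_blocks = alignment.aligned
    out: List[Optional[int]] = []
    for off in offsets:
        mapped = None
        for (rs, re), (qs, qe) in zip(ref_blocks, q_blocks):
            if rs <= off < re:
                mapped = qs + (off - rs)
                break
        out.append(mapped)
    return out


def _helixC_region(sequence: str, topology: TMTopology,
                   flank: int = 10) -> Optional[Tuple[int, str]]:
    if topology.n_helices < 3:
        return None
    s, e = topology.helices[2]  # helix C = third helix
    lo = max(0, s - 1 - flank)
    hi = min(len(sequence), e + flank)
    return lo, sequence[lo:hi]


def helixC_motif(sequence: str, topology: TMTopology) -> str:
    """Residues at the three helix-C proton-transfer reference positions.

    "DTE" marks the proton-pumping proteorhodopsin configuration (acceptor,
    stabiliser, donor). Returns "unknown" when helix C cannot be resolved or a
    position does not map through the reference alignment.
    """
    region = _helixC_region(sequence, topology)
    if region is None:
        return "unknown"
    lo, sub = region
    ref = reference()
    mapped = _map_reference_offsets(sub, [ref["d_offset"], ref["t_offset"],
                                          ref["e_offset"]])
    if any(m is None for m in mapped):
        return "unknown"
    return "".join(sub[m] for m in mapped)


def spectral_tuning(sequence: str, topology: TMTopology) -> Tuple[str, str]:
    """Residue at the spectral-tuning site (reference position 105 homolog).

    L indicates a green-light-absorbing proteorhodopsin, Q a blue-shifted one;
    anything else (or an unalignable site) is reported unknown.
    """
    region = _helixC_region(sequence, topology)
    if region is None:
        return "", "unknown"
    lo, sub = region
    mapped = _map_reference_offsets(sub, [reference()["tuning_offset"]])[0]
    if mapped is None:
        return "", "unknown"
    residue = sub[mapped]
    color = {"L": "green", "Q": "blue"}.get(residue, "unknown")
    return residue, color


def call_rhodopsin(protein_id: str, sequence: str) -> RhodopsinCall:
    """Full per-protein call: topology, class, helix-C triplet, tuning residue."""
    topology = predict_tm(sequence)
    call = classify_rhodopsin(sequence, topology, protein_id)
    if call.rh_class == "type1":
        call.helixC_triplet = helixC_motif(sequence, topology)
        call.tuning_residue, call.tuning_color = spectral_tuning(sequence, topology)
    return call
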
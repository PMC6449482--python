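"""Rigid-body superposition and the universal P-loop residue nomenclature.

P-loop channels share a structurally conserved pore domain; residues in the
S4-S5 linker (``k``), S5 (``o``), P1 (``p``) and S6 (``i``) helices can be
named by (repeat, segment code, index) labels that are comparable across
channels.  The shipped default map covers the hCav1.2 alpha-1 subunit and is
reconstructed from worked label/residue pairs; positions without such an
anchor are flagged provisional in the data file.

Superposition minimizes the RMS deviation of paired atoms (by convention
C-alpha atoms of the P1 helices, positions p38-p48, the most 3D-conserved
segments) with a proper rotation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

__all__ = ["UniversalLabel", "LabelMap", "Superposition", "label_to_resid",
           "resid_to_label", "select_by_labels", "superpose",
           "sequence_identity", "default_label_map", "SEGMENT_RANGES"]

# declared per-segment index ranges of the label map
SEGMENT_RANGES = {"k": (1, 11), "o": (1, 25), "p": (38, 48), "i": (9, 36)}


@dataclass(frozen=True)
class UniversalLabel:
    repeat: int          # 1-4
    segment_code: str    # k | o | p | i
    index: int

    def __post_init__(self):
        if self.repeat not in (1, 2, 3, 4):
            raise ValueError("repeat must be 1-4")
        if self.segment_code not in SEGMENT_RANGES:
            raise ValueError(f"unknown segment code {self.segment_code!r}")
        lo, hi = SEGMENT_RANGES[self.segment_code]
        if not lo <= self.index <= hi:
            raise ValueError(
                f"index {self.index} outside declared range "
                f"{self.segment_code}{lo}-{self.segment_code}{hi}")

    def __str__(self):
        return f"{self.repeat}{self.segment_code}{self.index}"


class LabelMap:
    """Anchored bijection between universal labels and residue numbers."""

    def __init__(self, anchors):
        # anchors: {(repeat, seg): (origin_index, anchor_resid, provisional)}
        self.anchors = dict(anchors)

    @classmethod
    def from_tsv(cls, path_or_file) -> "LabelMap":
        anchors = {}
        if hasattr(path_or_file, "read"):
            lines = path_or_file.read().splitlines()
        else:
            with open(path_or_file) as fh:
                lines = fh.read().splitlines()
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("repeat"):
                continue
            rep, seg, origin, anchor, prov = line.split("\t")
            anchors[(int(rep), seg)] = (int(origin), int(anchor),
                                        bool(int(prov)))
        return cls(anchors)

    def resid(self, label: UniversalLabel) -> int:
        key = (label.repeat, label.segment_code)
        if key not in self.anchors:
            raise KeyError(f"label map has no anchor for repeat "
                           f"{label.repeat} segment {label.segment_code!r}")
        origin, anchor, _ = self.anchors[key]
        return anchor + (label.index - origin)

    def label(self, resid: int) -> UniversalLabel:
        for (rep, seg), (origin, anchor, _) in self.anchors.items():
            lo, hi = SEGMENT_RANGES[seg]
            idx = origin + (resid - anchor)
            if lo <= idx <= hi:
                return UniversalLabel(rep, seg, idx)
        raise KeyError(f"residue {resid} is outside all declared label "
                       f"ranges")


def default_label_map() -> LabelMap:
    ref = importlib.resources.files("mcgate") / "data" / "label_map.tsv"
    with ref.open() as fh:
        return LabelMap.from_tsv(fh)


def label_to_resid(label: UniversalLabel, label_map: LabelMap) -> int:
    return label_map.resid(label)


def resid_to_label(resid: int, label_map: LabelMap) -> UniversalLabel:
    return label_map.label(resid)


def select_by_labels(system, repeat_set, segment_code: str, index_range,
                     label_map: LabelMap, atom_name: str = "CA"):
    """Atom locators for labelled positions, ordered by (repeat, index).

    ``index_range`` is inclusive ``(lo, hi)``.  Residue numbers are resolved
    against the system's alpha-1 segments (falling back to all segments);
    unresolvable labels are collected and reported together.
    """
    lo, hi = index_range
    out = []
    misses = []
    for rep in sorted(repeat_set):
        for idx in range(lo, hi + 1):
            label = UniversalLabel(rep, segment_code, idx)
            resnum = label_map.resid(label)
            found = None
            for seg in system.segments:
                for ri in seg.residue_indices:
                    if system.residues[ri].seq_number == resnum:
                        found = (seg.id, resnum, atom_name)
                        break
                if found:
                    break
            if found is None:
                misses.append(str(label))
            else:
                out.append(found)
    if misses:
        raise KeyError(f"labels not resolvable in system: {misses}")
    return out


@dataclass
class Superposition:
    rotation: np.ndarray       # proper rotation, det +1
    translation: np.ndarray
    rmsd: float
    per_atom_deviations: np.ndarray

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares superposition of paired coordinate sets.

    Finds the proper rotation R and translation t minimizing
    ``|| R x + t - y ||`` over the paired atoms; returns the fit together
    with per-atom deviations after transformation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("paired selections must have identical shape")
    if len(mobile) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centered = mobile - mobile.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selection is degenerate (collinear atoms)")
    sup = SVDSuperimposer()
    sup.set(reference, mobile)   # superimposes the second onto the first
    sup.run()
    rot, tran = sup.get_rotran()
    # Bio returns row-vector convention: y = x @ rot + tran
    fitted = mobile @ rot + tran
    dev = np.linalg.norm(fitted - reference, axis=1)
    return Superposition(rotation=np.asarray(rot).T,
                         translation=np.asarray(tran),
                         rmsd=float(np.sqrt(np.mean(dev ** 2))),
                         per_atom_deviations=dev)


def sequence_identity(seq_a: str, seq_b: str, span=None) -> float:
    """Percent identity between two aligned (gapped) sequences.

    ``span`` restricts the computation to alignment columns [start, stop)
    (0-based).  Columns where either sequence has a gap are not counted as
    identities but remain in the denominator of matched positions only when
    both are residues.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if span is not None:
        seq_a = seq_a[span[0]:span[1]]
        seq_b = seq_b[span[0]:span[1]]
    pairs = [(a, b) for a, b in zip(seq_a.upper(), seq_b.upper())
             if a not in "-." and b not in "-."]
    if not pairs:
        raise ValueError("no aligned residue pairs in span")
    same = sum(1 for a, b in pairs if a == b)
    return 100.0 * same / len(pairs)
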
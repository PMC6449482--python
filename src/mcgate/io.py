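"""Readers/writers, configuration and provenance.

PDB I/O goes through biotite; configuration is YAML with unknown keys
rejected against the documented defaults; every pipeline output directory
receives the resolved configuration and a provenance record sufficient for
a bit-identical re-run.  All file writes are atomic (temp file + rename).
"""

from __future__ import annotations

import hashlib
import json
import os
import string
import tempfile
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from biotite.structure import Atom as BAtom
from biotite.structure import array as batom_array
from biotite.structure.io.pdb import PDBFile

__all__ = ["TemplateStructure", "read_pdb", "write_pdb", "load_config",
           "save_config", "ProvenanceRecord", "write_provenance",
           "write_jsonl", "atomic_write_text", "DEFAULT_CONFIG"]


# ------------------------------------------------------------------- config
DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "results",
    "energy": {
        "cutoff": 9.0,
        "dielectric_slope": 4.0,
        "shift_mode": "shifted_force",
        "ionized_no_cutoff": True,
        "scale14": 0.5,
    },
    "restraints": {
        "pin_d": 1.0,
        "pin_k": 10.0,
        "bedplate_pin_d": 2.5,
        "sensor_pin_d": 2.0,
        "torsion_window_deg": 5.0,
        "aid_separation_cap": 9.0,
    },
    "mcm": {
        "temperature": 600.0,
        "max_min_iterations": 1000,
        "steered_min_iterations": 100,
        "convergence_window": 2000,
        "max_minimizations": 100000,
        "n_stages": 10,
        "stage_accepts": 50,
        "stage_proposals": 500,
    },
    "mutant": {
        "n_starts": 128,
        "r_flex": 15.0,
        "r_rigid": 20.0,
        "energy_window": 7.0,
    },
    "contacts": {
        "presence_floor": 0.4,
        "scheme": "fig3",
    },
}


def _merge(defaults, overrides, path=""):
    out = dict(defaults)
    for key, val in (overrides or {}).items():
        if key not in defaults:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"config key {path + key!r} must be a map")
            out[key] = _merge(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path=None, overrides=None) -> dict:
    """Resolved configuration: defaults <- YAML file <- overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, doc)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    atomic_write_text(path, yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


# -------------------------------------------------------------------- files
def atomic_write_text(path, text: str) -> None:
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_jsonl(records, path) -> None:
    atomic_write_text(path, "".join(json.dumps(r) + "\n" for r in records))


# --------------------------------------------------------------- provenance
@dataclass
class ProvenanceRecord:
    stage: str
    seed: int
    config_hash: str
    tool_version: str = ""
    input_digests: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def write_provenance(record: ProvenanceRecord, path) -> None:
    from . import __version__
    if not record.tool_version:
        record.tool_version = __version__
    atomic_write_text(path, json.dumps(asdict(record), indent=1,
                                       default=str))


# ---------------------------------------------------------------------- PDB
class TemplateStructure:
    """Lightweight coordinate container backed by a biotite atom array."""

    def __init__(self, atom_array, chain_segments=None, flagged=None):
        self.atoms = atom_array
        self.flagged_residues = flagged or []
        self._index = {}
        for i in range(atom_array.array_length()):
            key = (str(atom_array.chain_id[i]), int(atom_array.res_id[i]),
                   str(atom_array.atom_name[i]))
            self._index.setdefault(key, i)

    def get(self, key):
        i = self._index.get((key[0], int(key[1]), key[2]))
        return None if i is None else np.asarray(self.atoms.coord[i])

    def coords(self, chain, resnum, atom_name):
        return self.get((chain, resnum, atom_name))

    def calpha(self, chain, resnum):
        return self.get((chain, resnum, "CA"))

    def residue_keys(self):
        seen = []
        prev = None
        for i in range(self.atoms.array_length()):
            key = (str(self.atoms.chain_id[i]), int(self.atoms.res_id[i]))
            if key != prev:
                seen.append(key)
                prev = key
        return seen


def read_pdb(path) -> TemplateStructure:
    """Parse a PDB file into a template structure.

    The highest-occupancy altloc conformer is retained; insertion codes are
    preserved by biotite; residues missing backbone atoms are flagged (not
    dropped).  Malformed records raise with the offending line number.
    """
    try:
        pdb = PDBFile.read(path)
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        line = _find_bad_line(path)
        raise ValueError(
            f"cannot parse PDB file {path!r}"
            + (f" (near line {line})" if line else "") + f": {exc}"
        ) from exc
    flagged = []
    for key in {(str(c), int(r)) for c, r in
                zip(arr.chain_id, arr.res_id)}:
        names = set(arr.atom_name[(arr.chain_id == key[0])
                                  & (arr.res_id == key[1])])
        if not {"N", "CA", "C"} <= names:
            flagged.append(key)
    return TemplateStructure(arr, flagged=sorted(flagged))


def _find_bad_line(path):
    try:
        with open(path) as fh:
            for n, ln in enumerate(fh, 1):
                if ln.startswith(("ATOM", "HETATM")) and len(ln.rstrip()) < 54:
                    return n
    except OSError:
        return None
    return None


def write_pdb(system, path, chain_map=None) -> dict:
    """Write a system's coordinates as PDB; returns the segment -> chain-id
    mapping used (PDB chains are single characters)."""
    system.rebuild()
    letters = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if chain_map is None:
        chain_map = {seg.id: letters[i % len(letters)]
                     for i, seg in enumerate(system.segments)}
    atoms = []
    for seg in system.segments:
        for ri in seg.residue_indices:
            res = system.residues[ri]
            for ai in res.atom_indices:
                atoms.append(BAtom(
                    coord=system.cartesian[ai],
                    chain_id=chain_map[seg.id],
                    res_id=int(res.seq_number),
                    res_name=res.name,
                    atom_name=str(system.atom_names[ai]),
                    element=str(system.atom_elements[ai]),
                ))
    arr = batom_array(atoms)
    pdb = PDBFile()
    pdb.set_structure(arr)
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=".pdb")
    os.close(fd)
    try:
        pdb.write(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return chain_map
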
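"""Core domain types and structure/trajectory I/O.

Coordinates are Ångström throughout. Residue indices are 0-based within
their chain internally; file I/O and reports use 1-based numbering (PDB
convention). Structures are plain heavy-atom (or heavy+H) models: no force
field, no connectivity beyond what residue/chain topology implies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    FrameMismatchError,
    PdbParseError,
)

log = logging.getLogger(__name__)

#: Bondi-style van-der-Waals radii (Å). The default table shipped with the
#: package; user tables override per element.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_RADIUS = 1.50

#: Side-chain formal charges of the standard amino acids at pH 7.
PH7_SIDECHAIN_CHARGES: dict[str, int] = {
    "ASP": -1,
    "GLU": -1,
    "LYS": +1,
    "ARG": +1,
    "HIS": 0,
}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class Phase(str, Enum):
    """Simulation phase a replica belongs to."""

    BULK = "bulk"
    VACUUM = "vacuum"
    REHYDRATION = "rehydration"


@dataclass
class AtomRecord:
    """One atom of a structure.

    ``residue_index`` is 0-based within the chain; ``formal_charge`` is in
    elementary charges and lives on one representative atom per charged
    group (side-chain carbon for side chains, backbone N/O for termini).
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    vdw_radius: float
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")


class StructureModel:
    """One conformation: an ordered list of atoms with chain/residue topology."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        self._index_residues()

    def _index_residues(self) -> None:
        self._residue_atoms: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._residue_atoms.setdefault((a.chain_id, a.residue_index), []).append(i)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def sequence(self, chain_id: str) -> list[str]:
        """Residue names of one chain, ordered by residue index."""
        resnames: dict[int, str] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                resnames.setdefault(a.residue_index, a.residue_name)
        return [resnames[i] for i in sorted(resnames)]

    def residues(self) -> Iterator[tuple[str, int, str, list[int]]]:
        """Yield (chain_id, residue_index, residue_name, atom indices) in atom order."""
        for (chain, ri), idx in self._residue_atoms.items():
            yield chain, ri, self.atoms[idx[0]].residue_name, idx

    def residue_atom_indices(self, chain_id: str, residue_index: int) -> list[int]:
        return self._residue_atoms[(chain_id, residue_index)]

    def residue_charge(self, chain_id: str, residue_index: int) -> int:
        return sum(self.atoms[i].formal_charge
                   for i in self._residue_atoms[(chain_id, residue_index)])

    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    # -- copies ------------------------------------------------------------
    def copy(self) -> "StructureModel":
        return StructureModel([replace(a, position=a.position.copy()) for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape ({self.n_atoms}, 3), got {coords.shape}")
        new = self.copy()
        for a, xyz in zip(new.atoms, coords):
            a.position = xyz.copy()
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureModel):
            return NotImplemented
        if self.n_atoms != other.n_atoms:
            return False
        for a, b in zip(self.atoms, other.atoms):
            if (a.serial, a.name, a.element, a.residue_index, a.residue_name,
                    a.chain_id, a.formal_charge) != \
               (b.serial, b.name, b.element, b.residue_index, b.residue_name,
                    b.chain_id, b.formal_charge):
                return False
            if not np.array_equal(a.position, b.position):
                return False
        return True


@dataclass
class TrajectoryEnsemble:
    """Ordered frames of coordinates sharing one topology."""

    topology: StructureModel
    frames: np.ndarray          # (n_frames, n_atoms, 3) Å
    frame_times: np.ndarray     # ns, strictly increasing
    replica_id: str = "r0"
    phase: Phase = Phase.BULK

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise FrameMismatchError(
                f"frames carry {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}")
        if len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length must equal frame count")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        self.phase = Phase(self.phase)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class ReplicaSet:
    """Replica trajectories sharing one topology and phase."""

    replicas: list[TrajectoryEnsemble]

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("ReplicaSet needs at least one replica")
        ref = self.replicas[0]
        names = [a.name for a in ref.topology.atoms]
        for r in self.replicas[1:]:
            if r.topology.n_atoms != ref.topology.n_atoms or \
                    [a.name for a in r.topology.atoms] != names:
                raise FrameMismatchError(
                    f"replica {r.replica_id} does not share the set topology")
            if r.phase != ref.phase:
                raise ValueError("all replicas in a set must share one phase")

    @property
    def topology(self) -> StructureModel:
        return self.replicas[0].topology

    @property
    def phase(self) -> Phase:
        return self.replicas[0].phase

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def pooled_frames(self) -> np.ndarray:
        """All frames of all replicas concatenated, (sum n_frames, n_atoms, 3)."""
        return np.concatenate([r.frames for r in self.replicas], axis=0)


# ---------------------------------------------------------------------------
# element / radius resolution

def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    # two-letter elements seen in proteins; otherwise first letter
    two = stripped[:2].upper()
    if two in {"CL", "BR", "FE", "ZN", "MG", "NA", "SE"}:
        return two.capitalize()
    return stripped[0].upper()


def resolve_radius(element: str, radii_table: Mapping[str, float] | None,
                   default_radius: float = DEFAULT_RADIUS) -> float:
    table = dict(DEFAULT_VDW_RADII)
    if radii_table:
        table.update({k.upper() if len(k) == 1 else k.capitalize(): v
                      for k, v in radii_table.items()})
    key = element.upper() if len(element) == 1 else element.capitalize()
    if key in table:
        return table[key]
    if element.upper() in table:
        return table[element.upper()]
    log.warning("unknown element %r: using default radius %.2f Å", element, default_radius)
    return default_radius


# ---------------------------------------------------------------------------
# PDB reading / writing

def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serials may overflow or be blank; not load-bearing
    name = line[12:16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or "A"
    try:
        resseq = int(line[22:26])
    except ValueError as exc:
        raise PdbParseError(f"line {lineno}: unparseable residue number: {line.rstrip()!r}") from exc
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"line {lineno}: unparseable coordinates: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(name)
    return {"serial": serial, "name": name, "resname": resname, "chain": chain,
            "resseq": resseq, "xyz": (x, y, z), "element": element}


def read_structure(path: str | Path,
                   radii_table: Mapping[str, float] | None = None,
                   default_radius: float = DEFAULT_RADIUS) -> StructureModel:
    """Read the first model of a PDB file into a :class:`StructureModel`.

    Elements come from columns 77–78 with an atom-name fallback; vdW radii
    from ``radii_table`` over the built-in Bondi-style defaults. Unknown
    elements get ``default_radius`` with a logged warning.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    res_counter: dict[str, int] = {}
    last_resseq: dict[str, int | None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM  ", "HETATM"):
                continue
            p = _parse_atom_line(line, lineno)
            chain = p["chain"]
            if chain not in res_counter:
                res_counter[chain] = -1
                last_resseq[chain] = None
            if p["resseq"] != last_resseq[chain]:
                res_counter[chain] += 1
                last_resseq[chain] = p["resseq"]
            atoms.append(AtomRecord(
                serial=p["serial"], name=p["name"], element=p["element"],
                residue_index=res_counter[chain], residue_name=p["resname"],
                chain_id=chain, position=np.array(p["xyz"]),
                vdw_radius=resolve_radius(p["element"], radii_table, default_radius)))
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(atoms)


def _format_atom_name(name: str, element: str) -> str:
    # PDB column rule: 1-letter elements start in column 14 unless 4 chars
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(a: AtomRecord, serial: int) -> str:
    return (f"ATOM  {serial:5d} {_format_atom_name(a.name, a.element)} "
            f"{a.residue_name:>3s} {a.chain_id:1s}{a.residue_index + 1:4d}    "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB file (ATOM/TER/END)."""
    with open(path, "w") as fh:
        fh.write(_structure_block(structure))
        fh.write("END\n")


def _structure_block(structure: StructureModel,
                     coords: np.ndarray | None = None) -> str:
    lines = []
    serial = 0
    prev_chain = None
    atoms = structure.atoms
    pos = structure.coords if coords is None else np.asarray(coords)
    for i, a in enumerate(atoms):
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        tmp = replace(a, position=pos[i])
        lines.append(_atom_line(tmp, serial))
    lines.append("TER")
    return "\n".join(lines) + "\n"


def write_trajectory(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL per frame)."""
    with open(path, "w") as fh:
        for m, frame in enumerate(ensemble.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            fh.write(_structure_block(ensemble.topology, frame))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_pdb_models(path: Path) -> list[tuple[list[tuple[float, float, float]], int]]:
    models: list[tuple[list, int]] = []
    current: list | None = None
    model_no = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                model_no += 1
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append((current, model_no))
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:  # headerless single-model file
                    model_no += 1
                    current = []
                p = _parse_atom_line(line, lineno)
                current.append(p["xyz"])
    if current:  # file without trailing ENDMDL
        models.append((current, model_no))
    return models


def _read_xyz_models(path: Path) -> list[tuple[list[tuple[float, float, float]], int]]:
    models = []
    with open(path) as fh:
        lines = fh.readlines()
    i, model_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise PdbParseError(f"line {i + 1}: expected atom count in XYZ block") from exc
        model_no += 1
        block = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            try:
                block.append((float(parts[1]), float(parts[2]), float(parts[3])))
            except (IndexError, ValueError) as exc:
                raise PdbParseError(
                    f"line {i + 3 + j}: unparseable XYZ coordinates") from exc
        models.append((block, model_no))
        i += 2 + n
    return models


def read_trajectory(path: str | Path, topology: StructureModel,
                    dt: float = 1.0,
                    frame_times: Sequence[float] | None = None,
                    replica_id: str = "r0",
                    phase: Phase | str = Phase.BULK) -> TrajectoryEnsemble:
    """Read a multi-model PDB or XYZ file against a known topology.

    ``frame_times`` (ns) overrides the default ``dt × (index+1)`` clock.
    Every model must carry exactly the topology's atom count.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        models = _read_xyz_models(path)
    else:
        models = _read_pdb_models(path)
    if not models:
        raise EmptyStructureError(f"{path}: no coordinate models found")
    frames = []
    for xyz, model_no in models:
        if len(xyz) != topology.n_atoms:
            raise FrameMismatchError(
                f"model {model_no}: {len(xyz)} atoms, topology has {topology.n_atoms}")
        frames.append(np.array(xyz, dtype=float))
    if frame_times is None:
        frame_times = dt * (np.arange(len(frames)) + 1)
    return TrajectoryEnsemble(topology=topology, frames=np.stack(frames),
                              frame_times=np.asarray(frame_times, dtype=float),
                              replica_id=replica_id, phase=Phase(phase))


# ---------------------------------------------------------------------------
# solution-state formal charges

def _sidechain_rep_index(structure: StructureModel, atom_idx: list[int]) -> int:
    names = {structure.atoms[i].name: i for i in atom_idx}
    for cand in ("CB", "CG", "CA"):
        if cand in names:
            return names[cand]
    return atom_idx[0]


def assign_solution_charges(structure: StructureModel, pH: float = 7.0,
                            rules: Mapping[str, int] | None = None) -> StructureModel:
    """Assign formal charges from side-chain pKa rules at the given pH.

    Defaults (pH 7): Asp/Glu −1, Lys/Arg +1, His 0, plus +1 on each chain's
    N-terminal nitrogen and −1 on its C-terminal oxygen. Non-standard
    residues get charge 0 with a logged warning. Idempotent: charges are
    reset before assignment.
    """
    rules = dict(PH7_SIDECHAIN_CHARGES if rules is None else rules)
    out = structure.copy()
    for a in out.atoms:
        a.formal_charge = 0
    per_chain: dict[str, list[tuple[int, list[int]]]] = {}
    for chain, ri, resname, idx in out.residues():
        per_chain.setdefault(chain, []).append((ri, idx))
        if resname in rules:
            q = rules[resname]
            if q:
                out.atoms[_sidechain_rep_index(out, idx)].formal_charge = q
        elif resname not in STANDARD_RESIDUES:
            log.warning("non-standard residue %s %s%d: charge 0",
                        resname, chain, ri + 1)
    # termini: +1 on N-terminal N, −1 on C-terminal OXT/O
    for chain, residues in per_chain.items():
        residues.sort(key=lambda t: t[0])
        first_idx = residues[0][1]
        last_idx = residues[-1][1]
        n_names = {out.atoms[i].name: i for i in first_idx}
        c_names = {out.atoms[i].name: i for i in last_idx}
        n_at = n_names.get("N", first_idx[0])
        c_at = c_names.get("OXT", c_names.get("O", last_idx[-1]))
        out.atoms[n_at].formal_charge += 1
        out.atoms[c_at].formal_charge -= 1
    return out


# ---------------------------------------------------------------------------
# atom selections

def select_atoms(structure: StructureModel, selection: str) -> np.ndarray:
    """Resolve a selection string to ascending atom indices.

    Tokens (combined with ``and`` = intersection): ``all``, ``heavy``,
    ``calpha``, ``chain=X``, ``resid=A-B`` (1-based inclusive residue range,
    report numbering). Raises :class:`EmptySelectionError` on empty results.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    for token in [t.strip() for t in selection.split(" and ")]:
        if token == "all" or token == "":
            continue
        elif token == "heavy":
            mask &= np.array([a.element.upper() != "H" for a in structure.atoms])
        elif token == "calpha":
            mask &= np.array([a.name == "CA" for a in structure.atoms])
        elif token.startswith("chain="):
            cid = token.split("=", 1)[1]
            mask &= np.array([a.chain_id == cid for a in structure.atoms])
        elif token.startswith("resid="):
            rng = token.split("=", 1)[1]
            if "-" in rng:
                lo, hi = (int(v) for v in rng.split("-"))
            else:
                lo = hi = int(rng)
            mask &= np.array([lo <= a.residue_index + 1 <= hi for a in structure.atoms])
        else:
            raise EmptySelectionError(f"unknown selection token {token!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(f"selection {selection!r} matched no atoms")
    return idx
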
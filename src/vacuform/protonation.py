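"""Vacuum protonation-site assignment for electrosprayed proteins.

Electrospray ionization leaves a protein with a fixed net positive charge.
To mimic that in a vacuum model, extra protons are placed on the residues
most likely to take them: the six types with appreciable gas-phase
basicity (Lys, Arg, His, Gln, Asp, Glu). The protocol:

1. compute per-residue solvent-accessible surface area (SASA) averaged
   over solution-phase frames; drop residues below a 50 Å² exposure
   threshold (buried residues do not meet excess protons),
2. rank survivors by gas-phase basicity (GPB), descending,
3. skip candidates with a positively charged neighbour (Coulomb
   repulsion disfavours a second adjacent charge),
4. walk the ranked list, protonating identically in all sequence-identical
   chains, until the target net charge is reached exactly.

Protonating Asp/Glu neutralizes the carboxylate (−1 → 0); protonating
His/Gln adds a positive charge (0 → +1); Lys/Arg are already protonated
at pH 7 and cannot take a second proton.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .core import StructureModel, TrajectoryEnsemble
from .errors import (
    ConfigError,
    DataError,
    DoubleProtonationError,
    InsufficientSitesError,
    ParityError,
)
from .geometry import shrake_rupley_sasa

log = logging.getLogger(__name__)

#: Default gas-phase basicities (kJ/mol) for the six candidate residue
#: types, literature-style ordering Arg > Lys > His > Gln > Glu > Asp.
#: Only the ordering matters to the protocol; values are user-overridable.
DEFAULT_GPB: dict[str, float] = {
    "ARG": 1006.6,
    "LYS": 951.0,
    "HIS": 950.2,
    "GLN": 937.8,
    "GLU": 909.0,
    "ASP": 886.0,
}

CANDIDATE_TYPES = frozenset(DEFAULT_GPB)
#: Residue types whose protonation changes the charge (−1→0 or 0→+1).
PROTONATABLE = {"ASP": (-1, 0), "GLU": (-1, 0), "HIS": (0, 1), "GLN": (0, 1)}


def gpb_table(overrides: dict[str, float] | None = None) -> dict[str, float]:
    """The GPB table (kJ/mol), optionally overridden per residue type."""
    table = dict(DEFAULT_GPB)
    if overrides:
        for k, v in overrides.items():
            if v <= 0:
                raise ConfigError(f"GPB for {k} must be positive, got {v}")
            table[k.upper()] = float(v)
    return table


@dataclass
class CandidateSite:
    """One potential protonation site with its selection provenance."""

    chain_id: str
    residue_index: int        # 0-based internal; +1 in reports
    residue_name: str
    mean_sasa: float          # Å², averaged over frames
    sd_sasa: float
    gpb: float                # kJ/mol
    excluded: bool = False
    exclusion_reason: str = ""
    selected: bool = False
    outcome: str = ""         # filled by the planner for every visited site


@dataclass
class ProtonationPlan:
    """Ordered site decisions leading from the solution to the vacuum charge."""

    target_charge: int
    sites: list[CandidateSite]
    resulting_charge: int
    initial_charge: int
    sasa_threshold: float = 50.0
    symmetric: bool = True

    def selected_sites(self) -> list[CandidateSite]:
        return [s for s in self.sites if s.selected]

    def to_json(self, indent: int = 2) -> str:
        d = asdict(self)
        for s in d["sites"]:
            s["resid"] = s.pop("residue_index") + 1  # report numbering
        return json.dumps(d, indent=indent, sort_keys=True)

    def to_table(self) -> str:
        """Human-readable table: residue, mean SASA ± sd, charge states."""
        rows = ["Residue    SASA [Å²]          Solution  Vacuum"]
        for s in self.selected_sites():
            before, after = PROTONABLE_STATES[s.residue_name]
            rows.append(f"{s.residue_name}{s.residue_index + 1:<4d}({s.chain_id})  "
                        f"{s.mean_sasa:7.2f} (±{s.sd_sasa:.2f})   "
                        f"{before:+d}        {after:+d}")
        rows.append(f"Target charge {self.target_charge:+d} e; resulting "
                    f"{self.resulting_charge:+d} e")
        return "\n".join(rows)


PROTONABLE_STATES = PROTONATABLE  # alias used in reports


# ---------------------------------------------------------------------------
# step 1: per-residue SASA

def per_residue_sasa(trajectory: TrajectoryEnsemble, probe: float = 1.4,
                     restrict: frozenset[str] | set[str] | None = CANDIDATE_TYPES,
                     n_points: int = 960,
                     frame_stride: int = 1) -> pd.DataFrame:
    """Mean ± sd per-residue SASA over trajectory frames.

    A residue's SASA per frame is the sum of its member atoms' accessible
    areas (computed in the full-structure context). ``restrict`` limits the
    output to the given residue types (None = all).
    """
    if restrict is not None and len(restrict) == 0:
        raise DataError("empty residue-type restriction set")
    topo = trajectory.topology
    radii = topo.radii
    residues = [(chain, ri, name, idx) for chain, ri, name, idx in topo.residues()
                if restrict is None or name in restrict]
    frames = trajectory.frames[::frame_stride]
    if len(frames) == 0:
        raise DataError("per_residue_sasa needs at least one frame")
    per_frame = np.empty((len(frames), len(residues)))
    for f, frame in enumerate(frames):
        areas = shrake_rupley_sasa(frame, radii, probe=probe, n_points=n_points)
        for r, (_, _, _, idx) in enumerate(residues):
            per_frame[f, r] = areas[idx].sum()
    sd = per_frame.std(axis=0, ddof=1) if len(frames) > 1 else np.zeros(len(residues))
    return pd.DataFrame({
        "chain": [c for c, _, _, _ in residues],
        "residue_index": [ri for _, ri, _, _ in residues],
        "resname": [n for _, _, n, _ in residues],
        "mean_sasa": per_frame.mean(axis=0),
        "sd_sasa": sd,
    })


# ---------------------------------------------------------------------------
# step 2: candidate selection and ranking

def select_candidates(sasa_table: pd.DataFrame,
                      gpb: dict[str, float] | None = None,
                      threshold: float = 50.0) -> list[CandidateSite]:
    """Threshold on mean SASA, then rank by GPB.

    Residues with mean SASA < ``threshold`` are dropped. Survivors are
    sorted by GPB descending; ties broken by larger SASA, then lower
    residue index.
    """
    table = gpb_table(gpb)
    sites = []
    for row in sasa_table.itertuples():
        if row.resname not in table:
            continue
        if row.mean_sasa < threshold:
            continue
        sites.append(CandidateSite(
            chain_id=row.chain, residue_index=int(row.residue_index),
            residue_name=row.resname, mean_sasa=float(row.mean_sasa),
            sd_sasa=float(getattr(row, "sd_sasa", 0.0)),
            gpb=table[row.resname]))
    sites.sort(key=lambda s: (-s.gpb, -s.mean_sasa, s.residue_index, s.chain_id))
    return sites


# ---------------------------------------------------------------------------
# step 3: positive-neighbour exclusion

def _charged_group_centroid(structure: StructureModel, chain: str, ri: int) -> np.ndarray:
    idx = structure.residue_atom_indices(chain, ri)
    charged = [i for i in idx if structure.atoms[i].formal_charge != 0]
    use = charged or idx
    return np.mean([structure.atoms[i].position for i in use], axis=0)


def apply_neighbor_exclusion(candidates: list[CandidateSite],
                             structure: StructureModel,
                             mode: str = "sequence",
                             spatial_cutoff: float | None = None
                             ) -> list[CandidateSite]:
    """Mark candidates adjacent to a positive charge as excluded.

    ``sequence`` mode excludes a candidate whose sequence neighbour (±1 in
    the same chain) carries formal charge +1. ``spatial`` mode excludes a
    candidate whose charged-group centroid lies within ``spatial_cutoff``
    Å of any +1 residue's. The structure must carry solution charges.
    """
    if mode not in ("sequence", "spatial"):
        raise ConfigError(f"unknown neighbor-exclusion mode {mode!r}")
    if mode == "spatial" and spatial_cutoff is None:
        raise ConfigError("spatial neighbor-exclusion requires a cutoff")
    positives = [(chain, ri, name) for chain, ri, name, _ in structure.residues()
                 if structure.residue_charge(chain, ri) > 0]
    pos_by_chain: dict[str, dict[int, str]] = {}
    for chain, ri, name in positives:
        pos_by_chain.setdefault(chain, {})[ri] = name
    one_letter = {"LYS": "K", "ARG": "R", "HIS": "H"}
    for cand in candidates:
        if mode == "sequence":
            for off in (-1, +1):
                nb = cand.residue_index + off
                name = pos_by_chain.get(cand.chain_id, {}).get(nb)
                if name is not None:
                    cand.excluded = True
                    cand.exclusion_reason = (
                        f"positive neighbor {one_letter.get(name, name)} at "
                        f"i{off:+d}")
                    break
        else:
            c0 = _charged_group_centroid(structure, cand.chain_id, cand.residue_index)
            for chain, ri, name in positives:
                if chain == cand.chain_id and ri == cand.residue_index:
                    continue
                d = float(np.linalg.norm(
                    _charged_group_centroid(structure, chain, ri) - c0))
                if d <= spatial_cutoff:
                    cand.excluded = True
                    cand.exclusion_reason = (
                        f"positive residue {name}{ri + 1}({chain}) at {d:.1f} Å")
                    break
    return candidates


# ---------------------------------------------------------------------------
# step 4: plan construction and application

def build_protonation_plan(structure: StructureModel,
                           candidates: list[CandidateSite],
                           target_charge: int,
                           symmetric: bool = True,
                           sasa_threshold: float = 50.0) -> ProtonationPlan:
    """Walk the ranked candidate list until the target net charge is reached.

    In symmetric mode each accepted residue position is protonated in all
    sequence-identical chains simultaneously (consuming n_chains charge
    units per step), so the deficit must divide evenly by the chain count.
    Every visited site is recorded with its outcome.
    """
    current = structure.net_charge()
    if target_charge < current:
        raise ConfigError(f"target charge {target_charge:+d} below current {current:+d}")
    chains = structure.chains()
    n_chains = len(chains)
    needed = target_charge - current
    if symmetric:
        seqs = [structure.sequence(c) for c in chains]
        if any(s != seqs[0] for s in seqs[1:]):
            raise DataError("symmetric protonation requires sequence-identical chains")
        if needed % n_chains != 0:
            raise ParityError(
                f"charge deficit {needed} not divisible by {n_chains} chains")
    plan_sites: list[CandidateSite] = []
    processed: set[int] = set()  # id()s of sites already decided
    remaining = needed

    def visit(site: CandidateSite, outcome: str, selected: bool = False) -> None:
        site.outcome = outcome
        site.selected = selected
        plan_sites.append(site)
        processed.add(id(site))

    for cand in candidates:
        if remaining == 0:
            break
        if id(cand) in processed:
            continue
        if cand.excluded:
            visit(cand, f"excluded: {cand.exclusion_reason}")
            continue
        if cand.residue_name not in PROTONATABLE:
            visit(cand, "already protonated at pH 7")
            continue
        if symmetric:
            partners = [c for c in candidates
                        if c.residue_index == cand.residue_index and c is not cand]
            bad = next((p for p in partners if p.excluded), None)
            if bad is not None:
                visit(cand, f"symmetric partner excluded in chain {bad.chain_id}: "
                            f"{bad.exclusion_reason}")
                continue
            if len(partners) + 1 < n_chains:
                visit(cand, "site not eligible in all chains")
                continue
            visit(cand, "selected (all chains)", selected=True)
            for p in partners:
                visit(p, "selected (all chains)", selected=True)
            remaining -= n_chains
        else:
            visit(cand, "selected", selected=True)
            remaining -= 1
    if remaining > 0:
        raise InsufficientSitesError(
            f"candidates exhausted {remaining} charge unit(s) short of "
            f"target {target_charge:+d}", shortfall=remaining)
    return ProtonationPlan(target_charge=target_charge, sites=plan_sites,
                           resulting_charge=current + needed,
                           initial_charge=current,
                           sasa_threshold=sasa_threshold, symmetric=symmetric)


def apply_plan(structure: StructureModel, plan: ProtonationPlan) -> StructureModel:
    """Apply a protonation plan, returning a new structure.

    Each selected Asp/Glu goes −1 → 0 and each His/Gln 0 → +1 on the
    residue's charge-bearing atom. A site already in its protonated state
    raises :class:`DoubleProtonationError`.
    """
    out = structure.copy()
    for site in plan.selected_sites():
        before, after = PROTONATABLE[site.residue_name]
        q = out.residue_charge(site.chain_id, site.residue_index)
        if q == after:
            raise DoubleProtonationError(
                f"{site.residue_name}{site.residue_index + 1}({site.chain_id}) "
                f"already at charge {after:+d}")
        if q != before:
            raise DataError(
                f"{site.residue_name}{site.residue_index + 1}({site.chain_id}) "
                f"at unexpected charge {q:+d} (expected {before:+d})")
        idx = out.residue_atom_indices(site.chain_id, site.residue_index)
        carriers = [i for i in idx if out.atoms[i].formal_charge == before] if before \
            else [_sidechain_rep(out, idx)]
        out.atoms[carriers[0]].formal_charge = after
    if out.net_charge() != plan.resulting_charge:
        raise DataError(f"applied plan yields {out.net_charge():+d} e, "
                        f"plan promised {plan.resulting_charge:+d} e")
    return out


def _sidechain_rep(structure: StructureModel, idx: list[int]) -> int:
    names = {structure.atoms[i].name: i for i in idx}
    for cand in ("CB", "CG", "CA"):
        if cand in names:
            return names[cand]
    return idx[0]
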
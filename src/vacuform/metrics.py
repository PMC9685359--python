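"""Trajectory analytics: Kabsch superposition RMSD, ensemble-average
structures, per-residue RMSF, residue contact maps with replica occupancy,
and geometric hydrogen-bond counting.

All metrics are deterministic given their inputs. Replica aggregation
follows the convention that per-time-point averages carry the standard
deviation across replicas, while time-window averages carry the standard
error of the pooled values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ReplicaSet, StructureModel, select_atoms
from .errors import DataError, DegenerateFitError, EmptySelectionError

log = logging.getLogger(__name__)


@dataclass
class SeriesStat:
    """A replica-averaged time series: mean ± spread at each time point.

    ``samples`` (n_times × n_replicas), when present, holds the raw
    per-replica values so tail windows can pool them.
    """

    time: np.ndarray
    mean: np.ndarray
    spread: np.ndarray
    label: str = ""
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if not (len(self.time) == len(self.mean) == len(self.spread)):
            raise ValueError("time/mean/spread must have equal lengths")
        if np.any(self.spread < 0):
            raise ValueError("spread must be non-negative")


@dataclass
class OccupancyMatrix:
    """Residue×residue contact frequencies in [0, 1] over replica-frames."""

    matrix: np.ndarray
    residue_labels: list[tuple[str, int, str]]  # (chain, residue_index, name)
    chain_boundaries: list[int]                 # first residue row of each chain
    cutoff: float
    window: tuple[int, int]
    n_replicas: int

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("occupancy matrix must be symmetric")
        if np.any((m < 0) | (m > 1)):
            raise ValueError("occupancy values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition (proper rotation only).

    Fits ``mobile[selection]`` onto ``reference[selection]`` and returns
    ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best matches the
    reference; ``rmsd`` is evaluated on the selection after fitting.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    P = mobile[sel]
    Q = reference[sel]
    if len(P) < 3:
        raise DegenerateFitError(f"superposition needs >=3 atoms, got {len(P)}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(Q0, tol=1e-8) < 2 or np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateFitError("collinear point set: rotation underdetermined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(((fitted - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _superposed(mobile: np.ndarray, reference: np.ndarray,
                selection: np.ndarray) -> np.ndarray:
    R, t, _ = kabsch_superpose(mobile, reference, selection)
    return mobile @ R.T + t


# ---------------------------------------------------------------------------
# RMSD / average structure / RMSF

def rmsd_series(replicas: ReplicaSet, reference: StructureModel,
                selection: str = "calpha") -> SeriesStat:
    """Per-time-point superposed RMSD, averaged across replicas (± sd).

    All replicas must share one frame-time grid.
    """
    sel = select_atoms(replicas.topology, selection)
    ref = reference.coords
    times = replicas.replicas[0].frame_times
    for r in replicas.replicas[1:]:
        if len(r.frame_times) != len(times) or not np.allclose(r.frame_times, times):
            raise DataError(f"replica {r.replica_id}: frame times misaligned "
                            "(resampling not enabled)")
    vals = np.empty((len(times), replicas.n_replicas))
    for j, rep in enumerate(replicas.replicas):
        for i, frame in enumerate(rep.frames):
            _, _, rmsd = kabsch_superpose(frame, ref, sel)
            vals[i, j] = rmsd
    sd = vals.std(axis=1, ddof=1) if replicas.n_replicas > 1 else np.zeros(len(times))
    return SeriesStat(time=times, mean=vals.mean(axis=1), spread=sd,
                      label="rmsd [Å]", samples=vals)


def average_structure(replicas: ReplicaSet, selection: str = "all",
                      tol: float = 1e-6, max_iter: int = 50) -> StructureModel:
    """Iterative ensemble-average structure.

    Every pooled frame is superposed onto the running mean (fit on
    ``selection``, applied to all atoms); the mean is recomputed until it
    moves less than ``tol`` Å (at least two passes).
    """
    sel = select_atoms(replicas.topology, selection)
    frames = replicas.pooled_frames()
    mean = frames[0].copy()
    for _ in range(max_iter):
        fitted = np.stack([_superposed(f, mean, sel) for f in frames])
        new_mean = fitted.mean(axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            break
    return replicas.topology.with_coords(mean)


def rmsf_per_residue(replicas: ReplicaSet, average: StructureModel,
                     selection: str = "calpha"):
    """Per-residue RMSF (Å) about the ensemble-average structure.

    Each pooled frame is superposed onto the average; per-atom fluctuations
    ``sqrt(mean |x_i − x̄_i|²)`` are then averaged over each residue's
    selected atoms. Returns a DataFrame (chain, resid [1-based], resname,
    rmsf). Equals the RMSF of the concatenated replica trajectory.
    """
    import pandas as pd

    topo = replicas.topology
    sel = select_atoms(topo, selection)
    residue_of_sel = [(topo.atoms[i].chain_id, topo.atoms[i].residue_index,
                       topo.atoms[i].residue_name) for i in sel]
    missing = []
    covered = {(c, r) for c, r, _ in residue_of_sel}
    for chain, ri, name, _ in topo.residues():
        if (chain, ri) not in covered:
            missing.append(f"{chain}:{name}{ri + 1}")
    if missing:
        raise EmptySelectionError(
            f"selection {selection!r} misses residues: {', '.join(missing)}")
    frames = replicas.pooled_frames()
    ref = average.coords
    sq = np.zeros(len(sel))
    for f in frames:
        fitted = _superposed(f, ref, sel)
        sq += ((fitted[sel] - ref[sel]) ** 2).sum(axis=1)
    per_atom_msf = sq / len(frames)
    rows: dict[tuple[str, int, str], list[float]] = {}
    for key, msf in zip(residue_of_sel, per_atom_msf):
        rows.setdefault(key, []).append(msf)
    data = [{"chain": c, "resid": ri + 1, "resname": name,
             "rmsf": float(np.sqrt(np.mean(v)))}
            for (c, ri, name), v in rows.items()]
    return pd.DataFrame(data).sort_values(["chain", "resid"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# contacts

def _residue_index_arrays(topology: StructureModel):
    labels: list[tuple[str, int, str]] = []
    res_of_atom = np.empty(topology.n_atoms, dtype=int)
    for chain, ri, name, idx in topology.residues():
        res_of_atom[idx] = len(labels)
        labels.append((chain, ri, name))
    heavy = np.array([a.element.upper() != "H" for a in topology.atoms])
    boundaries, prev = [], None
    for k, (chain, _, _) in enumerate(labels):
        if chain != prev:
            boundaries.append(k)
            prev = chain
    return labels, res_of_atom, heavy, boundaries


def contact_map(coords: np.ndarray, topology: StructureModel,
                cutoff: float = 3.5) -> np.ndarray:
    """Boolean residue contact matrix (minimum heavy-atom distance ≤ cutoff).

    Symmetric with a True diagonal.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    labels, res_of_atom, heavy, _ = _residue_index_arrays(topology)
    n_res = len(labels)
    contacts = np.eye(n_res, dtype=bool)
    hidx = np.flatnonzero(heavy)
    tree = cKDTree(np.asarray(coords, dtype=float)[hidx])
    for a, b in tree.query_pairs(r=cutoff):
        ra, rb = res_of_atom[hidx[a]], res_of_atom[hidx[b]]
        contacts[ra, rb] = contacts[rb, ra] = True
    return contacts


def contact_occupancy(replicas: ReplicaSet,
                      window: tuple[int, int] | None = None,
                      cutoff: float = 3.5) -> OccupancyMatrix:
    """Contact occupancy over all (replica, frame-in-window) pairs.

    ``window`` is a per-replica frame slice ``(start, stop)``; ``None``
    means all frames. Occupancy 0 means the contact never occurred in any
    replica.
    """
    topo = replicas.topology
    labels, _, _, boundaries = _residue_index_arrays(topo)
    total = np.zeros((len(labels), len(labels)))
    n_obs = 0
    lo, hi = window if window is not None else (0, None)
    for rep in replicas.replicas:
        frames = rep.frames[lo:hi]
        if len(frames) == 0:
            raise DataError(f"replica {rep.replica_id}: empty frame window {window}")
        for frame in frames:
            total += contact_map(frame, topo, cutoff)
            n_obs += 1
    win = (lo, hi if hi is not None else replicas.replicas[0].n_frames)
    return OccupancyMatrix(matrix=total / n_obs, residue_labels=labels,
                           chain_boundaries=boundaries, cutoff=cutoff,
                           window=win, n_replicas=replicas.n_replicas)


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass
class HbondResult:
    count: int
    proxy_mode: bool  # True when no hydrogens were present (distance-only)


def hydrogen_bond_count(coords: np.ndarray, topology: StructureModel,
                        d_cutoff: float = 3.5,
                        angle_cutoff: float = 30.0) -> HbondResult:
    """Geometric hydrogen-bond count for one frame.

    Donors are N/O atoms with an attached hydrogen (H within 1.25 Å);
    acceptors are N/O. A bond requires donor–acceptor distance ≤
    ``d_cutoff`` and some H with H–D–A angle ≤ ``angle_cutoff``; pairs
    within one residue are ignored. Structures without hydrogens fall back
    to a distance-only donor-heavy-atom proxy, flagged in the result.
    """
    coords = np.asarray(coords, dtype=float)
    labels, res_of_atom, _, _ = _residue_index_arrays(topology)
    elem = np.array([a.element.upper() for a in topology.atoms])
    no_mask = (elem == "N") | (elem == "O")
    h_idx = np.flatnonzero(elem == "H")
    no_idx = np.flatnonzero(no_mask)
    if no_idx.size == 0:
        log.warning("no N/O atoms: hydrogen-bond count is 0")
        return HbondResult(0, proxy_mode=len(h_idx) == 0)
    proxy = len(h_idx) == 0
    attached: dict[int, list[int]] = {}
    if not proxy:
        htree = cKDTree(coords[h_idx])
        for k, i in enumerate(no_idx):
            hits = htree.query_ball_point(coords[i], 1.25)
            if hits:
                attached[i] = [h_idx[h] for h in hits]
        donors = [i for i in no_idx if i in attached]
    else:
        donors = list(no_idx)
        log.warning("structure has no hydrogens: counting donor-heavy-atom "
                    "proxy contacts only")
    count = 0
    atree = cKDTree(coords[no_idx])
    cos_cut = np.cos(np.radians(angle_cutoff))
    seen: set[tuple[int, int]] = set()
    for d in donors:
        for k in atree.query_ball_point(coords[d], d_cutoff):
            a = no_idx[k]
            if a == d or res_of_atom[a] == res_of_atom[d]:
                continue
            if proxy:
                key = (min(d, a), max(d, a))
                if key in seen:
                    continue
                seen.add(key)
                count += 1
            else:
                da = coords[a] - coords[d]
                da /= np.linalg.norm(da)
                for h in attached[d]:
                    dh = coords[h] - coords[d]
                    dh /= np.linalg.norm(dh)
                    if np.dot(da, dh) >= cos_cut:
                        count += 1
                        break
    return HbondResult(count=count, proxy_mode=proxy)


def plot_occupancy(occ: OccupancyMatrix, path: str, title: str = "") -> None:
    """Render an occupancy map to PNG with chain-boundary gridlines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(occ.matrix, vmin=0, vmax=1, origin="lower", cmap="viridis")
    for b in occ.chain_boundaries[1:]:
        ax.axhline(b - 0.5, color="w", lw=0.8)
        ax.axvline(b - 0.5, color="w", lw=0.8)
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="occupancy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
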
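"""Compaction and solution-structure-recovery arithmetic.

Vacuum exposure compacts a protein; rehydration relaxes most of the
compaction. This module quantifies both from phase-labelled metric series
(CCS, surface area, volume), contact-occupancy matrices, and hydrogen-bond
counts:

* compaction % = 100 · (bulk − vacuum_tail) / bulk
* recovery %   = 100 · (1 − |bulk − rehydration_tail| / bulk)

The absolute-gap form of recovery means over-expansion past the bulk
reference also lowers the score. Tail averages use the final fraction of
each series (default 10 %, mirroring a 50 ns tail of 500 ns trajectories).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import DataError, UndefinedRatioError
from .metrics import OccupancyMatrix, SeriesStat


def tail_average(series: SeriesStat, tail_fraction: float = 0.1
                 ) -> tuple[float, float]:
    """Mean ± sem over the final ``tail_fraction`` of a series.

    When the series carries raw per-replica samples the sem pools them;
    otherwise it is computed over the tail of the mean curve.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    n = len(series.mean)
    if n == 0:
        raise DataError("tail_average: empty series")
    k = max(1, int(round(n * tail_fraction)))
    if series.samples is not None:
        pooled = np.asarray(series.samples)[n - k:].ravel()
    else:
        pooled = series.mean[n - k:]
    mean = float(pooled.mean())
    sem = float(pooled.std(ddof=1) / np.sqrt(pooled.size)) if pooled.size > 1 else 0.0
    return mean, sem


def compaction_percent(bulk_ref: float, vacuum_tail: float) -> float:
    """Percent shrinkage of a metric in vacuum relative to the bulk reference."""
    if bulk_ref <= 0:
        raise ValueError("bulk reference must be positive")
    return 100.0 * (bulk_ref - vacuum_tail) / bulk_ref


def recovery_percent(bulk_ref: float, rehydration_tail: float
                     ) -> tuple[float, float]:
    """Recovery score and signed gap relative to the bulk reference.

    Returns ``(percent, gap)`` with ``gap = bulk_ref − rehydration_tail``
    and ``percent = 100·(1 − |gap|/bulk_ref)``.
    """
    if bulk_ref <= 0:
        raise ValueError("bulk reference must be positive")
    gap = bulk_ref - rehydration_tail
    return 100.0 * (1.0 - abs(gap) / bulk_ref), gap


def charge_bookkeeping(solution_charge: int, sites_per_chain: int,
                       n_chains: int) -> int:
    """Net vacuum charge after symmetric protonation (+1 e per site per chain)."""
    if sites_per_chain < 0 or n_chains < 0:
        raise ValueError("counts must be non-negative")
    return solution_charge + sites_per_chain * n_chains


def rmsf_change_percent(value_vacuum: float, value_rehydrated: float) -> float:
    """Signed percent change of a fluctuation value from vacuum to rehydrated."""
    if value_vacuum <= 0:
        raise ValueError("vacuum value must be positive")
    return 100.0 * (value_rehydrated - value_vacuum) / value_vacuum


@dataclass
class ContactRecovery:
    """Set comparison of binarized contact maps across the three phases."""

    restored_fraction: float           # |bulk ∩ rehyd| / |bulk|
    persistent_vacuum_fraction: float  # |(vac \ bulk) ∩ rehyd| / |vac \ bulk|
    n_bulk: int
    n_vacuum_only: int
    presence_threshold: float


def contact_recovery(bulk_occ: OccupancyMatrix, vacuum_occ: OccupancyMatrix,
                     rehydration_occ: OccupancyMatrix,
                     presence_threshold: float = 0.5) -> ContactRecovery:
    """Fraction of bulk contacts restored after rehydration, and fraction of
    vacuum-induced novel contacts that persist.

    Maps are binarized at ``presence_threshold`` and compared over
    unordered off-diagonal residue pairs. The persistent fraction is NaN
    when vacuum introduced no novel contacts.
    """
    b, v, r = bulk_occ.matrix, vacuum_occ.matrix, rehydration_occ.matrix
    if not (b.shape == v.shape == r.shape):
        raise DataError("occupancy matrices must share dimensions")
    iu = np.triu_indices(b.shape[0], k=1)
    B = b[iu] >= presence_threshold
    V = v[iu] >= presence_threshold
    R = r[iu] >= presence_threshold
    n_bulk = int(B.sum())
    if n_bulk == 0:
        raise UndefinedRatioError("bulk contact set is empty: restored fraction undefined")
    restored = float((B & R).sum() / n_bulk)
    vac_only = V & ~B
    n_vac_only = int(vac_only.sum())
    persistent = float((vac_only & R).sum() / n_vac_only) if n_vac_only else float("nan")
    return ContactRecovery(restored_fraction=restored,
                           persistent_vacuum_fraction=persistent,
                           n_bulk=n_bulk, n_vacuum_only=n_vac_only,
                           presence_threshold=presence_threshold)


@dataclass
class PhaseGeometry:
    """Tail-window (or reference) averages of the three size metrics."""

    ccs: tuple[float, float]     # (mean Å², sem)
    sasa: tuple[float, float]    # (mean Å², sem)
    volume: tuple[float, float]  # (mean Å³, sem)


@dataclass
class RecoveryReport:
    """Headline compaction/recovery numbers for one three-phase dataset."""

    bulk_ref: PhaseGeometry
    vacuum_tail: PhaseGeometry
    rehydration_tail: PhaseGeometry
    compaction_pct: dict[str, float]
    recovery_pct: dict[str, float]
    ccs_gap: float
    contact: ContactRecovery | None
    hbond_mean: dict[str, float]
    tail_fraction: float

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        rows = [
            "| metric | bulk ref | vacuum tail | rehydration tail | compaction % | recovery % |",
            "|---|---|---|---|---|---|",
        ]
        for key, unit in (("ccs", "Å²"), ("sasa", "Å²"), ("volume", "Å³")):
            b = getattr(self.bulk_ref, key)
            v = getattr(self.vacuum_tail, key)
            r = getattr(self.rehydration_tail, key)
            rows.append(
                f"| {key} [{unit}] | {b[0]:.1f} (±{b[1]:.1f}) | {v[0]:.1f} (±{v[1]:.1f}) "
                f"| {r[0]:.1f} (±{r[1]:.1f}) | {self.compaction_pct[key]:.2f} "
                f"| {self.recovery_pct[key]:.2f} |")
        lines = ["# Recovery report", "", *rows, "",
                 f"CCS gap (bulk − rehydration tail): {self.ccs_gap:.1f} Å²", ""]
        if self.contact is not None:
            lines += [
                f"Restored bulk contacts: {self.contact.restored_fraction:.3f} "
                f"(of {self.contact.n_bulk})",
                f"Persistent vacuum-only contacts: "
                f"{self.contact.persistent_vacuum_fraction:.3f} "
                f"(of {self.contact.n_vacuum_only})", ""]
        if self.hbond_mean:
            hb = ", ".join(f"{k}: {v:.1f}" for k, v in self.hbond_mean.items())
            lines.append(f"Mean hydrogen bonds per phase: {hb}")
        return "\n".join(lines) + "\n"


def build_report(bulk: PhaseGeometry, vacuum: PhaseGeometry,
                 rehydration: PhaseGeometry,
                 contact: ContactRecovery | None = None,
                 hbond_mean: dict[str, float] | None = None,
                 tail_fraction: float = 0.1) -> RecoveryReport:
    """Assemble a :class:`RecoveryReport` from per-phase geometry averages.

    The same compaction/recovery formulas are applied uniformly to CCS,
    surface area and volume.
    """
    compaction, recov = {}, {}
    for key in ("ccs", "sasa", "volume"):
        b = getattr(bulk, key)[0]
        v = getattr(vacuum, key)[0]
        r = getattr(rehydration, key)[0]
        compaction[key] = compaction_percent(b, v)
        recov[key], _ = recovery_percent(b, r)
    _, ccs_gap = recovery_percent(bulk.ccs[0], rehydration.ccs[0])
    return RecoveryReport(bulk_ref=bulk, vacuum_tail=vacuum,
                          rehydration_tail=rehydration,
                          compaction_pct=compaction, recovery_pct=recov,
                          ccs_gap=ccs_gap, contact=contact,
                          hbond_mean=hbond_mean or {},
                          tail_fraction=tail_fraction)
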
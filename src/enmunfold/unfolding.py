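"""Iterative bond-breaking simulations of thermal and force-induced unfolding.

Thermal mode: at every step the intact non-covalent contact with the
largest mean-square distance fluctuation <(dR_ij)^2> breaks, the Kirchhoff
matrix is updated and the fluctuations are recomputed on the new topology.

Force mode: a constant pulling force (unit forces along +/-x at the chain
termini by default) is applied; the contact with the largest relative
stretching |u_i - u_j| of the static displacement field breaks each step.

Backbone springs never break.  Per event the trajectory records the
fraction of native contacts Q, the mean coordination number <z>, and the
number of floppy modes f of the anisotropic Hessian on the current
topology at native geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .network import (
    ElasticNetwork,
    UnbalancedForceError,
    anm_hessian,
    floppy_count,
    force_displacements,
    pair_fluctuations,
)

__all__ = [
    "BondBreakEvent",
    "UnfoldingTrajectory",
    "RunFinished",
    "default_pulling_forces",
    "thermal_step",
    "force_step",
    "run_unfolding",
    "bond_breaking_order_per_residue",
]

#: Relative tolerance within which two criterion values count as tied;
#: ties break to the lexicographically smallest (i, j).
TIE_RTOL = 1e-9


class RunFinished(Exception):
    """No further bond can be broken (exhaustion or disconnected termini)."""


class BondBreakEvent(NamedTuple):
    step: int                 # 1-based event rank
    pair: tuple[int, int]     # broken contact, 1-based residue positions
    value: float              # criterion value (fluctuation or stretch)


@dataclass
class UnfoldingTrajectory:
    """Ordered record of one unfolding run."""

    events: list[BondBreakEvent]
    q_series: np.ndarray
    z_series: np.ndarray
    f_series: np.ndarray | None
    mode: Literal["thermal", "force"]
    n_native: int
    n_residues: int

    @property
    def n_events(self) -> int:
        return len(self.events)


def _argmax_bond(candidates: dict[tuple[int, int], float]) -> tuple[tuple[int, int], float]:
    """Largest-criterion bond; near-ties resolved lexicographically."""
    best_val = max(candidates.values())
    tol = TIE_RTOL * max(abs(best_val), 1e-300)
    tied = [p for p, v in candidates.items() if v >= best_val - tol]
    pair = min(tied)
    return pair, candidates[pair]


def thermal_step(net: ElasticNetwork, kBT: float = 1.0) -> BondBreakEvent:
    """Break the contact with the largest mean-square distance fluctuation."""
    if not net.contacts:
        raise RunFinished("no non-covalent bonds remain")
    fluct = pair_fluctuations(net, kBT=kBT)
    candidates = {
        (i, j): float(fluct[i - 1, j - 1]) for (i, j) in net.contacts
    }
    pair, value = _argmax_bond(candidates)
    net.break_bond(pair)
    return BondBreakEvent(step=len(net.broken), pair=pair, value=value)


def default_pulling_forces(n_residues: int) -> np.ndarray:
    """Unit forces along x at the termini: F_x(1) = -1, F_x(N) = +1."""
    forces = np.zeros((n_residues, 3))
    forces[0, 0] = -1.0
    forces[-1, 0] = 1.0
    return forces


def force_step(net: ElasticNetwork, forces: np.ndarray) -> BondBreakEvent:
    """Break the contact with the largest stretch |u_i - u_j| under load."""
    if not net.contacts:
        raise RunFinished("no non-covalent bonds remain")
    forces = np.asarray(forces, dtype=float)
    if np.abs(forces).max() == 0.0:
        raise ValueError("zero force field: bond stretch argmax is undefined")
    try:
        u = force_displacements(net, forces)
    except UnbalancedForceError as err:
        # Loaded residues ended up on separate fragments: no static solution.
        raise RunFinished(str(err)) from err
    candidates = {
        (i, j): float(np.linalg.norm(u[i - 1] - u[j - 1]))
        for (i, j) in net.contacts
    }
    pair, value = _argmax_bond(candidates)
    net.break_bond(pair)
    return BondBreakEvent(step=len(net.broken), pair=pair, value=value)


def run_unfolding(
    net: ElasticNetwork,
    mode: Literal["thermal", "force"] = "thermal",
    *,
    stop_after: int | None = None,
    forces: np.ndarray | None = None,
    compute_floppy: bool = True,
    floppy_threshold: float = 1e-4,
    kBT: float = 1.0,
) -> UnfoldingTrajectory:
    """Run bond breaking until ``stop_after`` events or exhaustion.

    The network is mutated in place.  Deterministic given the network and
    configuration.  ``compute_floppy=False`` skips the per-event Hessian
    eigendecomposition when the floppy-mode series is not needed.
    """
    if mode not in ("thermal", "force"):
        raise ValueError(f"unknown mode {mode!r}")
    n_native = len(net.contacts)
    n = net.n_residues
    if mode == "force" and forces is None:
        forces = default_pulling_forces(n)
    limit = n_native if stop_after is None else min(stop_after, n_native)

    events: list[BondBreakEvent] = []
    q_series, z_series, f_series = [], [], []
    for _ in range(limit):
        try:
            if mode == "thermal":
                event = thermal_step(net, kBT=kBT)
            else:
                event = force_step(net, forces)
        except RunFinished:
            break
        events.append(event)
        q_series.append(len(net.contacts) / n_native)
        z_series.append(net.mean_coordination)
        if compute_floppy:
            f_series.append(floppy_count(anm_hessian(net), floppy_threshold))
    return UnfoldingTrajectory(
        events=events,
        q_series=np.array(q_series),
        z_series=np.array(z_series),
        f_series=np.array(f_series) if compute_floppy else None,
        mode=mode,
        n_native=n_native,
        n_residues=n,
    )


def bond_breaking_order_per_residue(traj: UnfoldingTrajectory) -> np.ndarray:
    """Mean 1-based event rank of each residue's broken bonds.

    Residues that take part in no breaking event get NaN and are excluded
    from downstream correlations.
    """
    total = np.zeros(traj.n_residues)
    count = np.zeros(traj.n_residues)
    for event in traj.events:
        for res in event.pair:
            total[res - 1] += event.step
            count[res - 1] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)
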
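"""Macrostates as fixed-width windows on order-parameter dihedrals.

Snapshots are projected onto a chosen dihedral whose 360-degree range is cut
into equal half-open windows (18 degrees by default, 20 windows per order
parameter).  The snapshots falling in one window constitute an observed
macrostate.  Windows from the same order parameter are disjoint and cover
the trajectory; windows from different order parameters may overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discretize import (
    ConformerDefinition,
    DihedralTrajectory,
    assign_torsional_states,
    count_unique,
    encode_conformers,
)

__all__ = ["MacrostateSelector", "MacrostateSet", "build_macrostates",
           "count_conformers_per_macrostate", "nested_subsets"]


@dataclass(frozen=True)
class MacrostateSelector:
    """One half-open window [lo, hi) on one order-parameter torsion."""

    order_param: int
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("window must satisfy lo < hi")

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class MacrostateSet:
    """Macrostates of one trajectory: selectors, memberships and counts.

    ``membership[k]`` holds the snapshot indices of selector ``k``; empty
    windows are retained (flagged unobserved) so the window grid stays
    complete, but they are excluded from pairwise free-energy analyses.
    ``conformer_counts[name]`` stores N_conf per macrostate for one
    conformer definition (NaN where unobserved).
    """

    selectors: list
    membership: list
    n_snapshots: int
    conformer_counts: dict = field(default_factory=dict)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.membership], dtype=np.int64)

    @property
    def observed(self) -> np.ndarray:
        return self.counts > 0

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(self.observed))

    def __len__(self) -> int:
        return len(self.selectors)


def build_macrostates(traj: DihedralTrajectory, order_params, window_width: float = 18.0) -> MacrostateSet:
    """Partition the trajectory into windows per order-parameter dihedral.

    ``order_params`` are 0-based torsion column indices.  ``window_width``
    must divide 360 evenly; windows are anchored at -180 degrees, giving
    e.g. [-180,-162), ..., [162,180) for the default 18-degree width.
    Every snapshot lands in exactly one window per order parameter.
    """
    if not float(window_width) > 0 or 360.0 % float(window_width) != 0.0:
        raise ValueError("window width must evenly divide 360 degrees")
    n_windows = int(round(360.0 / window_width))
    order_params = [int(p) for p in order_params]
    for p in order_params:
        if not 0 <= p < traj.n_torsions:
            raise IndexError(f"order parameter index {p} outside trajectory")

    selectors: list = []
    membership: list = []
    for p in order_params:
        ang = traj.angles[:, p]
        # canonical range is (-180, 180]; put +180 in the last window's [.., 180) slot
        # by treating it as its circle-equivalent -180 (left edge of window 0)
        rel = np.mod(ang + 180.0, 360.0)
        win = np.minimum((rel / window_width).astype(np.int64), n_windows - 1)
        for w in range(n_windows):
            lo = -180.0 + w * window_width
            selectors.append(MacrostateSelector(order_param=p, lo=lo, hi=lo + window_width))
            membership.append(np.flatnonzero(win == w))
    return MacrostateSet(selectors=selectors, membership=membership, n_snapshots=traj.n_snapshots)


def count_conformers_per_macrostate(mset: MacrostateSet, traj: DihedralTrajectory,
                                    conf_def: ConformerDefinition) -> MacrostateSet:
    """Fill ``mset.conformer_counts[conf_def.name]`` with per-macrostate N_conf.

    N_conf is the number of distinct conformer ids among a macrostate's
    member snapshots (non-empty bins of the 3**m id space).  Unobserved
    macrostates get NaN.
    """
    states = assign_torsional_states(traj, conf_def.boundaries)
    ids = encode_conformers(states, conf_def)
    n_conf = np.full(len(mset), np.nan)
    for k, members in enumerate(mset.membership):
        if len(members) > 0:
            n_conf[k] = count_unique(ids[members])
    mset.conformer_counts[conf_def.name] = n_conf
    return mset


def nested_subsets(traj: DihedralTrajectory, fractions) -> list:
    """Time-ordered prefix subsets of the trajectory, one per fraction.

    Fractions must be strictly increasing and lie in (0, 1]; subset k is a
    prefix of subset k+1, mirroring nested trajectory-set constructions.
    """
    fr = [float(f) for f in fractions]
    if len(fr) == 0:
        raise ValueError("at least one fraction is required")
    if any(not 0.0 < f <= 1.0 for f in fr):
        raise ValueError("fractions must lie in (0, 1]")
    if any(b <= a for a, b in zip(fr, fr[1:])):
        raise ValueError("fractions must be strictly increasing")
    out = []
    for f in fr:
        m = int(np.floor(f * traj.n_snapshots))
        if m < 1:
            raise ValueError(f"fraction {f} selects an empty prefix")
        out.append(traj.subset_rows(np.arange(m), source_suffix=f"[:{m}]"))
    return out
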
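"""Torsional-state discretization of dihedral trajectories.

A molecular configuration is reduced to the vector of its dihedral (torsion)
angles.  Each torsion's 360-degree range is partitioned into three arcs
("torsional states", the rotameric gauche-/anti/gauche+ trisection by
default), and a *conformer* is the joint assignment of torsional states over
a chosen subset of torsions.  Two snapshots belong to the same conformer iff
they share the torsional state of every selected torsion.  Conformers are
explicit, non-overlapping and configurational-space-filling: every snapshot
maps to exactly one conformer.

Conformer identifiers are mixed-radix base-3 integers over the ordered
torsion subset (least significant digit first).  For subsets of up to 39
torsions the id fits an int64; larger subsets (3**43 exceeds 64 bits) fall
back to arbitrary-precision Python integers.  Counting distinct conformers
is a sort + run-count, never a materialization of the 3**m id space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DihedralTrajectory",
    "TorsionStateBoundaries",
    "ConformerDefinition",
    "wrap_angle",
    "assign_torsional_states",
    "encode_conformers",
    "count_unique",
]

#: largest subset size whose base-3 id fits a signed 64-bit integer (3**39 < 2**63)
_MAX_INT64_TORSIONS = 39


def wrap_angle(angle):
    """Wrap angle(s) in degrees onto the canonical range (-180, 180].

    -180 is identified with +180 so every angle has a single representative.
    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite angle encountered")
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    # map -180 -> 180 (mod puts -180 at -180 through the sign trick; be explicit)
    wrapped = np.where(wrapped <= -180.0, wrapped + 360.0, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass
class DihedralTrajectory:
    """Per-snapshot torsion angles, optionally with potential energies.

    Parameters
    ----------
    angles : ndarray, shape (n_snapshots, n_torsions)
        Dihedral angles in degrees; wrapped to (-180, 180] on construction.
    torsion_labels : sequence of str, optional
        Unique names, default ``t1..tD`` (1-based, matching the common
        numbering of torsion tables).
    energies : ndarray, shape (n_snapshots,), optional
        Potential energy per snapshot in kT units.
    source : str
        Provenance note (file path, synthetic-system spec, ...).
    """

    angles: np.ndarray
    torsion_labels: tuple = None
    energies: np.ndarray = None
    source: str = ""

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 2:
            raise ValueError("angles must be a 2-D (n_snapshots, n_torsions) array")
        if a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError("trajectory needs at least one snapshot and one torsion")
        self.angles = wrap_angle(a)
        if self.torsion_labels is None:
            self.torsion_labels = tuple(f"t{i + 1}" for i in range(a.shape[1]))
        else:
            self.torsion_labels = tuple(str(x) for x in self.torsion_labels)
            if len(self.torsion_labels) != a.shape[1]:
                raise ValueError("number of labels does not match number of torsions")
            if len(set(self.torsion_labels)) != len(self.torsion_labels):
                raise ValueError("torsion labels must be unique")
        if self.energies is not None:
            e = np.asarray(self.energies, dtype=float)
            if e.shape != (a.shape[0],):
                raise ValueError("energies must be one value per snapshot")
            self.energies = e

    @property
    def n_snapshots(self) -> int:
        return self.angles.shape[0]

    @property
    def n_torsions(self) -> int:
        return self.angles.shape[1]

    def subset_rows(self, index: np.ndarray, source_suffix: str = "") -> "DihedralTrajectory":
        """Trajectory restricted to the given snapshot indices (order kept)."""
        e = None if self.energies is None else self.energies[index]
        return DihedralTrajectory(
            self.angles[index],
            torsion_labels=self.torsion_labels,
            energies=e,
            source=self.source + source_suffix,
        )


@dataclass(frozen=True)
class TorsionStateBoundaries:
    """Three cuts partitioning the circle into three half-open arcs.

    Arc ``k`` is ``[cut_k, cut_{k+1})`` with periodic wrap-around; the left
    edge belongs to the arc.  Cuts must be strictly increasing within
    (-180, 180].  The default trisection ``(-180, -60, 60)`` gives the arcs
    [-180,-60), [-60,60), [60,180).
    """

    cuts: tuple = (-180.0, -60.0, 60.0)

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        if len(cuts) != 3:
            raise ValueError("exactly three cuts are required for three torsional states")
        if not all(-180.0 < c <= 180.0 or c == -180.0 for c in cuts):
            # allow -180 as a cut (identified with +180 on the circle)
            raise ValueError("cuts must lie in [-180, 180]")
        if not (cuts[0] < cuts[1] < cuts[2]):
            raise ValueError("cuts must be strictly increasing")
        object.__setattr__(self, "cuts", cuts)

    def shifted(self, degrees: float) -> "TorsionStateBoundaries":
        """Boundaries rotated by ``degrees``, re-sorted into increasing order."""
        moved = sorted(wrap_angle(np.asarray(self.cuts) + degrees).tolist())
        return TorsionStateBoundaries(tuple(moved))


@dataclass(frozen=True)
class ConformerDefinition:
    """A named conformer discretization: torsion subset + state boundaries.

    ``torsion_subset`` holds 0-based column indices into the trajectory's
    angle matrix, in a fixed order (the order defines the mixed-radix
    encoding).  The total number of possible conformers is ``3**len(subset)``
    and is never materialized.
    """

    name: str
    torsion_subset: tuple
    boundaries: TorsionStateBoundaries = field(default_factory=TorsionStateBoundaries)
    n_states_per_torsion: int = 3

    def __post_init__(self):
        subset = tuple(int(i) for i in self.torsion_subset)
        if len(subset) == 0:
            raise ValueError("torsion subset must be non-empty")
        if len(set(subset)) != len(subset):
            raise ValueError("torsion subset contains duplicates")
        if any(i < 0 for i in subset):
            raise ValueError("torsion indices are 0-based and non-negative")
        if self.n_states_per_torsion != 3:
            raise ValueError("three torsional states per torsion are required")
        object.__setattr__(self, "torsion_subset", subset)

    @property
    def n_torsions(self) -> int:
        return len(self.torsion_subset)

    @property
    def n_possible_conformers(self) -> int:
        return 3 ** len(self.torsion_subset)


def assign_torsional_states(traj, boundaries: TorsionStateBoundaries = None) -> np.ndarray:
    """Map every (snapshot, torsion) angle to its torsional state 0/1/2.

    ``traj`` may be a :class:`DihedralTrajectory` or a plain angle array.
    States are numbered in boundary order; an angle exactly on a cut belongs
    to the arc whose left edge it is.  Assignment depends only on the wrapped
    angle and the boundaries.
    """
    if boundaries is None:
        boundaries = TorsionStateBoundaries()
    angles = traj.angles if isinstance(traj, DihedralTrajectory) else wrap_angle(np.asarray(traj, dtype=float))
    c0, c1, c2 = boundaries.cuts
    # rotate so arc 0 starts at 0, then state = floor over the two remaining cuts
    rel = np.mod(angles - c0, 360.0)
    r1 = (c1 - c0) % 360.0
    r2 = (c2 - c0) % 360.0
    states = np.zeros(np.shape(rel), dtype=np.uint8)
    states[rel >= r1] = 1
    states[rel >= r2] = 2
    return states


def encode_conformers(states: np.ndarray, conf_def: ConformerDefinition) -> np.ndarray:
    """Encode torsional-state rows as mixed-radix base-3 conformer ids.

    ``id = sum_j state[:, subset[j]] * 3**j`` (least significant digit first
    over the ordered subset).  Returns an int64 vector for subsets of up to
    39 torsions, otherwise an object array of Python integers.  Two snapshots
    share an id iff they share the torsional state of every subset torsion.
    """
    states = np.asarray(states)
    if states.ndim != 2:
        raise ValueError("state matrix must be 2-D")
    m = states.shape[1]
    for idx in conf_def.torsion_subset:
        if idx >= m:
            raise IndexError(f"torsion index {idx} missing from state matrix with {m} columns")
    cols = states[:, list(conf_def.torsion_subset)]
    k = cols.shape[1]
    if k <= _MAX_INT64_TORSIONS:
        radix = 3 ** np.arange(k, dtype=np.int64)
        return cols.astype(np.int64) @ radix
    # arbitrary precision path for very large subsets (3**43 > 2**63)
    radix_py = [3**j for j in range(k)]
    out = np.empty(cols.shape[0], dtype=object)
    for i, row in enumerate(cols):
        out[i] = sum(int(s) * r for s, r in zip(row, radix_py))
    return out


def decode_conformer_id(conformer_id, n_torsions: int) -> tuple:
    """Inverse of :func:`encode_conformers` for a single id."""
    cid = int(conformer_id)
    digits = []
    for _ in range(n_torsions):
        digits.append(cid % 3)
        cid //= 3
    if cid != 0:
        raise ValueError("id out of range for the given subset size")
    return tuple(digits)


def count_unique(ids: np.ndarray) -> int:
    """Number of distinct conformer ids (sort + run-count; order independent)."""
    ids = np.asarray(ids)
    if ids.size == 0:
        raise ValueError("cannot count conformers of an empty id vector")
    if ids.dtype == object:
        srt = sorted(ids.tolist())
        return 1 + sum(a != b for a, b in zip(srt, srt[1:]))
    srt = np.sort(ids)
    return int(1 + np.count_nonzero(np.diff(srt)))


def unique_counts(ids: np.ndarray):
    """Distinct ids and their multiplicities (sorted by id)."""
    ids = np.asarray(ids)
    if ids.size == 0:
        raise ValueError("cannot tally an empty id vector")
    if ids.dtype == object:
        from collections import Counter

        tally = Counter(ids.tolist())
        keys = sorted(tally)
        return np.array(keys, dtype=object), np.array([tally[k] for k in keys], dtype=np.int64)
    return np.unique(ids, return_counts=True)
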
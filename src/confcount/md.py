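"""Optional adapter: extract dihedral time series from MD trajectory files.

The core of the package consumes dihedral tables only; this thin adapter
turns an XTC/DCD/PDB trajectory plus a topology into a
:class:`~confcount.discretize.DihedralTrajectory` using mdtraj.  The adapter
is optional — importing it without mdtraj installed raises a clear error,
and nothing else in the package depends on it.
"""

from __future__ import annotations

import numpy as np

from .discretize import DihedralTrajectory

__all__ = ["extract_dihedrals_from_md", "dihedral_from_positions"]


def dihedral_from_positions(p0, p1, p2, p3) -> np.ndarray:
    """Standard dihedral angle (degrees, (-180, 180]) from four points.

    Sign convention: looking down the p1->p2 bond, a clockwise rotation of
    the p2-p3 bond relative to p0-p1 is positive (IUPAC); a planar cis
    arrangement gives 0 and trans gives 180.  Accepts (..., 3) stacks.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    from .discretize import wrap_angle

    return wrap_angle(ang)


def extract_dihedrals_from_md(trajectory_file, topology_file, torsion_atoms,
                              labels=None) -> DihedralTrajectory:
    """Compute per-frame dihedrals for named atom quadruples via mdtraj.

    ``torsion_atoms`` is a sequence of 4-tuples of atom names (or integer
    atom indices); missing atoms raise ``KeyError`` naming the offender.
    """
    try:
        import mdtraj as md
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "the MD adapter requires mdtraj (install the 'md' extra); the core "
            "package reads dihedral tables without it"
        ) from exc

    traj = md.load(str(trajectory_file), top=str(topology_file))
    quadruples = []
    for quad in torsion_atoms:
        if len(quad) != 4:
            raise ValueError(f"torsion spec {quad!r} must name exactly four atoms")
        idx = []
        for a in quad:
            if isinstance(a, (int, np.integer)):
                idx.append(int(a))
            else:
                found = [at.index for at in traj.topology.atoms if at.name == str(a)]
                if len(found) != 1:
                    raise KeyError(
                        f"atom name {a!r} matched {len(found)} atoms in the topology")
                idx.append(found[0])
        quadruples.append(idx)
    angles = np.degrees(md.compute_dihedrals(traj, np.array(quadruples)))
    return DihedralTrajectory(
        angles,
        torsion_labels=labels,
        source=f"{trajectory_file}+{topology_file}",
    )
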
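"""Reading and writing dihedral tables, configs and result tables.

The universal on-disk input is a delimited text table (TSV or CSV) whose
header names the torsions; an optional ``energy`` column carries per-snapshot
potential energies in kT.  Lines starting with ``#`` are provenance comments
and are ignored on read.  Result tables are TSV with a ``#`` provenance
header (config hash, seed) so every output is traceable to its run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discretize import ConformerDefinition, DihedralTrajectory, TorsionStateBoundaries

__all__ = ["read_dihedral_table", "write_dihedral_table", "RunConfig",
           "conformer_definitions_from_config", "write_table", "read_table"]

ENERGY_COLUMN = "energy"


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_dihedral_table(path) -> DihedralTrajectory:
    """Read a dihedral table (header row = torsion labels, optional energy).

    Angles are wrapped to (-180, 180].  Non-numeric cells are reported with
    their 1-based line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter_for(path)
    try:
        raw = pd.read_csv(path, sep=sep, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file (a header row naming torsions is required)")
    if raw.shape[1] < 1 or raw.shape[0] < 1:
        raise ValueError(f"{path}: need a header row and at least one data row")
    if any(c.replace(".", "", 1).replace("-", "", 1).isdigit() for c in raw.columns):
        raise ValueError(f"{path}: header row appears to contain data, not torsion labels")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} in column "
            f"{raw.columns[c]!r} at data line {r + 2}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value in column {raw.columns[c]!r} at data line {r + 2}")
    energies = None
    if ENERGY_COLUMN in numeric.columns:
        energies = numeric.pop(ENERGY_COLUMN).to_numpy()
    return DihedralTrajectory(
        numeric.to_numpy(dtype=float),
        torsion_labels=tuple(numeric.columns),
        energies=energies,
        source=str(path),
    )


def write_dihedral_table(traj: DihedralTrajectory, path, provenance: dict = None) -> None:
    """Write a trajectory as a delimited table (energy column if present)."""
    path = Path(path)
    sep = _delimiter_for(path)
    df = pd.DataFrame(traj.angles, columns=list(traj.torsion_labels))
    if traj.energies is not None:
        df[ENERGY_COLUMN] = traj.energies
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line)
        df.to_csv(fh, sep=sep, index=False, float_format="%.10g")


def _provenance_lines(provenance: dict = None):
    if not provenance:
        return []
    return [f"# {k}: {v}\n" for k, v in provenance.items()]


def write_table(df: pd.DataFrame, path, provenance: dict = None) -> None:
    """Write a result table as TSV with a '#' provenance header."""
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Validated run configuration, serializable to YAML for provenance.

    ``conformer_defs`` entries are mappings with keys ``name``, ``torsions``
    (1-based indices, matching the conventional torsion-table numbering) and
    optional ``cuts`` (three boundary angles in degrees).  ``order_params``
    are 1-based torsion indices; ``input`` is a table path or a synthetic
    system name.
    """

    input: str
    output_dir: str = "."
    conformer_defs: list = field(default_factory=list)
    order_params: list = None
    window_width: float = 18.0
    fractions: list = field(default_factory=lambda: [0.1, 0.5, 1.0])
    seed: int = 0

    def __post_init__(self):
        if 360.0 % float(self.window_width) != 0.0:
            raise ValueError("window width must evenly divide 360")
        for f in self.fractions:
            if not 0.0 < float(f) <= 1.0:
                raise ValueError("subset fractions must lie in (0, 1]")
        if list(self.fractions) != sorted(set(map(float, self.fractions))):
            raise ValueError("subset fractions must be strictly increasing")
        for cd in self.conformer_defs:
            if "name" not in cd or "torsions" not in cd:
                raise ValueError("each conformer definition needs 'name' and 'torsions'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed}


def conformer_definitions_from_config(entries, n_torsions: int) -> list:
    """Build :class:`ConformerDefinition` objects from config mappings.

    Config torsion indices are 1-based (table numbering); internal indices
    are 0-based columns of the trajectory.
    """
    defs = []
    for entry in entries:
        torsions = [int(t) for t in entry["torsions"]]
        if any(not 1 <= t <= n_torsions for t in torsions):
            raise ValueError(
                f"conformer definition {entry['name']!r}: torsion indices are 1-based "
                f"and must lie in 1..{n_torsions}"
            )
        cuts = entry.get("cuts")
        boundaries = TorsionStateBoundaries(tuple(cuts)) if cuts else TorsionStateBoundaries()
        defs.append(ConformerDefinition(
            name=str(entry["name"]),
            torsion_subset=tuple(t - 1 for t in torsions),
            boundaries=boundaries,
        ))
    return defs
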
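"""Conformational entropy over conformer weights and its Boltzmann/KL split.

For a macrostate whose member snapshots occupy N_conf conformers with
normalized weights P_i (snapshot fractions), the conformational entropy in
units of k is the Shannon entropy

    S_conf = -sum_i P_i ln P_i = ln N_conf - D_KL(P || uniform),

so S_conf splits exactly into the Boltzmann (ideal-gas) term k ln N_conf and
minus k times the Kullback-Leibler divergence of the observed weights from
the uniform distribution over occupied conformers.  The per-pair statistic

    δΔS = ΔS_conf - ΔS_Boltz = -ΔD_KL    (k units, T = 1)

mirrors δΔF: when conformer weights carry the same distribution everywhere
(ISWD) the KL terms cancel between macrostates and the entropy change is
pure conformer counting — the count-based entropy change equals minus the
conformer-count free-energy change at T = 1.

Exact bookkeeping on snapshot multiplicities: writing c = sum_i P_i ln n_i
(the snapshot-level intra-conformer entropy of a macrostate),

    δΔF = -δΔS - Δc,

so δΔF = -T δΔS holds exactly whenever Δc = 0 (e.g. every occupied conformer
holds one snapshot, or the multiplicity profile is shared).  On enumerable
synthetic systems the full decomposition S_total = S_conf + <S_intra> is
available microstate-exactly (see :mod:`confcount.synthetic`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import assign_torsional_states, encode_conformers, unique_counts
from .macrostates import MacrostateSet

__all__ = ["conformer_weights", "conformational_entropy", "kl_to_uniform",
           "macrostate_entropy_table", "pairwise_ddS", "EECReport"]

_NORM_TOL = 1e-9


def conformer_weights(member_ids) -> np.ndarray:
    """Normalized conformer weights P_i within one macrostate.

    ``member_ids`` are the conformer ids of the macrostate's member
    snapshots; P_i is the fraction of snapshots in conformer i.
    """
    ids = np.asarray(member_ids)
    if ids.size == 0:
        raise ValueError("conformer weights of an empty macrostate are undefined")
    _, counts = unique_counts(ids)
    return counts / counts.sum()


def _check_normalized(p: np.ndarray):
    if p.size == 0:
        raise ValueError("empty weight vector")
    if np.any(p < 0):
        raise ValueError("weights must be non-negative")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"weights sum to {p.sum():.12f}, not 1 within {_NORM_TOL}")


def conformational_entropy(p) -> float:
    """Shannon entropy -sum p ln p in k units (0 for a single conformer).

    Zero-probability entries contribute 0 via the p ln p -> 0 limit; the
    entropy is computed over the occupied support.
    """
    p = np.asarray(p, dtype=float)
    _check_normalized(p)
    q = p[p > 0]
    return float(-np.sum(q * np.log(q)))


def kl_to_uniform(p) -> float:
    """D_KL(P || uniform over the vector's support), in nats.

    The reference is uniform over the N entries of ``p`` (occupied
    conformers); satisfies S_conf = ln N - D_KL exactly and D_KL >= 0 with
    equality iff uniform.
    """
    p = np.asarray(p, dtype=float)
    _check_normalized(p)
    n = p.size
    q = p[p > 0]
    return float(np.sum(q * np.log(q * n)))


def macrostate_entropy_table(mset: MacrostateSet, traj, conf_def) -> pd.DataFrame:
    """Per observed macrostate: N_snap, N_conf, S_conf, S_Boltz, D_KL, mean_U.

    S_conf/S_Boltz in k units, D_KL in nats; mean_U (kT) is NaN when the
    trajectory carries no energies.  The snapshot-multiplicity term
    mean_ln_mult = sum_i P_i ln n_i is included: it is the snapshot-level
    intra-conformer entropy that closes the δΔF/δΔS bookkeeping.
    """
    states = assign_torsional_states(traj, conf_def.boundaries)
    ids = encode_conformers(states, conf_def)
    rows = []
    for k, members in enumerate(mset.membership):
        if len(members) == 0:
            continue
        _, counts = unique_counts(ids[members])
        p = counts / counts.sum()
        s_conf = conformational_entropy(p)
        n_conf = p.size
        mean_u = float(np.mean(traj.energies[members])) if traj.energies is not None else np.nan
        rows.append({
            "macrostate": k,
            "n_snap": int(len(members)),
            "n_conf": int(n_conf),
            "S_conf": s_conf,
            "S_Boltz": float(np.log(n_conf)),
            "D_KL": float(np.log(n_conf)) - s_conf,
            "mean_ln_mult": float(np.sum(p * np.log(counts))),
            "mean_U": mean_u,
        })
    return pd.DataFrame(rows)


def pairwise_ddS(mset: MacrostateSet, traj, conf_def) -> pd.DataFrame:
    """Per-pair ΔS_conf, ΔS_Boltz and δΔS over observed macrostates (k units).

    δΔS = ΔS_conf - ΔS_Boltz = -ΔD_KL; pair orientation matches
    :func:`confcount.free_energy.pairwise_ddF` (lower index j = start state,
    higher index i = end state), M(M-1)/2 rows.
    """
    ent = macrostate_entropy_table(mset, traj, conf_def)
    if len(ent) < 2:
        raise ValueError("pairwise analysis needs at least two observed macrostates")
    s_conf = ent["S_conf"].to_numpy()
    s_boltz = ent["S_Boltz"].to_numpy()
    idx = ent["macrostate"].to_numpy()
    j_idx, i_idx = np.triu_indices(len(ent), k=1)
    d_conf = s_conf[i_idx] - s_conf[j_idx]
    d_boltz = s_boltz[i_idx] - s_boltz[j_idx]
    return pd.DataFrame({
        "macrostate_i": idx[i_idx],
        "macrostate_j": idx[j_idx],
        "dS_conf": d_conf,
        "dS_Boltz": d_boltz,
        "ddS": d_conf - d_boltz,
    })


@dataclass
class EECReport:
    """Entropy-enthalpy compensation bookkeeping for one macrostate pair.

    All terms in kT units with T = 1 (entropies in k times T).  The
    thermodynamic identity ΔF = ΔU - TΔS_total holds exactly on enumerable
    systems; the EEC residual ΔU - TΔ<S_intra> - T(ΔS_conf - ΔS_Boltz)
    equals ΔF - ΔF_conf and vanishes for exact-ISWD constructions, where the
    enthalpy change is cancelled by the intra-conformer entropy change.
    """

    dU: float
    dS_intra: float
    dS_conf: float
    dS_Boltz: float
    dF_exact: float
    dF_conf: float

    @property
    def dS_total(self) -> float:
        return self.dS_intra + self.dS_conf

    @property
    def closure(self) -> float:
        """ΔF - (ΔU - TΔS_total); zero to numerical precision by construction."""
        return self.dF_exact - (self.dU - self.dS_total)

    @property
    def residual(self) -> float:
        """EEC residual ΔU - TΔ<S_intra> - T(ΔS_conf - ΔS_Boltz) = ΔF - ΔF_conf."""
        return self.dU - self.dS_intra - (self.dS_conf - self.dS_Boltz)
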
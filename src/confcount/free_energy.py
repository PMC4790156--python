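"""Snapshot-count and conformer-count free energies and the δΔF diagnostic.

Two estimators of the free-energy difference between observed macrostates A
and B (everything in kT units, β = 1):

* population based:      ΔF_snap = -ln(N_snap_B / N_snap_A)
* conformer-count based: ΔF_conf = -ln(N_conf_B / N_conf_A)

The second is exact when the thermally accessible conformers have an
invariant statistical weight distribution (ISWD) across configurational
space, so the per-pair difference δΔF = ΔF_snap - ΔF_conf diagnoses how far
a conformer definition is from ISWD.  Summaries follow the cumulative
probability distribution (CPD) of |δΔF| and its area under the curve (AUC):
larger AUC means smaller deviations.  The -ln N_snap vs -ln N_conf scatter
with its least-squares fit is the scaling diagnostic (identity line = ISWD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discretize import ConformerDefinition, DihedralTrajectory
from .macrostates import MacrostateSet, build_macrostates, count_conformers_per_macrostate, nested_subsets

__all__ = ["delta_F_snap", "delta_F_conf", "pairwise_ddF", "cpd", "CPDCurve",
           "scaling_data", "ScalingFit", "convergence_trend"]


class UndefinedFreeEnergyError(ValueError):
    """Raised when a macrostate has zero counts, so -kT ln(N_B/N_A) is undefined."""


def _check_counts(n_a, n_b, what: str):
    if n_a < 1 or n_b < 1 or not np.isfinite(n_a) or not np.isfinite(n_b):
        empty = "A" if (not np.isfinite(n_a) or n_a < 1) else "B"
        raise UndefinedFreeEnergyError(
            f"free energy undefined: macrostate {empty} has no observed {what}"
        )


def delta_F_snap(n_snap_A, n_snap_B) -> float:
    """ΔF(A→B) = -ln(N_snap_B / N_snap_A) in kT; requires both counts >= 1."""
    _check_counts(n_snap_A, n_snap_B, "snapshots")
    return float(-np.log(n_snap_B / n_snap_A))


def delta_F_conf(n_conf_A, n_conf_B) -> float:
    """ΔF(A→B) = -ln(N_conf_B / N_conf_A) in kT; requires both counts >= 1."""
    _check_counts(n_conf_A, n_conf_B, "conformers")
    return float(-np.log(n_conf_B / n_conf_A))


def pairwise_ddF(mset: MacrostateSet, conf_name: str) -> pd.DataFrame:
    """Per-pair ΔF_snap, ΔF_conf and δΔF over all observed macrostate pairs.

    Pairs are oriented (lower original index = start state j, higher = end
    state i), one row per unordered pair, M(M-1)/2 rows for M observed
    macrostates.  ``conf_name`` selects a conformer definition whose counts
    were filled by :func:`~confcount.macrostates.count_conformers_per_macrostate`.
    """
    if conf_name not in mset.conformer_counts:
        raise KeyError(f"no conformer counts stored under {conf_name!r}")
    obs = np.flatnonzero(mset.observed)
    if obs.size < 2:
        raise ValueError("pairwise analysis needs at least two observed macrostates")
    n_snap = mset.counts[obs].astype(float)
    n_conf = mset.conformer_counts[conf_name][obs]
    f_snap = -np.log(n_snap)          # per-macrostate -ln N (unnormalized)
    f_conf = -np.log(n_conf)
    j_idx, i_idx = np.triu_indices(obs.size, k=1)
    # orientation j -> i with i the higher original index
    d_snap = f_snap[i_idx] - f_snap[j_idx]
    d_conf = f_conf[i_idx] - f_conf[j_idx]
    return pd.DataFrame(
        {
            "macrostate_i": obs[i_idx],
            "macrostate_j": obs[j_idx],
            "dF_snap": d_snap,
            "dF_conf": d_conf,
            "ddF": d_snap - d_conf,
        }
    )


@dataclass
class CPDCurve:
    """Empirical cumulative probability distribution of absolute values."""

    x: np.ndarray          # sorted distinct |values|
    cum_prob: np.ndarray   # P(|v| <= x), non-decreasing, ends at 1
    auc: float             # integral of the step CDF over [0, x_max]
    x_max: float

    def evaluate(self, q) -> np.ndarray:
        """CDF value(s) at q (right-continuous step function)."""
        padded = np.concatenate(([0.0], self.cum_prob))
        return np.take(padded, np.searchsorted(self.x, np.asarray(q, dtype=float), side="right"))


def _step_cdf_auc(xs: np.ndarray, probs: np.ndarray, x_max: float) -> float:
    """Exact integral over [0, x_max] of the right-continuous ECDF step function."""
    area = 0.0
    prev_x = 0.0
    prev_p = 0.0
    for x, p in zip(xs, probs):
        if x > x_max:
            break
        area += (x - prev_x) * prev_p
        prev_x, prev_p = x, p
    area += (x_max - prev_x) * prev_p
    return area


def cpd(values, x_max: float = None) -> CPDCurve:
    """CPD of |values| with its AUC over [0, x_max].

    ``x_max`` defaults to max|values| but should be fixed by the caller when
    several curves are compared, so their AUCs share an abscissa range.
    Larger AUC means the mass of |values| sits closer to zero.
    """
    v = np.abs(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cpd of an empty value list")
    xs, counts = np.unique(v, return_counts=True)
    probs = np.cumsum(counts) / v.size
    if x_max is None:
        x_max = float(xs[-1])
    if x_max < 0:
        raise ValueError("x_max must be non-negative")
    auc = _step_cdf_auc(xs, probs, float(x_max))
    return CPDCurve(x=xs, cum_prob=probs, auc=float(auc), x_max=float(x_max))


@dataclass
class ScalingFit:
    """-ln N_snap vs -ln N_conf points (normalized) and their OLS fit."""

    x: np.ndarray  # -ln(N_snap / sum N_snap) per observed macrostate
    y: np.ndarray  # -ln(N_conf / sum N_conf)
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


def scaling_data(mset: MacrostateSet, conf_name: str) -> ScalingFit:
    """Scaling diagnostic: -ln N_snap vs -ln N_conf with a linear fit.

    Counts are normalized within each order-parameter family (each family's
    windows partition the trajectory) so points from different order
    parameters share a scale.  Under ISWD the points fall on the identity
    line: slope 1, intercept 0, r² = 1.
    """
    if conf_name not in mset.conformer_counts:
        raise KeyError(f"no conformer counts stored under {conf_name!r}")
    obs = np.flatnonzero(mset.observed)
    if obs.size < 3:
        raise ValueError("scaling fit needs at least three observed macrostates")
    counts = mset.counts.astype(float)
    n_conf = mset.conformer_counts[conf_name]
    params = np.array([s.order_param for s in mset.selectors])
    xs, ys = [], []
    for p in np.unique(params):
        fam = np.flatnonzero((params == p) & mset.observed)
        tot_snap = counts[fam].sum()
        tot_conf = n_conf[fam].sum()
        xs.append(-np.log(counts[fam] / tot_snap))
        ys.append(-np.log(n_conf[fam] / tot_conf))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return ScalingFit(x=x, y=y, slope=np.nan, intercept=np.nan,
                          r_squared=np.nan, degenerate=True)
    fit = stats.linregress(x, y)
    return ScalingFit(x=x, y=y, slope=float(fit.slope), intercept=float(fit.intercept),
                      r_squared=float(fit.rvalue**2))


def convergence_trend(traj: DihedralTrajectory, conf_defs, fractions,
                      order_params=None, window_width: float = 18.0) -> pd.DataFrame:
    """|δΔF| CPD-AUC across nested trajectory subsets, per conformer definition.

    For each prefix subset the macrostates are rebuilt and the |δΔF| AUC is
    computed over an abscissa range shared across all subsets and
    definitions.  A definition whose AUC grows with subset size behaves like
    ISWD ("shrinking" deviations); a decreasing AUC marks a definition whose
    weight distribution varies across configurational space ("broadening").

    Returns a tidy frame with columns (conf_def, fraction, n_snapshots,
    n_pairs, auc, classification); the classification is repeated on each of
    a definition's rows.
    """
    if isinstance(conf_defs, ConformerDefinition):
        conf_defs = [conf_defs]
    fractions = list(fractions)
    if len(fractions) < 2:
        raise ValueError("convergence trend needs at least two subset fractions")
    if order_params is None:
        order_params = range(traj.n_torsions)
    subsets = nested_subsets(traj, fractions)

    ddf: dict = {}
    for sub, frac in zip(subsets, fractions):
        mset = build_macrostates(sub, order_params, window_width)
        for cd in conf_defs:
            count_conformers_per_macrostate(mset, sub, cd)
            ddf[(cd.name, frac)] = pairwise_ddF(mset, cd.name)

    x_max = max(float(np.max(np.abs(t["ddF"]))) for t in ddf.values())
    rows = []
    for cd in conf_defs:
        aucs = []
        for frac in fractions:
            table = ddf[(cd.name, frac)]
            curve = cpd(table["ddF"].to_numpy(), x_max=x_max)
            aucs.append(curve.auc)
            rows.append({"conf_def": cd.name, "fraction": frac,
                         "n_snapshots": int(np.floor(frac * traj.n_snapshots)),
                         "n_pairs": len(table), "auc": curve.auc})
        diffs = np.diff(aucs)
        if np.all(diffs >= 0):
            label = "shrinking"
        elif np.all(diffs <= 0):
            label = "broadening"
        else:
            label = "mixed"
        for r in rows[-len(fractions):]:
            r["classification"] = label
    return pd.DataFrame(rows)
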
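"""Exactly solvable Boltzmann systems: ground truth for every estimator.

Three families, all with energies in kT (beta = 1) and all deterministic
given an integer seed:

* :class:`DoubleWellSpec` — a 1-D piecewise-constant double well (two flat
  wells of equal width separated by a barrier).  The classic counterexample:
  a uniform discretization of the coordinate can never have an invariant
  statistical weight distribution once the wells differ in depth, so the
  conformer-count free energy misses the population free energy by exactly
  the well-depth gap.

* :class:`TorsionSystem` — D torsions on a periodic grid with per-torsion
  site energies and optional pairwise coupling.  Without coupling the joint
  Boltzmann distribution factorizes, so exact marginals, macrostate weights
  and the full entropy decomposition are available at any D; with coupling
  the system is enumerated outright (capped) as a brute-force oracle.

* :class:`GatedSystem` — a coupled construction with exact ISWD by design:
  the order-parameter torsion's window index selects which rotamer arcs of
  the remaining torsions are accessible, and all accessible microstates are
  iso-energetic.  Every accessible conformer then carries the same weight,
  macrostate mass is proportional to its accessible conformer count, and the
  conformer-count free energy is exact in the sampling limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .discretize import (
    ConformerDefinition,
    DihedralTrajectory,
    TorsionStateBoundaries,
    assign_torsional_states,
)
from .macrostates import MacrostateSelector

__all__ = [
    "DoubleWellSpec", "DoubleWellSamples", "sample_double_well",
    "exact_well_weights", "double_well_ddf",
    "TorsionSystem", "SampleSet", "sample_torsion_system",
    "exact_macrostate_weight", "exact_entropy_report", "ExactEntropyReport",
    "eec_check", "popc_like_system", "equal_arc_mass_system",
    "GatedSystem", "sample_gated_system",
    "EnumerationCapError", "DEFAULT_ENUMERATION_CAP",
]

DEFAULT_ENUMERATION_CAP = 10**7


class EnumerationCapError(RuntimeError):
    """Raised when a coupled system is too large to enumerate exactly."""


# --------------------------------------------------------------------------
# double well
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubleWellSpec:
    """Two flat wells of equal width separated by a flat barrier.

    Well A sits at the left edge of the domain with bottom energy 0; well B
    at the right edge with bottom energy ``delta_U`` (kT).  The region in
    between is at ``barrier_height`` (kT), which must exceed both bottoms.
    """

    delta_U: float = 2.0
    well_width: float = 0.25
    barrier_height: float = 12.0
    domain: tuple = (0.0, 1.0)

    def __post_init__(self):
        lo, hi = self.domain
        if not self.well_width > 0:
            raise ValueError("well width must be positive")
        if not hi - lo > 2 * self.well_width:
            raise ValueError("wells must be disjoint sub-intervals of the domain")
        if not self.barrier_height > max(0.0, self.delta_U):
            raise ValueError("barrier must be higher than both well bottoms")

    @property
    def well_A(self) -> tuple:
        return (self.domain[0], self.domain[0] + self.well_width)

    @property
    def well_B(self) -> tuple:
        return (self.domain[1] - self.well_width, self.domain[1])

    def energy(self, x) -> np.ndarray:
        """Piecewise-constant potential U(x) in kT."""
        x = np.asarray(x, dtype=float)
        u = np.full(x.shape, self.barrier_height)
        u[(x >= self.well_A[0]) & (x <= self.well_A[1])] = 0.0
        u[(x >= self.well_B[0]) & (x <= self.well_B[1])] = self.delta_U
        return u


@dataclass
class DoubleWellSamples:
    """Boltzmann samples from a double well with per-sample labels A/B/barrier."""

    x: np.ndarray
    labels: np.ndarray     # 'A', 'B' or 'barrier'
    energies: np.ndarray   # kT, exactly spec.energy(x)
    spec: DoubleWellSpec
    provenance: dict = field(default_factory=dict)


def exact_well_weights(spec: DoubleWellSpec) -> dict:
    """Exact Boltzmann mass of well A, well B and the barrier (normalized).

    Closed form for the piecewise-constant potential: each segment's mass is
    its length times exp(-U).
    """
    w = spec.well_width
    barrier_len = (spec.domain[1] - spec.domain[0]) - 2 * w
    m_a = w
    m_b = w * math.exp(-spec.delta_U)
    m_bar = barrier_len * math.exp(-spec.barrier_height)
    z = m_a + m_b + m_bar
    return {"A": m_a / z, "B": m_b / z, "barrier": m_bar / z}


def sample_double_well(spec: DoubleWellSpec, n: int, seed: int) -> DoubleWellSamples:
    """Draw n exact Boltzmann samples by inverse-CDF over the flat segments."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    weights = exact_well_weights(spec)
    segs = ["A", "barrier", "B"]
    bounds = {
        "A": spec.well_A,
        "barrier": (spec.well_A[1], spec.well_B[0]),
        "B": spec.well_B,
    }
    p = np.array([weights["A"], weights["barrier"], weights["B"]])
    which = rng.choice(3, size=n, p=p)
    u = rng.random(n)
    x = np.empty(n)
    labels = np.empty(n, dtype=object)
    for k, name in enumerate(segs):
        m = which == k
        lo, hi = bounds[name]
        x[m] = lo + u[m] * (hi - lo)
        labels[m] = name
    return DoubleWellSamples(
        x=x, labels=labels.astype(str), energies=spec.energy(x), spec=spec,
        provenance={"sampler": "inverse_cdf", "seed": int(seed), "n": int(n)},
    )


def double_well_ddf(samples: DoubleWellSamples, n_cells: int = 40) -> dict:
    """δΔF between the well macrostates under a uniform conformer grid on x.

    The coordinate is cut into ``n_cells`` equal cells (the "uniform
    conformer" definition); macrostates are the two wells.  Orientation is
    deep well (A) as end state, i.e. ΔF(B→A), so in the deep-well limit
    δΔF converges to -delta_U: the uniform discretization fails ISWD by
    exactly the well-depth gap.
    """
    from .discretize import count_unique
    from .free_energy import delta_F_conf, delta_F_snap

    lo, hi = samples.spec.domain
    cell = np.floor((samples.x - lo) / (hi - lo) * n_cells).astype(np.int64)
    cell = np.clip(cell, 0, n_cells - 1)
    in_a = samples.labels == "A"
    in_b = samples.labels == "B"
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("one of the wells received no samples")
    nc_a = count_unique(cell[in_a])
    nc_b = count_unique(cell[in_b])
    df_snap = delta_F_snap(n_b, n_a)  # B -> A
    df_conf = delta_F_conf(nc_b, nc_a)
    return {
        "n_snap_A": n_a, "n_snap_B": n_b,
        "n_conf_A": nc_a, "n_conf_B": nc_b,
        "dF_snap": df_snap, "dF_conf": df_conf,
        "ddF": df_snap - df_conf,
    }


# --------------------------------------------------------------------------
# grid torsion systems
# --------------------------------------------------------------------------

@dataclass
class TorsionSystem:
    """D torsions on a periodic grid with site energies and optional coupling.

    ``site_energies`` has shape (D, grid_size), kT units.  ``coupling`` is a
    tuple of ``(i, j, matrix)`` pairwise terms, ``matrix[g_i, g_j]`` in kT
    (i < j after normalization).  Without coupling the joint Boltzmann
    distribution factorizes over torsions.
    """

    site_energies: np.ndarray
    coupling: tuple = ()

    def __post_init__(self):
        e = np.asarray(self.site_energies, dtype=float)
        if e.ndim != 2 or e.shape[1] < 3:
            raise ValueError("site_energies must be (n_torsions, grid_size>=3)")
        if not np.all(np.isfinite(e)):
            raise ValueError("site energies must be finite")
        self.site_energies = e
        norm = []
        for i, j, m in self.coupling:
            i, j = int(i), int(j)
            m = np.asarray(m, dtype=float)
            if i == j or not (0 <= i < e.shape[0] and 0 <= j < e.shape[0]):
                raise ValueError("coupling indices must be two distinct torsions")
            if i > j:
                i, j, m = j, i, m.T
            if m.shape != (e.shape[1], e.shape[1]) or not np.all(np.isfinite(m)):
                raise ValueError("coupling matrix must be (grid, grid) and finite")
            norm.append((i, j, m))
        self.coupling = tuple(norm)

    @property
    def n_torsions(self) -> int:
        return self.site_energies.shape[0]

    @property
    def grid_size(self) -> int:
        return self.site_energies.shape[1]

    @property
    def is_factorized(self) -> bool:
        return len(self.coupling) == 0

    @property
    def bin_width(self) -> float:
        return 360.0 / self.grid_size

    @property
    def bin_centers(self) -> np.ndarray:
        """Angle at each grid bin center, within (-180, 180]."""
        return -180.0 + (np.arange(self.grid_size) + 0.5) * self.bin_width

    def energy_of(self, grid_idx: np.ndarray) -> np.ndarray:
        """Total energy (kT) of microstates given as (n, D) grid indices."""
        g = np.atleast_2d(np.asarray(grid_idx, dtype=np.int64))
        e = self.site_energies[np.arange(self.n_torsions), g].sum(axis=1)
        for i, j, m in self.coupling:
            e = e + m[g[:, i], g[:, j]]
        return e

    def angles_to_grid(self, angles: np.ndarray) -> np.ndarray:
        """Nearest-bin grid indices for angles in degrees."""
        rel = np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0)
        return np.minimum((rel / self.bin_width).astype(np.int64), self.grid_size - 1)

    def marginals(self) -> np.ndarray:
        """Exact per-torsion Boltzmann marginals (factorized systems only)."""
        if not self.is_factorized:
            raise ValueError("exact marginals require a factorized (uncoupled) system")
        w = np.exp(-(self.site_energies - self.site_energies.min(axis=1, keepdims=True)))
        return w / w.sum(axis=1, keepdims=True)


@dataclass
class SampleSet:
    """Samples from a synthetic system: trajectory + energies + provenance."""

    trajectory: DihedralTrajectory
    grid_indices: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    @property
    def energies(self) -> np.ndarray:
        return self.trajectory.energies


def sample_torsion_system(system: TorsionSystem, n: int, seed: int,
                          sampler: str = "exact_factorized",
                          burn_in: int = None, thinning: int = None) -> SampleSet:
    """Draw n Boltzmann samples from a grid torsion system.

    ``exact_factorized`` draws each torsion independently from its exact
    marginal (factorized systems only).  ``mcmc`` runs single-site Metropolis
    with burn-in 10 * D * grid_size sweeps and thinning D sweeps by default
    (one sweep = D single-site updates), recorded in provenance.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    d, g = system.n_torsions, system.grid_size

    if sampler == "exact_factorized":
        if not system.is_factorized:
            raise ValueError("exact_factorized sampler requires an uncoupled system")
        p = system.marginals()
        idx = np.column_stack([rng.choice(g, size=n, p=p[j]) for j in range(d)])
        prov = {"sampler": "exact_factorized", "seed": int(seed), "n": int(n)}
    elif sampler == "mcmc":
        if burn_in is None:
            burn_in = 10 * d * g
        if thinning is None:
            thinning = d
        idx = _metropolis(system, n, rng, burn_in, thinning)
        prov = {"sampler": "mcmc", "seed": int(seed), "n": int(n),
                "burn_in_sweeps": int(burn_in), "thinning_sweeps": int(thinning)}
    else:
        raise ValueError(f"unknown sampler {sampler!r}")

    traj = DihedralTrajectory(
        system.bin_centers[idx],
        energies=system.energy_of(idx),
        source=f"synthetic:{prov['sampler']}:seed={seed}",
    )
    return SampleSet(trajectory=traj, grid_indices=idx, provenance=prov)


def _metropolis(system: TorsionSystem, n: int, rng, burn_in: int, thinning: int) -> np.ndarray:
    """Single-site Metropolis over the microstate grid; returns (n, D) indices."""
    d, g = system.n_torsions, system.grid_size
    site = system.site_energies
    neigh = [[] for _ in range(d)]  # per site: (other site, matrix oriented [g_self, g_other])
    for i, j, m in system.coupling:
        neigh[i].append((j, m))
        neigh[j].append((i, m.T))

    state = rng.integers(0, g, size=d)
    out = np.empty((n, d), dtype=np.int64)
    total_sweeps = burn_in + n * thinning
    sites = rng.integers(0, d, size=total_sweeps * d)
    props = rng.integers(0, g, size=total_sweeps * d)
    logu = np.log(rng.random(total_sweeps * d))
    k = 0
    stored = 0
    for sweep in range(total_sweeps):
        for _ in range(d):
            s, new = sites[k], props[k]
            old = state[s]
            de = site[s, new] - site[s, old]
            for other, m in neigh[s]:
                de += m[new, state[other]] - m[old, state[other]]
            if de <= 0 or logu[k] < -de:
                state[s] = new
            k += 1
        if sweep >= burn_in and (sweep - burn_in) % thinning == 0 and stored < n:
            out[stored] = state
            stored += 1
    if stored < n:  # pad from the tail (only if thinning overshoots); keep deterministic
        out[stored:] = state
    return out


# --------------------------------------------------------------------------
# exact enumeration / factorized analytics
# --------------------------------------------------------------------------

def _window_mask(system: TorsionSystem, selector: MacrostateSelector) -> np.ndarray:
    """Boolean mask over grid bins whose center falls in [lo, hi)."""
    centers = system.bin_centers
    return (centers >= selector.lo) & (centers < selector.hi)


def _joint_energy(system: TorsionSystem, cap: int) -> np.ndarray:
    """Full microstate energy tensor, shape (G,)*D; raises above the cap."""
    d, g = system.n_torsions, system.grid_size
    if g**d > cap:
        raise EnumerationCapError(
            f"grid_size**n_torsions = {g}**{d} exceeds the enumeration cap {cap}")
    e = np.zeros((g,) * d)
    for j in range(d):
        shape = [1] * d
        shape[j] = g
        e = e + system.site_energies[j].reshape(shape)
    for i, j, m in system.coupling:
        shape = [1] * d
        shape[i] = g
        shape[j] = g
        e = e + m.reshape(shape)
    return e


def _joint_distribution(system: TorsionSystem, cap: int) -> np.ndarray:
    """Full joint Boltzmann tensor, shape (G,)*D; raises above the cap."""
    e = _joint_energy(system, cap)
    w = np.exp(-(e - e.min()))
    return w / w.sum()


def exact_macrostate_weight(system: TorsionSystem, selector: MacrostateSelector,
                            cap: int = DEFAULT_ENUMERATION_CAP) -> float:
    """Exact Boltzmann probability of the selector's window.

    Factorized systems use the order-parameter torsion's exact marginal (any
    D); coupled systems are enumerated outright, subject to the cap.
    """
    mask = _window_mask(system, selector)
    if system.is_factorized:
        return float(system.marginals()[selector.order_param][mask].sum())
    p = _joint_distribution(system, cap)
    sl = [slice(None)] * system.n_torsions
    sl[selector.order_param] = mask
    return float(p[tuple(sl)].sum())


def _entropy(p: np.ndarray) -> float:
    q = p[p > 0]
    return float(-np.sum(q * np.log(q)))


@dataclass
class ExactEntropyReport:
    """Microstate-exact entropy decomposition of one macrostate.

    All entropies in k units, energies in kT.  ``S_total`` always equals the
    direct Shannon entropy over microstates; the grouped form satisfies
    S_total = S_conf + mean_S_intra and S_conf = S_Boltz - D_KL exactly.
    Per-conformer arrays (``P``, ``S_intra``) may be omitted (None) when the
    conformer space is too large to materialize on factorized systems.
    """

    weight: float
    n_conf: int
    S_conf: float
    S_Boltz: float
    D_KL: float
    mean_S_intra: float
    S_total: float
    mean_U: float
    P: np.ndarray = None
    S_intra: np.ndarray = None


def exact_entropy_report(system: TorsionSystem, selector: MacrostateSelector,
                         conf_def: ConformerDefinition,
                         cap: int = DEFAULT_ENUMERATION_CAP,
                         method: str = "auto") -> ExactEntropyReport:
    """Exact conformer weights and entropy decomposition within a macrostate.

    ``method='factorized'`` computes everything from per-torsion marginals
    (uncoupled systems, any D); ``'enumerate'`` brute-forces the full grid
    (capped).  ``'auto'`` picks factorized when available.
    """
    if method == "auto":
        method = "factorized" if system.is_factorized else "enumerate"
    if method == "factorized":
        if not system.is_factorized:
            raise ValueError("factorized analytics require an uncoupled system")
        return _entropy_report_factorized(system, selector, conf_def)
    if method == "enumerate":
        return _entropy_report_enumerate(system, selector, conf_def, cap)
    raise ValueError(f"unknown method {method!r}")


def _bin_states(system: TorsionSystem, boundaries: TorsionStateBoundaries) -> np.ndarray:
    """Torsional state (0/1/2) of each grid bin center."""
    return assign_torsional_states(system.bin_centers, boundaries)


def _entropy_report_factorized(system, selector, conf_def) -> ExactEntropyReport:
    q = system.marginals().copy()
    mask = _window_mask(system, selector)
    op = selector.order_param
    w = float(q[op][mask].sum())
    if w <= 0:
        raise ValueError("macrostate has zero Boltzmann weight")
    cond = q[op] * mask
    q[op] = cond / cond.sum()

    states = _bin_states(system, conf_def.boundaries)
    subset = conf_def.torsion_subset
    s_conf = 0.0
    n_conf = 1
    mean_s_intra = 0.0
    per_torsion_w = []
    for j in range(system.n_torsions):
        h_bins = _entropy(q[j])
        if j in subset:
            wst = np.array([q[j][states == s].sum() for s in range(3)])
            occ = wst > 0
            s_conf += _entropy(wst)
            n_conf *= int(occ.sum())
            per_torsion_w.append(wst)
            # conditional bin entropy within each occupied state
            for s in np.flatnonzero(occ):
                psel = q[j][states == s]
                mean_s_intra += wst[s] * _entropy(psel / wst[s])
        else:
            mean_s_intra += h_bins
    s_total = float(sum(_entropy(q[j]) for j in range(system.n_torsions)))
    mean_u = float(sum((q[j] * system.site_energies[j]).sum() for j in range(system.n_torsions)))

    P = None
    if n_conf <= 10**6:
        # joint conformer weights: outer product of per-torsion occupied state
        # weights (order of entries is not meaningful, only the multiset is)
        P = np.array([1.0])
        for wst in per_torsion_w:
            P = np.outer(P, wst[wst > 0]).ravel()
    return ExactEntropyReport(
        weight=w, n_conf=n_conf, S_conf=s_conf, S_Boltz=float(np.log(n_conf)),
        D_KL=float(np.log(n_conf)) - s_conf, mean_S_intra=mean_s_intra,
        S_total=s_total, mean_U=mean_u, P=P, S_intra=None,
    )


def _entropy_report_enumerate(system, selector, conf_def, cap) -> ExactEntropyReport:
    d, g = system.n_torsions, system.grid_size
    e = _joint_energy(system, cap)
    w_all = np.exp(-(e - e.min()))
    p = w_all / w_all.sum()
    mask = _window_mask(system, selector)
    sl = [slice(None)] * d
    sl[selector.order_param] = mask
    sel = np.zeros((g,) * d, dtype=bool)
    sel[tuple(sl)] = True
    w = float(p[sel].sum())
    if w <= 0:
        raise ValueError("macrostate has zero Boltzmann weight")
    pt = p[sel] / w  # conditional microstate probabilities within the macrostate

    states = _bin_states(system, conf_def.boundaries)
    cid = np.zeros((g,) * d, dtype=np.int64)
    for pos, j in enumerate(conf_def.torsion_subset):
        shape = [1] * d
        shape[j] = g
        cid = cid + (states.astype(np.int64) * 3**pos).reshape(shape)
    cid_sel = cid[sel]

    n_bins = 3 ** len(conf_def.torsion_subset)
    pw = np.bincount(cid_sel, weights=pt, minlength=n_bins)
    plogp = np.bincount(cid_sel, weights=np.where(pt > 0, pt * np.log(np.where(pt > 0, pt, 1.0)), 0.0),
                        minlength=n_bins)
    occ = pw > 0
    P = pw[occ]
    A = plogp[occ]
    s_intra = -A / P + np.log(P)
    s_conf = _entropy(P)
    n_conf = int(occ.sum())
    s_total = _entropy(pt)
    mean_u = float(np.sum(pt * e[sel]))
    return ExactEntropyReport(
        weight=w, n_conf=n_conf, S_conf=s_conf, S_Boltz=float(np.log(n_conf)),
        D_KL=float(np.log(n_conf)) - s_conf,
        mean_S_intra=float(np.sum(P * s_intra)),
        S_total=s_total, mean_U=mean_u, P=P, S_intra=s_intra,
    )


def eec_check(system: TorsionSystem, sel_a: MacrostateSelector, sel_b: MacrostateSelector,
              conf_def: ConformerDefinition, cap: int = DEFAULT_ENUMERATION_CAP,
              method: str = "auto"):
    """Exact entropy-enthalpy bookkeeping between two macrostates.

    Returns an :class:`confcount.entropy.EECReport` whose ``closure``
    (ΔF - ΔU + TΔS_total) vanishes to numerical precision, and whose
    ``residual`` (ΔU - TΔ<S_intra> - T(ΔS_conf - ΔS_Boltz)) equals
    ΔF - ΔF_conf: zero exactly when the conformer definition has ISWD.
    """
    from .entropy import EECReport

    ra = exact_entropy_report(system, sel_a, conf_def, cap=cap, method=method)
    rb = exact_entropy_report(system, sel_b, conf_def, cap=cap, method=method)
    df_exact = -math.log(rb.weight / ra.weight)
    df_conf = -math.log(rb.n_conf / ra.n_conf)
    return EECReport(
        dU=rb.mean_U - ra.mean_U,
        dS_intra=rb.mean_S_intra - ra.mean_S_intra,
        dS_conf=rb.S_conf - ra.S_conf,
        dS_Boltz=rb.S_Boltz - ra.S_Boltz,
        dF_exact=df_exact,
        dF_conf=df_conf,
    )


# --------------------------------------------------------------------------
# reference system constructors
# --------------------------------------------------------------------------

def popc_like_system(seed: int = 0, n_torsions: int = 12, grid_size: int = 360,
                     coupled: bool = False, coupling_strength: float = 0.5) -> TorsionSystem:
    """A lipid-tail-like torsion system: three rotamer wells per torsion.

    Each torsion has Gaussian wells at -60/60/180 degrees with seeded random
    depths in [1, 4] kT (width 20 degrees), mimicking the three-basin
    structure of aliphatic-chain dihedrals with exponentially varying basin
    weights.  With ``coupled=True`` a smooth nearest-neighbour cosine
    coupling of the given strength (kT) is added.
    """
    rng = np.random.default_rng(seed)
    centers = -180.0 + (np.arange(grid_size) + 0.5) * (360.0 / grid_size)
    site = np.zeros((n_torsions, grid_size))
    for j in range(n_torsions):
        depths = rng.uniform(1.0, 4.0, size=3)
        e = np.zeros(grid_size)
        for mu, dep in zip((-60.0, 60.0, 180.0), depths):
            dist = np.abs((centers - mu + 180.0) % 360.0 - 180.0)
            e -= dep * np.exp(-0.5 * (dist / 20.0) ** 2)
        site[j] = e - e.min()
    coupling = ()
    if coupled:
        th = np.deg2rad(centers)
        m = coupling_strength * (1.0 - np.cos(th[:, None] - th[None, :]))
        coupling = tuple((j, j + 1, m) for j in range(n_torsions - 1))
    return TorsionSystem(site_energies=site, coupling=coupling)


def equal_arc_mass_system(seed: int = 0, n_torsions: int = 2, grid_size: int = 36,
                          roughness: float = 2.0) -> TorsionSystem:
    """A rugged system whose three rotamer arcs all carry equal Boltzmann mass.

    Within each 120-degree arc the energy profile is random (seeded,
    amplitude ``roughness`` kT) but each arc is shifted so its Boltzmann
    mass matches the others exactly.  With conformers = arcs and macrostates
    aligned to arc boundaries this realizes exact ISWD with *different* mean
    energies per arc: the enthalpy difference between macrostates is
    cancelled exactly by the intra-conformer entropy difference.
    """
    if grid_size % 3 != 0:
        raise ValueError("grid size must be divisible by 3 for arc alignment")
    rng = np.random.default_rng(seed)
    third = grid_size // 3
    site = np.empty((n_torsions, grid_size))
    for j in range(n_torsions):
        e = rng.uniform(0.0, roughness, size=grid_size)
        for a in range(3):
            segment = e[a * third:(a + 1) * third]
            mass = np.exp(-segment).sum()
            segment += np.log(mass)  # shift so each arc's mass is exactly 1
            e[a * third:(a + 1) * third] = segment
        site[j] = e
    return TorsionSystem(site_energies=site)


# --------------------------------------------------------------------------
# gated (exact-ISWD) coupled system
# --------------------------------------------------------------------------

@dataclass
class GatedSystem:
    """Order-parameter-gated torsion system with exact ISWD by construction.

    Torsion 0 is the order parameter; its range is split into
    ``n_windows`` equal windows.  For each window v and each gated torsion
    j >= 1, only the rotamer arcs in ``allowed[j-1][v]`` are accessible; all
    accessible microstates have energy 0 and everything else is excluded.
    The Boltzmann mass of window v is proportional to
    K(v) = prod_j |allowed[j-1][v]| — the number of accessible conformers —
    and every accessible conformer carries identical weight, so the
    conformer-count free energy between windows is exact in the sampling
    limit (exact ISWD), with exponentially varying window weights.
    """

    allowed: tuple            # allowed[j][v] = tuple of accessible arcs (subset of {0,1,2})
    n_windows: int = 20
    boundaries: TorsionStateBoundaries = field(default_factory=TorsionStateBoundaries)

    def __post_init__(self):
        for per_window in self.allowed:
            if len(per_window) != self.n_windows:
                raise ValueError("each gated torsion needs one arc set per window")
            for arcs in per_window:
                if not 1 <= len(arcs) <= 3 or any(a not in (0, 1, 2) for a in arcs):
                    raise ValueError("arc sets must be non-empty subsets of {0,1,2}")

    @property
    def n_gated(self) -> int:
        return len(self.allowed)

    @property
    def n_torsions(self) -> int:
        return self.n_gated + 1

    @property
    def window_width(self) -> float:
        return 360.0 / self.n_windows

    def conformer_count(self, window: int) -> int:
        """K(v): number of accessible conformers over the gated torsions."""
        k = 1
        for per_window in self.allowed:
            k *= len(per_window[window])
        return k

    def window_weights(self) -> np.ndarray:
        """Exact Boltzmann weight of each window (proportional to K(v))."""
        k = np.array([self.conformer_count(v) for v in range(self.n_windows)], dtype=float)
        return k / k.sum()

    @classmethod
    def random(cls, seed: int, n_gated: int = 12, n_windows: int = 20) -> "GatedSystem":
        """Seeded random gate pattern with arc-set sizes drawn from {1, 2, 3}."""
        rng = np.random.default_rng(seed)
        allowed = []
        for _ in range(n_gated):
            per_window = []
            for _ in range(n_windows):
                size = int(rng.integers(1, 4))
                arcs = tuple(sorted(rng.choice(3, size=size, replace=False).tolist()))
                per_window.append(arcs)
            allowed.append(tuple(per_window))
        return cls(allowed=tuple(allowed), n_windows=n_windows)


def sample_gated_system(system: GatedSystem, n: int, seed: int,
                        stratified: bool = True) -> SampleSet:
    """Draw n exact samples: window by weight, then arcs uniform over gates.

    With ``stratified=True`` (default) the window sequence follows a
    golden-ratio low-discrepancy stream over the exact window weights, so
    every time-ordered prefix of the sample carries near-exact window
    populations (discrepancy O(log n) snapshots) — a variance-reduction
    choice that isolates discretization effects from window-count shot
    noise.  ``stratified=False`` draws windows i.i.d. multinomially.
    Conditional on the window, arcs and angles are always i.i.d.  All
    accessible microstates are iso-energetic, so per-snapshot energies are
    identically zero.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    nw = system.n_windows
    width = system.window_width
    weights = system.window_weights()
    if stratified:
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        u = np.mod((np.arange(n) + 1) * phi, 1.0)
        win = np.searchsorted(np.cumsum(weights), u, side="right")
    else:
        win = rng.choice(nw, size=n, p=weights)
    angles = np.empty((n, system.n_torsions))
    angles[:, 0] = -180.0 + (win + rng.random(n)) * width

    cuts = np.array(list(system.boundaries.cuts) + [system.boundaries.cuts[0] + 360.0])
    u_arc = rng.random((n, system.n_gated))
    u_pos = rng.random((n, system.n_gated))
    for v in range(nw):
        rows = np.flatnonzero(win == v)
        if rows.size == 0:
            continue
        for jg in range(system.n_gated):
            arcs = np.array(system.allowed[jg][v])
            pick = arcs[(u_arc[rows, jg] * len(arcs)).astype(np.int64).clip(max=len(arcs) - 1)]
            lo = cuts[pick]
            hi = cuts[pick + 1]
            angles[rows, jg + 1] = lo + u_pos[rows, jg] * (hi - lo)
    traj = DihedralTrajectory(
        angles,
        energies=np.zeros(n),
        source=f"synthetic:gated:seed={seed}",
    )
    return SampleSet(trajectory=traj, provenance={"sampler": "gated_exact", "seed": int(seed), "n": int(n)})
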
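# Methods

## Model and assumptions

A configuration of a molecule is reduced to its vector of dihedral angles
(degrees, canonical range (−180, 180] with −180 ≡ +180).  Each torsion's
circle is partitioned into three half-open arcs ("torsional states"), the
left edge belonging to the arc.  A **conformer** is the joint torsional-state
assignment over an ordered subset of torsions; with m torsions the id space
has 3^m cells, encoded as mixed-radix base-3 integers (least significant
digit first).  Subsets of up to 39 torsions use int64 ids; larger subsets
(3^43 > 2^63) fall back to exact Python integers.  The id space is never
materialized: distinct-conformer counting is a sort plus run count.

A **macrostate** is the set of snapshots whose order-parameter dihedral
falls in a fixed half-open window (default 18°, 20 windows per dihedral,
anchored at −180°).  Windows of one order parameter partition the
trajectory; windows of different order parameters may overlap and their
macrostates are pooled in pairwise analyses.  Empty windows are retained but
flagged unobserved and excluded from pairwise statistics, where the
free-energy estimators are undefined at zero counts.

Everything is computed at β = 1: free energies in kT, entropies in k,
T = 1 where a T factor is needed.  Two estimators per macrostate pair
(oriented lower index → higher index; signs are a convention):

* ΔF_snap = −ln(N_snap_i / N_snap_j)  — population based;
* ΔF_conf = −ln(N_conf_i / N_conf_j)  — conformer-count based, exact iff
  accessible conformers have an invariant statistical weight distribution
  (ISWD).

δΔF = ΔF_snap − ΔF_conf is the ISWD diagnostic.  Its |·| distribution is
summarized by the empirical CDF ("CPD") and the exact integral of that step
function over a caller-fixed range shared by every curve being compared
(so AUCs are comparable across definitions and trajectory sizes; for a step
CDF the exact integral is what a trapezoidal rule converges to, and keeps
degenerate cases exact, e.g. all-zero deviations give AUC = full range).

## Entropy decomposition

Within a macrostate with conformer weights P_i (snapshot fractions over the
N_conf occupied conformers):

* S_conf = −Σ P_i ln P_i = ln N_conf − D_KL(P ‖ uniform), both identities
  enforced to 1e-12 relative in tests.  Support convention: all sums run
  over occupied conformers only, with p ln p → 0 at p = 0.
* δΔS = ΔS_conf − ΔS_Boltz = −ΔD_KL per pair, same orientation as δΔF.
* Snapshot-multiplicity bookkeeping: writing c = Σ P_i ln n_i (the
  snapshot-level mean intra-conformer entropy), the exact identity
  δΔF = −δΔS − Δc holds on any data.  Hence δΔF = −T·δΔS exactly whenever
  the multiplicity profile is shared (Δc = 0), e.g. one snapshot per
  conformer; the package's tests pin this with a hand-computed construction
  (counts {1,1,2} vs {1×12, 4}, both with c = ln2/2, giving
  δΔF = ln(13/12) = −δΔS exactly).

On enumerable synthetic systems the full decomposition is computed
microstate-exactly: S_total = S_conf + ⟨S_intra⟩ equals the direct Shannon
entropy over microstates (1e-10 relative), ΔF = ΔU − TΔS_total closes to
numerical precision, and the entropy–enthalpy compensation residual
ΔU − TΔ⟨S_intra⟩ − T(ΔS_conf − ΔS_Boltz) equals ΔF − ΔF_conf, vanishing
exactly under ISWD.  ⟨S_intra⟩ is only defined where microstates can be
enumerated; for trajectory data the per-macrostate entropy table instead
reports the snapshot-multiplicity term c, which plays the same role in the
δΔF/δΔS bookkeeping.

## Synthetic systems (what they emulate, and what they do not)

All samplers are deterministic given an integer seed, and stored energies
are exactly recomputable from the stored configurations.

**Double well** — a 1-D piecewise-constant potential: two flat wells of
equal width (bottoms 0 and ΔU kT) separated by a flat barrier
(default 12 kT).  Sampling is exact inverse-CDF over the flat segments.
This is the counterexample showing that fineness alone cannot buy ISWD:
under any uniform cell grid the wells' cells differ in weight by e^(−ΔU),
so δΔF between the well macrostates converges to −ΔU (orientation
deep-well-as-end-state) regardless of cell count.  Defaults
(ΔU = 2 kT, well width 0.25 on [0,1], 40 cells, 10^6 samples) recover −ΔU
well within 0.05 kT.

**Torsion grid systems** — D torsions on a periodic grid (default 360
one-degree bins, centers in (−180, 180]), per-torsion site energies,
optional pairwise coupling matrices.  Uncoupled systems factorize: exact
marginals, macrostate weights and the full entropy decomposition are
available at any D, and sampling is exact per-torsion inverse-CDF.  Coupled
systems are enumerated outright (cap 10^7 microstates) as the brute-force
oracle, and sampled by single-site Metropolis (burn-in 10·D·grid sweeps,
thinning D sweeps by default, recorded in provenance; chosen for
reproducibility, not efficiency).  The "POPC-like" constructor places three
Gaussian wells per torsion at −60/60/180° with seeded random depths in
[1, 4] kT and width 20° — three rotameric basins with exponentially varying
weights, mirroring aliphatic-chain dihedrals — with optional
nearest-neighbour cosine coupling.  The "equal-arc-mass" constructor draws
a rugged profile per arc and shifts each arc to exactly unit Boltzmann
mass: different mean energies per arc with identical weights, realizing
exact ISWD where ΔU ≠ 0 is cancelled exactly by Δ⟨S_intra⟩.

**Gated system** — the study system for the convergence-trend diagnostic.
Torsion 0 is the order parameter; its window index v selects which rotamer
arcs of each remaining torsion are accessible (arc-set sizes drawn from
{1, 2, 3} per window, seeded), and all accessible microstates are
iso-energetic.  Every accessible conformer then carries identical weight and
window mass is proportional to its accessible conformer count
K(v) = Π|A_j(v)| — exact ISWD with exponentially varying window weights.
The sampler allocates windows along a golden-ratio low-discrepancy stream
over the exact window weights (every time-ordered prefix carries near-exact
window populations, discrepancy O(log n)); arcs and angles are i.i.d.
conditional on the window.  This variance-reduction choice isolates
discretization effects from window-count shot noise; an i.i.d. multinomial
mode is available.  Study conditions for the trend: 12 gated torsions,
10^6 snapshots, nested prefixes 0.1/0.5/1.0, fine definition = all 12 gated
torsions, coarse = 11 of them.  The fine definition's conformer occupancy
factor is identical across windows (N(v)/K(v) = n/ΣK), so its δΔF shrinks
toward zero as counts converge, while the coarse definition's counts
saturate at limits that mismatch the window weights, so its |δΔF| broadens
toward the nonzero asymptote — the shrinking-vs-broadening ISWD signature.

What the synthetic systems do **not** emulate: Cartesian geometry, force
fields, solvent, kinetics and temporal correlation (synthetic snapshots are
exchangeable; real MD frames are autocorrelated, so real convergence trends
need longer trajectories than the nominal snapshot counts suggest), and
continuous energy variation within conformers of real molecules.  Passing
tests certify the estimators and identities, not the ISWD quality of any
particular real discretization.

## Numerical and design choices

* Torsional-state boundaries default to cuts {−180, −60, 60}° (the
  gauche−/anti-adjacent trisection); a +60°-shifted variant is provided and
  both are configurable.  Equal arcs are used throughout — no adaptive or
  energy-weighted binning.
* Half-open windows/arcs with the left edge included give deterministic,
  order-free tie-breaking for boundary angles.
* Macrostate windows are anchored at −180°; nested trajectory subsets are
  time-ordered prefixes, not random subsamples.
* The scaling diagnostic normalizes N_snap and N_conf within each
  order-parameter family (each family's windows partition the trajectory)
  before the least-squares fit; a constant axis is reported as a degenerate
  fit rather than fitted.
* Pair tables hold M(M−1)/2 rows for M observed macrostates; with the
  43-dihedral / 18°-window reference setup that is 860 macrostates and
  369,370 pairs, computed in seconds.
* Histogram binning for δΔF density plots (where drawn) is
  Freedman–Diaconis; all quantitative statements use the CPD/AUC, which is
  binning-free.
* Problem sizes used by the test suite and the acceptance script — 10^6
  double-well and gated samples, 10^5 samples for the Monte-Carlo
  convergence check, 12^3-microstate coupled grids for enumeration — were
  chosen so exact oracles stay cheap while sampling errors remain well below
  the effects being measured.
* Criterion-style stochastic checks use the delta-method standard error of
  −ln(n_i/n_j) under multinomial counts, including the covariance term; a
  per-pair 3-SE tolerance is combined with a 1% family allowance across the
  190 pairs, since ~0.3% of honest 3σ exceedances are expected by chance.

## Known limitations

* The conformer-count estimator needs every compared macrostate observed;
  no extrapolation to unobserved regions is attempted.
* ⟨S_intra⟩ from trajectory data would require microstate densities the
  data cannot supply; only the snapshot-multiplicity surrogate is reported.
* The MCMC sampler is a plain single-site Metropolis intended for small
  oracle systems, not production sampling of large coupled grids.
* Angle handling assumes degrees; radians must be converted upstream.
* The MD adapter matches atoms by unique name within the topology; systems
  with duplicated atom names need integer indices instead.
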
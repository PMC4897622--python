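"""Rate-equation model of bulk ring assembly.

Deterministic coagulation–fragmentation kinetics over the ten rigid species
(open chains of 1–9 homodimers plus the closed ring).  Each open chain has
one free donor end and one free acceptor end, so chain(i) + chain(j) →
chain(i+j) proceeds through two distinguishable end pairings when i ≠ j and
one when i = j; no species beyond the 9-chain can form because the snapped
geometry of a longer chain would self-overlap.  Forward rate constants are
diffusion-limited and estimated from the encounter window and the rigid-body
diffusion tensors (or from short BD encounter simulations); every backward
rate follows from detailed balance through the per-bond equilibrium
constant, K_bond = 1/K_D with K_D = 60 μM calibrated to the measured
N-term/N-term affinity.

Ring closure is special: the rigid 9-chain holds its free ends permanently
in the bound configuration, so closure is reaction-limited with equilibrium

    [ring]/[9-chain] = c_eff · exp(|E|) / (9 K_D),

where c_eff = 1/(N_A v_b) is the effective molarity presented by the
pre-organized ends (v_b = encounter-window volume), exp(|E|) the ring
stabilization and the factor 9 the opening multiplicity (any one of nine
bonds opens the ring into the same 9-chain).  Because microscopic closure
is effectively instantaneous on these time scales, the ODE treats the
9-chain/ring exchange adiabatically (one lumped species partitioned by the
closure equilibrium); only the equilibrium ratio is physical.

Concentrations are μM, time is seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .geometry import InvalidParameterError, ModelParams
from .reactions import AffinityCalibration, EncounterWindow
from .species import mean_translational_diffusion
from .units import NM3_PER_NS_TO_PER_UM_S


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the last valid state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class RateMatrix:
    """Association/dissociation rate constants for the chain+ring system.

    ``k_ij[i-1, j-1]`` is the diffusion-limited rate constant (μM⁻¹ s⁻¹) for
    one *specific* end pairing of chain(i) + chain(j); the two-fold channel
    multiplicity for i ≠ j is applied by the ODE right-hand side.  ``kd_um``
    is the per-bond dissociation constant (μM) and fixes every backward rate
    b_ij = k_ij · K_D.  ``c_eff_um`` is the ring-closure effective molarity.
    """

    k_ij: np.ndarray  # (9, 9) μM^-1 s^-1
    kd_um: float
    c_eff_um: float
    uncertain: np.ndarray | None = None  # bool flags for non-converged entries

    @property
    def k_off(self) -> float:
        """Reference per-bond dissociation rate (1/s), monomer+monomer channel."""
        return float(self.k_ij[0, 0]) * self.kd_um

    def ring_equilibrium(self, ring_energy: float) -> float:
        """[ring]/[9-chain] at equilibrium for stabilization E ≤ 0 (k_BT)."""
        if ring_energy > 0:
            raise InvalidParameterError("ring stabilization energy must be <= 0")
        if self.kd_um == 0.0:
            return math.inf  # unbreakable bonds: the ring is absorbing
        return self.c_eff_um * math.exp(-ring_energy) / (9.0 * self.kd_um)


def estimate_diffusive_rates(
    params: ModelParams | None = None,
    window: EncounterWindow | None = None,
    calibration: AffinityCalibration = AffinityCalibration(),
    reps: int = 200_000,
    seed: int = 2024,
    method: str = "window",
    bd_events: int = 60,
) -> RateMatrix:
    """Diffusion-limited association rate constants for all chain pairs.

    ``method="window"``: Smoluchowski-with-window estimator — the rate for
    one end pairing is 4π (D_i + D_j) · w_d · f_rot, the diffusion-limited
    flux onto the anchor-tolerance sphere diluted by the orientational
    acceptance of the window (f_rot by Monte Carlo with ``reps`` samples).
    This freezes the mutual orientation during the approach and is a lower
    bound; because rotational diffusion is fast on the approach time scale,
    the dynamically measured rate is several-fold larger.

    ``method="bd"``: measure the monomer+monomer rate by short BD
    first-passage simulations (``bd_events`` encounters) and scale the rest
    of the matrix by (D_i + D_j)/(2 D_1) from the rigid-body tensors.

    The size dependence and every equilibrium observable are identical
    between the two routes; only the absolute kinetic time scale differs.
    Chain + chain binding counts both free-end pairings — that bookkeeping
    lives in the ODE system, not here.
    """
    window = window or EncounterWindow()
    d_mean = mean_translational_diffusion(params)
    uncertain = None
    if method == "bd":
        k11, ci = bd_encounter_rate(window, n_events=bd_events, seed=seed, params=params)
        k = k11 * (d_mean[:, None] + d_mean[None, :]) / (2.0 * d_mean[0])
        if (ci[1] - ci[0]) / k11 > 0.6:
            uncertain = np.ones((9, 9), dtype=bool)  # CI wider than ±30%
    elif method == "window":
        f_rot = window.rotation_fraction(n_samples=reps, seed=seed)
        k = np.zeros((9, 9))
        for i in range(9):
            for j in range(9):
                k_nm3_ns = (
                    4.0 * math.pi * (d_mean[i] + d_mean[j]) * window.max_anchor_dist * f_rot
                )
                k[i, j] = k_nm3_ns * NM3_PER_NS_TO_PER_UM_S
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return RateMatrix(
        k_ij=k,
        kd_um=calibration.kd_nn,
        c_eff_um=window.effective_molarity(),
        uncertain=uncertain,
    )


@dataclass
class ClusterPopulations:
    """Time series of species concentrations and relative populations.

    ``concentrations[t, s]`` is the molar concentration of species s (chains
    of size 1..9 at columns 0..8, the ring at column 9).  The relative
    population p_i is the probability that a homodimer belongs to an
    oligomer of size i (the ring counted as its own category):
    p_i = i·c_i / Σ_mass, p_ring = 9·c_ring / Σ_mass.
    """

    times: np.ndarray  # (T,) seconds
    concentrations: np.ndarray  # (T, 10) μM

    MASS_WEIGHTS = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 9], dtype=float)

    @property
    def total_mass(self) -> np.ndarray:
        return self.concentrations @ self.MASS_WEIGHTS

    @property
    def relative_populations(self) -> np.ndarray:
        mass = self.concentrations * self.MASS_WEIGHTS
        return mass / mass.sum(axis=1, keepdims=True)

    @property
    def ring_fraction(self) -> np.ndarray:
        """Fraction of homodimer mass in complete rings."""
        return self.relative_populations[:, 9]

    def final(self) -> np.ndarray:
        return self.concentrations[-1]


@dataclass(frozen=True)
class OdeSystem:
    """Chain kinetics with adiabatic ring closure.

    Microscopically the last bond of the rigid 9-chain closes at the
    reaction-limited rate k_ring, instantaneous on rate-equation time
    scales; representing it with a finite rate only adds an arbitrarily
    stiff mode whose prefactor has no physical content.  The system
    therefore lumps the 9-chain and the ring into one species z = c9 + cR
    partitioned at every instant by the closure equilibrium
    cR/c9 = ρ = c_eff·e^{|E|}/(9 K_D); only the open-chain part of z
    fragments.  State vector: c1..c8, z.
    """

    rates: RateMatrix
    ring_energy: float
    c0: float  # initial monomer concentration, μM
    rho: float = field(init=False, default=0.0)

    def __post_init__(self):
        if self.ring_energy > 0:
            raise InvalidParameterError("ring stabilization energy must be <= 0")
        if self.c0 <= 0:
            raise InvalidParameterError("initial concentration must be positive")
        object.__setattr__(self, "rho", self.rates.ring_equilibrium(self.ring_energy))

    @property
    def open_fraction(self) -> float:
        """Fraction of the lumped 9-mer species that is the open chain."""
        return 0.0 if math.isinf(self.rho) else 1.0 / (1.0 + self.rho)

    def _chains(self, y):
        c = np.empty(9)
        c[:8] = y[:8]
        c[8] = y[8] * self.open_fraction
        return c

    def rhs(self, t, y):
        k = self.rates.k_ij
        kd = self.rates.kd_um
        c = self._chains(y)
        dy = np.zeros(9)
        for i in range(9):
            for j in range(i, 9):
                s = i + j + 2  # product size
                if s > 9:
                    break
                rate = k[i, j] * c[i] * c[j] * (2.0 if i != j else 1.0)
                dy[s - 1] += rate
                dy[i] -= rate
                dy[j] -= rate
        for s in range(2, 10):  # fragmentation of the open chain of size s
            cs = c[s - 1]
            for m in range(1, s):
                b = k[m - 1, s - m - 1] * kd * cs
                dy[s - 1] -= b
                dy[m - 1] += b
                dy[s - m - 1] += b
        return dy

    def jac(self, t, y):
        k = self.rates.k_ij
        kd = self.rates.kd_um
        c = self._chains(y)
        open_frac = self.open_fraction
        jm = np.zeros((9, 9))

        def dvar(idx):
            # derivative of c[idx] w.r.t. state variable idx
            return open_frac if idx == 8 else 1.0

        for i in range(9):
            for j in range(i, 9):
                s = i + j + 2
                if s > 9:
                    break
                f = 2.0 if i != j else 1.0
                for var, dval in (
                    (i, f * k[i, j] * c[j] * dvar(i)),
                    (j, f * k[i, j] * c[i] * dvar(j)),
                ):
                    jm[s - 1, var] += dval
                    jm[i, var] -= dval
                    jm[j, var] -= dval
        for s in range(2, 10):
            d = dvar(s - 1)
            for m in range(1, s):
                b = k[m - 1, s - m - 1] * kd * d
                jm[s - 1, s - 1] -= b
                jm[m - 1, s - 1] += b
                jm[s - m - 1, s - 1] += b
        return jm

    def split(self, y_rows: np.ndarray) -> np.ndarray:
        """Map state rows (c1..c8, z) to the 10-column species layout."""
        y_rows = np.atleast_2d(y_rows)
        out = np.zeros((len(y_rows), 10))
        out[:, :8] = y_rows[:, :8]
        out[:, 8] = y_rows[:, 8] * self.open_fraction
        out[:, 9] = y_rows[:, 8] - out[:, 8]
        return out


def build_ode_system(rates: RateMatrix, ring_energy: float, c0: float) -> OdeSystem:
    """Coagulation–fragmentation system for chains 1..9 plus the ring."""
    return OdeSystem(rates=rates, ring_energy=ring_energy, c0=c0)


def integrate(
    system: OdeSystem,
    t_end: float | None = None,
    rtol: float = 1e-9,
    atol_rel: float = 1e-14,
    steady_tol: float = 1e-8,
    n_report: int = 200,
) -> ClusterPopulations:
    """Integrate the system (stiff-capable); mass is conserved by construction.

    With ``t_end`` None, integrates in expanding windows until the largest
    absolute change of the mass-weighted relative populations per decade of
    time falls below ``steady_tol`` (steady state).  The criterion acts on
    the populations rather than raw concentrations so that integrator noise
    on species many orders of magnitude below the total cannot stall it.
    """
    y0 = np.zeros(9)
    y0[0] = system.c0
    atol = atol_rel * system.c0

    def run(t0, t1, y_init, n_pts):
        ts = np.geomspace(max(t0, t1 * 1e-12), t1, n_pts) if t0 == 0 else np.geomspace(t0, t1, n_pts)
        sol = solve_ivp(
            system.rhs,
            (t0, t1),
            y_init,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=ts,
        )
        if not sol.success:
            raise IntegrationError(f"integrator failed: {sol.message}", state=sol)
        return sol

    if t_end is not None:
        sol = run(0.0, t_end, y0, n_report)
        return ClusterPopulations(sol.t, system.split(sol.y.T))

    # expanding-window steady-state search
    t1 = 1.0 / (system.rates.k_ij[0, 0] * system.c0 + system.rates.k_off)
    times = [np.array([0.0])]
    states = [y0[None, :]]
    weights = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
    y = y0
    t0 = 0.0
    for _ in range(60):
        sol = run(t0, t1, y, 30)
        times.append(sol.t)
        states.append(sol.y.T)
        y_new = sol.y[:, -1]
        delta = float(np.max(np.abs((y_new - y) * weights))) / system.c0
        y, t0 = y_new, t1
        t1 *= 10.0
        if delta < steady_tol:
            break
    else:
        raise IntegrationError("steady state not reached", state=(times, states))
    return ClusterPopulations(np.concatenate(times), system.split(np.concatenate(states)))


def equilibrium_oracle(
    k_bond: float,
    ring_energy: float,
    c_total: float,
    c_eff_um: float | None = None,
) -> np.ndarray:
    """Closed-form mass-action equilibrium of the chain+ring system.

    ``k_bond`` is the per-bond association constant (μM⁻¹, = 1/K_D);
    ``c_eff_um`` the ring-closure effective molarity (defaults to the value
    implied by the default encounter window).  Solves the conservation
    constraint for the free monomer concentration by bracketed root finding;
    independent of all kinetic prefactors.  Returns concentrations (10,).
    """
    if k_bond <= 0:
        raise InvalidParameterError("per-bond equilibrium constant must be positive")
    if ring_energy > 0:
        raise InvalidParameterError("ring stabilization energy must be <= 0")
    if c_eff_um is None:
        c_eff_um = EncounterWindow().effective_molarity()
    kd = 1.0 / k_bond
    rho = c_eff_um * math.exp(-ring_energy) / (9.0 * kd)

    def mass(x):
        chains = sum(n * k_bond ** (n - 1) * x**n for n in range(1, 10))
        ring = 9.0 * rho * k_bond**8 * x**9
        return chains + ring - c_total

    if c_total <= 0:
        return np.zeros(10)
    try:
        x = brentq(mass, 0.0, c_total, xtol=1e-18, rtol=8.9e-16, maxiter=300)
    except ValueError as exc:  # pragma: no cover
        raise IntegrationError(f"root bracketing failed on [0, {c_total}]") from exc
    c = np.array([k_bond ** (n - 1) * x**n for n in range(1, 10)] + [rho * k_bond**8 * x**9])
    return c


def bd_encounter_rate(
    window: EncounterWindow | None = None,
    box_edge: float = 30.0,
    n_events: int = 60,
    delta_t: float = 1.0,
    seed: int = 0,
    params: ModelParams | None = None,
) -> tuple[float, tuple[float, float]]:
    """Diffusion-limited monomer+monomer rate constant from BD first-passage
    sampling (μM⁻¹ s⁻¹), with a bootstrap-free Poisson CI.

    Two non-reacting homodimers are placed uniformly in a periodic box;
    the waiting time until their free ends first enter the encounter window
    is recorded, the pair is re-randomized, and the rate constant follows
    from k = V / ⟨τ⟩.  This is the measurement route behind the
    Smoluchowski-with-window estimator used by default; the estimate is
    flagged non-converged if the relative CI width exceeds 30%.
    """
    import warnings

    from .reactions import ReactionParameters
    from .simulate import Simulation

    window = window or EncounterWindow()
    rng = np.random.default_rng(seed)
    box = (box_edge, box_edge, box_edge)
    taus = []
    # association probability 1 per encounter (diffusion-limited): detect the
    # first step at which the window condition holds
    reaction = ReactionParameters(k_a=50.0, k_d=0.0, delta_t=delta_t, window=window)
    chunk = 2000
    for _ in range(n_events):
        sim = Simulation(reaction, box, params=params, capacity=4,
                         seed=int(rng.integers(0, 2**31 - 1)))
        sim.place_random_homodimers(2)
        steps = 0
        while True:
            sim.run(chunk, record_every=chunk)
            steps += chunk
            if sim.species_counts()[1] > 0:
                break
            if steps > 5_000_000:  # pragma: no cover
                break
        taus.append(steps * delta_t)
    taus = np.array(taus)
    mean = taus.mean()
    k_nm3_ns = box_edge**3 / mean
    k = k_nm3_ns * NM3_PER_NS_TO_PER_UM_S
    # exponential waiting times: CI of the mean from the gamma distribution
    from scipy import stats as _st

    lo, hi = _st.gamma.interval(0.95, a=len(taus), scale=mean / len(taus))
    ci = (box_edge**3 / hi * NM3_PER_NS_TO_PER_UM_S, box_edge**3 / lo * NM3_PER_NS_TO_PER_UM_S)
    if (ci[1] - ci[0]) / k > 0.6:
        warnings.warn("bd_encounter_rate: confidence interval wider than 30%", stacklevel=2)
    return k, ci
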
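"""Kinetic model of surface-activated peptide polymerization under
wetting-drying cycles.

The LDH surface carries a fixed population of adsorbed, activated species
X_n (chains of length n, surface-population units, capacity 100).  During a
dehydration phase, chain extension X_1 + X_n -> X_{n+1} proceeds with a
single rate constant k until the monomers are exhausted:

    dX_1/dt = -k X_1 sum_{n>=2} X_n
    dX_n/dt =  k X_1 (X_{n-1} - X_n)          for n >= 2

(X_{n-1} is X_1 itself for n = 2).  In this default variant the monomer pool
is depleted only by chain extension — dimer formation proceeds as if the
bath kept the monomer density topped up during drying — which yields the
model's characteristic results: dimers through hexamers after a single
dehydration, and 10-mers only after more than ten cycles.  The strictly
stoichiometric closed-surface variant (``mass_conserving=True``) adds a
factor-2 dimerization loss, -k X_1 (2 X_1 + sum_{n>=2} X_n), under which the
monomer-unit mass sum_n n X_n is exactly conserved during a dehydration;
that variant is the deterministic counterpart of the Gillespie twin below.
A wetting step then releases a fraction (default 5%) of every chain of
length >= 2 into solution and repopulates the surface with monomers from an
infinite amino-acid bath, restoring the total population to capacity.  One
dehydration + wetting round is a wetting-drying cycle.

A seeded Gillespie stochastic twin of the dehydration phase serves as an
independent cross-check of the deterministic integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "KineticState",
    "CycleLedger",
    "dehydration_phase",
    "wetting_step",
    "run_cycles",
    "gillespie_dehydration",
]


@dataclass(frozen=True)
class KineticParams:
    """Model constants: capacity, rate, desorption, truncation, tolerances."""

    capacity: float = 100.0
    k: float = 1.0
    desorb_fraction: float = 0.05
    n_max: int = 64
    threshold: float = 1.0  # "significant amount": 1% of default capacity
    x1_tol: float = 1e-6
    rtol: float = 1e-9
    atol: float = 1e-12
    mass_conserving: bool = False

    def validate(self) -> None:
        if self.capacity <= 0 or self.k <= 0 or self.n_max < 2:
            raise ValueError("capacity, k must be positive and n_max >= 2")
        if not 0.0 <= self.desorb_fraction <= 1.0:
            raise ValueError("desorb_fraction must lie in [0, 1]")
        if self.x1_tol <= 0:
            raise ValueError("x1_tol must be positive")


@dataclass
class KineticState:
    """Surface concentrations X[n-1] = [X_n] plus the release ledger."""

    x: np.ndarray
    released: np.ndarray
    cycle_index: int = 0

    @classmethod
    def initial(cls, params: KineticParams) -> "KineticState":
        x = np.zeros(params.n_max)
        x[0] = params.capacity
        return cls(x, np.zeros(params.n_max))

    @property
    def monomer_units(self) -> float:
        """Total monomer-unit mass on the surface, sum_n n*X_n."""
        return float(np.arange(1, len(self.x) + 1) @ self.x)

    @property
    def total_population(self) -> float:
        return float(self.x.sum())

    def copy(self) -> "KineticState":
        return KineticState(self.x.copy(), self.released.copy(), self.cycle_index)


def _rhs(params: KineticParams):
    k = params.k

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        x1 = x[0]
        dx = np.empty_like(x)
        dimer_loss = 2.0 * x1 if params.mass_conserving else 0.0
        dx[0] = -k * x1 * (dimer_loss + x[1:].sum())
        # dX_n = k X1 (X_{n-1} - X_n); X_{n-1} for n=2 is X_1 itself
        dx[1:] = k * x1 * (x[:-1] - x[1:])
        return dx

    return rhs


def dehydration_phase(
    state: KineticState, params: KineticParams | None = None, tol: float | None = None
) -> KineticState:
    """Integrate chain extension until the monomers are exhausted.

    Uses a stiff-safe adaptive integrator (LSODA) and stops at the event
    X_1 < ``tol`` (default ``params.x1_tol``) — the practical reading of
    "reactions stop when [X_1] = 0", which an ODE only reaches
    asymptotically.  With ``mass_conserving=True`` the monomer-unit mass is
    conserved to integrator tolerance.  Tiny negative concentrations from
    roundoff are clipped to zero.
    """
    params = params or KineticParams()
    params.validate()
    tol = params.x1_tol if tol is None else tol
    if tol <= 0:
        raise ValueError("tol must be positive")
    if state.x[0] <= tol:
        return state.copy()

    def exhausted(_t: float, x: np.ndarray) -> float:
        return x[0] - tol

    exhausted.terminal = True
    exhausted.direction = -1
    # conservative horizon: the slowest decay scale is ~1/(k * capacity)
    t_end = 1e4 / (params.k * max(params.capacity, 1.0))
    sol = solve_ivp(
        _rhs(params),
        (0.0, t_end),
        state.x,
        method="LSODA",
        events=exhausted,
        rtol=params.rtol,
        atol=params.atol,
    )
    if not sol.success or sol.t_events[0].size == 0:
        raise RuntimeError(
            f"dehydration failed to converge (status {sol.status}); "
            f"final state {sol.y[:, -1]}"
        )
    x = np.clip(sol.y[:, -1], 0.0, None)
    overflow = x[-1]
    if overflow > 1e-9 * params.capacity:
        raise RuntimeError(
            f"chain-length truncation overflow: X[{params.n_max}] = {overflow:g}; "
            "increase n_max"
        )
    return KineticState(x, state.released.copy(), state.cycle_index)


def wetting_step(state: KineticState, params: KineticParams | None = None) -> KineticState:
    """Release peptides and repopulate the surface with monomers.

    Every chain of length >= 2 desorbs a fraction ``desorb_fraction`` (added
    to the cumulative release ledger); the freed plus pre-existing vacancies
    are refilled with monomers from the infinite solution bath, restoring the
    total surface population to ``capacity``.
    """
    params = params or KineticParams()
    params.validate()
    x = state.x.copy()
    released = state.released.copy()
    d = params.desorb_fraction
    released[1:] += d * x[1:]
    x[1:] *= 1.0 - d
    x[0] += params.capacity - x.sum()
    return KineticState(x, released, state.cycle_index + 1)


@dataclass
class CycleLedger:
    """Per-cycle record of surface distributions and released material.

    ``surface[c]`` is the converged distribution after dehydration of cycle
    c+1 (before that cycle's wetting); ``released_cum[c]`` the cumulative
    released amounts after its wetting step.  ``first_cycle[n-1]`` is the
    first cycle at which the converged X_n reached the significance
    threshold (0 = never).
    """

    surface: np.ndarray
    released_cum: np.ndarray
    first_cycle: np.ndarray
    params: KineticParams

    def to_frame(self) -> pd.DataFrame:
        n_cycles, n_max = self.surface.shape
        return pd.DataFrame(
            self.surface,
            index=pd.Index(np.arange(1, n_cycles + 1), name="cycle"),
            columns=[f"X{n}" for n in range(1, n_max + 1)],
        )

    def longest_significant(self, cycle: int = 1) -> int:
        """Longest chain length whose converged concentration reached the
        threshold at the given (1-based) cycle."""
        sig = np.flatnonzero(self.surface[cycle - 1] >= self.params.threshold)
        return int(sig[-1] + 1) if sig.size else 0


def run_cycles(n_cycles: int, params: KineticParams | None = None) -> CycleLedger:
    """Alternate dehydration and wetting for ``n_cycles`` cycles.

    Records the converged surface distribution of every cycle, the cumulative
    released amounts, and the first cycle at which each chain length reached
    the significance threshold.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    params = params or KineticParams()
    params.validate()
    state = KineticState.initial(params)
    surface = np.zeros((n_cycles, params.n_max))
    released = np.zeros((n_cycles, params.n_max))
    first = np.zeros(params.n_max, dtype=int)
    for c in range(1, n_cycles + 1):
        state = dehydration_phase(state, params)
        surface[c - 1] = state.x
        newly = (first == 0) & (state.x >= params.threshold)
        first[newly] = c
        state = wetting_step(state, params)
        released[c - 1] = state.released
    return CycleLedger(surface, released, first, params)


# ---------------------------------------------------------------------------
# stochastic twin
# ---------------------------------------------------------------------------

def gillespie_dehydration(
    params: KineticParams | None = None,
    n_runs: int = 1000,
    rng_seed: int = 0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie realizations of one dehydration phase.

    Discrete molecules with propensities a_dim = k n_1 (n_1 - 1) for
    dimerization (consuming two monomers) and a_n = k n_1 n_x for extension of
    each chain of length n >= 2, run until the monomers are exhausted — the
    stochastic counterpart of the mass-conserving ODE.  Returns the per-length
    ensemble mean and its Monte-Carlo standard error.
    """
    params = params or KineticParams()
    params.validate()
    rng = np.random.default_rng(rng_seed)
    n_max = params.n_max
    if x0 is None:
        x0 = np.zeros(n_max)
        x0[0] = params.capacity
    init = np.rint(x0).astype(int)
    results = np.zeros((n_runs, n_max))
    for r in range(n_runs):
        n = init.copy()
        while n[0] > 0:
            n1 = n[0]
            a = params.k * n1 * n[1:].astype(float)
            a_dim = params.k * n1 * (n1 - 1)
            total = a_dim + a.sum()
            if total <= 0:
                break
            u = rng.random() * total
            if u < a_dim:
                n[0] -= 2
                n[1] += 1
            else:
                j = int(np.searchsorted(np.cumsum(a), u - a_dim, side="right"))
                if j + 2 >= n_max:
                    raise RuntimeError("chain grew past n_max in a Gillespie run")
                n[0] -= 1
                n[j + 1] -= 1
                n[j + 2] += 1
        results[r] = n
    mean = results.mean(axis=0)
    se = results.std(axis=0, ddof=1) / np.sqrt(n_runs)
    return mean, se
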
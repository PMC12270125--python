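"""Quantitative ensemble: pedigree-resampled parameter sets, persistence
screening, and press-perturbed biomass dynamics.

Each ensemble member is a parameter set drawn uniformly around the base
values (half-width = pedigree fraction).  Members are compiled into a
dynamic model with foraging-arena consumption

    Q_ij(B) = Q0_ij · V·b_i·b_j / (V − 1 + b_j),   b = B/B0,  V = 2

(calibrated so Q(B0) = Q0), saturating producer growth, and background
mortality ``M0_i = PB_i·(1 − EE_i)`` — with EE taken from the *base*
model's balance, so perturbed parameter sets are genuinely off-balance
and may crash, which is what the 50-year persistence filter screens for.
Zero-pedigree members reproduce the base model and sit at its fixed point.

Integration is fixed-step RK4 at a monthly step.  A press either ramps a
group's biomass to ±10% of its baseline reference over ten years and
holds it (forced biomass), or scales fishing effort the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .foodweb import FoodWeb, Role, mass_balance
from .qnm import PressScenario, ResponseTally

__all__ = [
    "ParameterSet",
    "ForcingSpec",
    "Trajectory",
    "BaselineReference",
    "RunOutcome",
    "DynamicModel",
    "sample_parameter_set",
    "simulate_dynamics",
    "persistence_filter",
    "run_baseline",
    "run_press",
    "ensemble_tally",
    "EnsembleError",
]

VULNERABILITY = 2.0
DT = 1.0 / 12.0
PERSIST_FRACTION = 1e-4
PCT_CUTOFF = 0.02


class EnsembleError(RuntimeError):
    pass


@dataclass(frozen=True)
class ParameterSet:
    """One resampled realization of the web's uncertain parameters."""

    web: FoodWeb
    biomass: np.ndarray
    pb: np.ndarray
    qb: np.ndarray
    diet: np.ndarray
    seed: int | None = None


@dataclass(frozen=True)
class ForcingSpec:
    """Press forcing: override a group's biomass or scale fleet effort.

    ``fraction`` is the signed relative change (e.g. +0.10); the forcing
    ramps linearly from 0 to ``fraction`` over ``ramp_years`` and is then
    held for the rest of the run.  ``reference`` is the biomass the forced
    group is pinned to at ramp start (biomass mode only).
    """

    target: str
    mode: str  # "biomass" | "effort"
    fraction: float
    ramp_years: float = 10.0
    reference: float = math.nan

    def __post_init__(self):
        if self.mode not in ("biomass", "effort"):
            raise ValueError(f"forcing mode must be 'biomass' or 'effort', got {self.mode!r}")

    def multiplier(self, t: float) -> float:
        ramp = min(t / self.ramp_years, 1.0) if self.ramp_years > 0 else 1.0
        return 1.0 + self.fraction * ramp


@dataclass
class Trajectory:
    times: np.ndarray  # years, monthly
    biomass: np.ndarray  # (n_steps + 1, n_groups)
    catch: np.ndarray  # (n_steps + 1, n_groups), t·km⁻²·yr⁻¹
    persistent: bool
    names: tuple[str, ...]

    def mean_over(self, t0: float, t1: float) -> np.ndarray:
        m = (self.times >= t0) & (self.times <= t1)
        return self.biomass[m].mean(axis=0)

    def mean_catch_over(self, t0: float, t1: float) -> np.ndarray:
        m = (self.times >= t0) & (self.times <= t1)
        return self.catch[m].mean(axis=0)


@dataclass(frozen=True)
class BaselineReference:
    """Reference points from an unforced 100-year run."""

    biomass: np.ndarray  # per group, mean over final ten years
    fleet_catch: float  # summed mean catch over final ten years
    persistent: bool


@dataclass(frozen=True)
class RunOutcome:
    """Per-element percent differences vs baseline and their sign classes."""

    elements: tuple[str, ...]
    pct: np.ndarray
    sign: np.ndarray  # int in {−1, 0, +1}
    persistent: bool


# ---------------------------------------------------------------------------


def sample_parameter_set(
    web: FoodWeb, rng: np.random.Generator | int | None = None
) -> ParameterSet:
    """Draw biomass, P/B, Q/B and diet uniformly around base values.

    Each parameter θ with pedigree p is drawn from U(θ(1−p), θ(1+p));
    diet columns are perturbed entry-wise by the predator's diet pedigree
    and re-normalized.  Zero pedigrees leave values untouched.
    """
    rng = np.random.default_rng(rng)
    ped = web.pedigree

    def draw(base: np.ndarray, p: np.ndarray) -> np.ndarray:
        out = base.copy()
        active = (p > 0) & np.isfinite(base)
        u = rng.uniform(-1.0, 1.0, size=base.shape)
        out[active] = base[active] * (1.0 + p[active] * u[active])
        return out

    biomass = draw(web.biomass, ped.biomass)
    pb = draw(web.pb, ped.pb)
    qb = draw(web.qb, ped.qb)

    diet = web.diet.copy()
    consumers = np.flatnonzero(web.mask(Role.CONSUMER))
    for j in consumers:
        p = ped.diet[j]
        if p <= 0:
            continue
        col = diet[:, j]
        jitter = 1.0 + p * rng.uniform(-1.0, 1.0, size=col.shape)
        col = col * jitter
        s = col.sum()
        diet[:, j] = col / s if s > 0 else web.diet[:, j]

    return ParameterSet(web=web, biomass=biomass, pb=pb, qb=qb, diet=diet)


def base_parameter_set(web: FoodWeb) -> ParameterSet:
    return ParameterSet(
        web=web,
        biomass=web.biomass,
        pb=web.pb,
        qb=web.qb,
        diet=web.diet.copy(),
    )


class DynamicModel:
    """Compiled ODE system for one parameter set."""

    def __init__(self, ps: ParameterSet):
        web = ps.web
        self.web = web
        self.names = web.names
        n = web.n
        self.n = n

        self.living = web.mask(Role.PRODUCER, Role.CONSUMER)
        self.producers = web.mask(Role.PRODUCER)
        self.consumers = web.mask(Role.CONSUMER)
        self.detritus = web.mask(Role.DETRITUS)
        self.fleet = web.mask(Role.FLEET)
        self.dynamic = ~self.fleet  # state variables

        self.B0 = np.where(self.fleet, 1.0, ps.biomass)
        self.pb = ps.pb
        self.qb = ps.qb

        # growth efficiency & base consumption rates from the resampled set
        self.GE = np.zeros(n)
        self.GE[self.consumers] = ps.pb[self.consumers] / ps.qb[self.consumers]
        self.Q0 = np.zeros((n, n))
        cons = np.flatnonzero(self.consumers)
        self.Q0[:, cons] = ps.diet[:, cons] * (ps.biomass[cons] * ps.qb[cons])

        # background mortality uses the BASE model's EE: off-balance
        # parameter draws then drift and can crash (persistence screen)
        base_ee = mass_balance(web, check=False).ee
        self.M0 = np.zeros(n)
        self.M0[self.living] = ps.pb[self.living] * (1.0 - base_ee[self.living])

        self.F = np.zeros(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = web.catch / self.B0
        self.F[self.living] = f[self.living]

        self.unassim = web.unassim

        # detritus fate: flows split across pools ∝ base pool biomass;
        # linear export calibrated so detritus starts at steady state
        det = np.flatnonzero(self.detritus)
        self.det_share = np.zeros(n)
        if det.size:
            w = self.B0[det]
            self.det_share[det] = w / w.sum()
        self.export_rate = np.zeros(n)
        if det.size:
            Q_base = self._consumption(self.B0)
            inflow0 = self._detritus_inflow(self.B0, Q_base)
            cons0 = Q_base.sum(axis=1)
            self.export_rate[det] = (inflow0[det] - cons0[det]) / self.B0[det]

        # stiffness estimate for integrator sub-stepping: near-equilibrium
        # self-rates are ≈ PB/2 + F for living groups, turnover for detritus
        rates = [0.0]
        liv = np.flatnonzero(self.living)
        if liv.size:
            rates.append(float((self.pb[liv] / 2.0 + self.F[liv]).max()))
        if det.size:
            cons_rate = Q_base.sum(axis=1)[det] / self.B0[det]
            rates.append(float((np.abs(self.export_rate[det]) + cons_rate).max()))
        self.rate_scale = max(rates)

    # -- pieces -------------------------------------------------------------

    def _consumption(self, B: np.ndarray) -> np.ndarray:
        """Foraging-arena consumption matrix Q[prey, predator] at state B."""
        b = np.divide(B, self.B0, out=np.ones_like(B), where=self.B0 > 0)
        V = VULNERABILITY
        denom = V - 1.0 + b[None, :]
        return self.Q0 * (V * b[:, None] * b[None, :]) / denom

    def _detritus_inflow(self, B: np.ndarray, Q: np.ndarray) -> np.ndarray:
        total = (self.unassim * Q.sum(axis=0)).sum() + (self.M0 * B * self.living).sum()
        return self.det_share * total

    def derivatives(self, B: np.ndarray, effort_mult: float = 1.0) -> np.ndarray:
        Q = self._consumption(B)
        predation = Q.sum(axis=1)
        intake = Q.sum(axis=0)
        F = self.F * effort_mult

        dB = np.zeros(self.n)
        p = self.producers
        b = np.divide(B, self.B0, out=np.ones_like(B), where=self.B0 > 0)
        dB[p] = (
            self.pb[p] * B[p] * 2.0 / (1.0 + b[p])
            - predation[p]
            - self.M0[p] * B[p]
            - F[p] * B[p]
        )
        c = self.consumers
        dB[c] = (
            self.GE[c] * intake[c]
            - predation[c]
            - self.M0[c] * B[c]
            - F[c] * B[c]
        )
        d = self.detritus
        dB[d] = self._detritus_inflow(B, Q)[d] - predation[d] - self.export_rate[d] * B[d]
        return dB

    def catch_rates(self, B: np.ndarray, effort_mult: float = 1.0) -> np.ndarray:
        return self.F * effort_mult * B

    # -- integration --------------------------------------------------------

    def run(
        self,
        years: float,
        forcing: ForcingSpec | None = None,
        dt: float = DT,
        b_init: np.ndarray | None = None,
    ) -> Trajectory:
        n_steps = int(round(years / dt))
        times = np.arange(n_steps + 1) * dt
        B = self.B0.copy() if b_init is None else np.asarray(b_init, float).copy()
        B[self.fleet] = 0.0

        forced_idx = None
        effort_forced = False
        if forcing is not None:
            forced_idx = self.names.index(forcing.target)
            effort_forced = forcing.mode == "effort"
            if not effort_forced:
                ref = forcing.reference
                if not np.isfinite(ref):
                    ref = self.B0[forced_idx]

        bio = np.empty((n_steps + 1, self.n))
        cat = np.empty((n_steps + 1, self.n))
        persistent = True
        floor = PERSIST_FRACTION * self.B0

        def effort_at(t: float) -> float:
            if forcing is not None and effort_forced:
                return forcing.multiplier(t)
            return 1.0

        def clamp(state: np.ndarray, t: float) -> np.ndarray:
            if forcing is not None and not effort_forced:
                state = state.copy()
                state[forced_idx] = ref * forcing.multiplier(t)
            return state

        B = clamp(B, 0.0)
        bio[0] = B
        cat[0] = self.catch_rates(B, effort_at(0.0))

        # keep |λ|·h comfortably inside the RK4 stability region
        n_sub = max(1, int(np.ceil(self.rate_scale * dt / 1.2)))
        h = dt / n_sub
        ceiling = 1e9 * np.where(self.B0 > 0, self.B0, 1.0)

        def f(state: np.ndarray, tt: float) -> np.ndarray:
            dB = self.derivatives(clamp(state, tt), effort_at(tt))
            if forced_idx is not None and not effort_forced:
                dB[forced_idx] = 0.0
            return dB

        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for k in range(n_steps):
                for s in range(n_sub):
                    t = k * dt + s * h
                    k1 = f(B, t)
                    k2 = f(B + 0.5 * h * k1, t + 0.5 * h)
                    k3 = f(B + 0.5 * h * k2, t + 0.5 * h)
                    k4 = f(B + h * k3, t + h)
                    B = B + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                B = clamp(B, (k + 1) * dt)

                blown = not np.all(np.isfinite(B[self.dynamic])) or np.any(
                    B[self.dynamic] > ceiling[self.dynamic]
                )
                if blown:
                    persistent = False
                    times = times[: k + 2]
                    bio = bio[: k + 2]
                    cat = cat[: k + 2]
                    bio[k + 1] = np.nan
                    cat[k + 1] = np.nan
                    break
                B = np.maximum(B, 0.0)
                if np.any(B[self.dynamic] < floor[self.dynamic]):
                    persistent = False
                bio[k + 1] = B
                cat[k + 1] = self.catch_rates(B, effort_at((k + 1) * dt))

        return Trajectory(
            times=times, biomass=bio, catch=cat, persistent=persistent, names=self.names
        )


# ---------------------------------------------------------------------------


def simulate_dynamics(
    ps: ParameterSet,
    years: float,
    forcing: ForcingSpec | None = None,
    dt: float = DT,
) -> Trajectory:
    return DynamicModel(ps).run(years, forcing=forcing, dt=dt)


def persistence_filter(
    ensemble: list[ParameterSet], years: float = 50.0, dt: float = DT
) -> tuple[list[ParameterSet], dict]:
    """Keep parameter sets whose unforced run persists for ``years``.

    Returns the plausible subset (draw order preserved) and attrition stats.
    """
    kept = []
    for ps in ensemble:
        if simulate_dynamics(ps, years, dt=dt).persistent:
            kept.append(ps)
    stats = {
        "n_drawn": len(ensemble),
        "n_plausible": len(kept),
        "rate": len(kept) / len(ensemble) if ensemble else float("nan"),
    }
    return kept, stats


def run_baseline(ps: ParameterSet, years: float = 100.0, dt: float = DT) -> BaselineReference:
    """Unforced reference run; means over the final ten years."""
    traj = simulate_dynamics(ps, years, dt=dt)
    if not traj.persistent:
        return BaselineReference(
            biomass=np.full(ps.web.n, np.nan), fleet_catch=math.nan, persistent=False
        )
    ref_b = traj.mean_over(years - 10.0, years)
    ref_c = float(traj.mean_catch_over(years - 10.0, years).sum())
    return BaselineReference(biomass=ref_b, fleet_catch=ref_c, persistent=True)


def _classify(pct: np.ndarray, cutoff: float = PCT_CUTOFF) -> np.ndarray:
    sign = np.zeros(len(pct), dtype=int)
    sign[pct > cutoff] = 1
    sign[pct < -cutoff] = -1
    return sign


def run_press(
    ps: ParameterSet,
    scenario: PressScenario,
    baseline: BaselineReference | None = None,
    years: float = 100.0,
    ramp_years: float = 10.0,
    fraction: float = 0.10,
    dt: float = DT,
) -> RunOutcome:
    """One perturbed run vs its baseline; ±2% cutoff sign classes.

    A press on the fleet scales effort; any other target pins that group's
    biomass with a ten-year ramp to ±10% of its baseline reference.
    """
    web = ps.web
    if baseline is None:
        baseline = run_baseline(ps, years=years, dt=dt)
    n = web.n
    if not baseline.persistent:
        return RunOutcome(
            elements=web.names,
            pct=np.full(n, np.nan),
            sign=np.zeros(n, dtype=int),
            persistent=False,
        )

    target_idx = web.index(scenario.element)
    is_fleet = web.groups[target_idx].role == Role.FLEET
    forcing = ForcingSpec(
        target=scenario.element,
        mode="effort" if is_fleet else "biomass",
        fraction=scenario.direction * fraction,
        ramp_years=ramp_years,
        reference=math.nan if is_fleet else float(baseline.biomass[target_idx]),
    )
    traj = simulate_dynamics(ps, years, forcing=forcing, dt=dt)
    if not traj.persistent:
        return RunOutcome(
            elements=web.names,
            pct=np.full(n, np.nan),
            sign=np.zeros(n, dtype=int),
            persistent=False,
        )

    mean_b = traj.mean_over(years - 10.0, years)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = (mean_b - baseline.biomass) / baseline.biomass
    fleet = web.mask(Role.FLEET)
    if fleet.any():
        pert_catch = float(traj.mean_catch_over(years - 10.0, years).sum())
        if baseline.fleet_catch > 0:
            pct[fleet] = (pert_catch - baseline.fleet_catch) / baseline.fleet_catch
        else:
            pct[fleet] = 0.0
    pct = np.where(np.isfinite(pct), pct, 0.0)
    return RunOutcome(elements=web.names, pct=pct, sign=_classify(pct), persistent=True)


def ensemble_tally(
    web: FoodWeb,
    scenario: PressScenario,
    n_members: int = 1000,
    rng: np.random.Generator | int | None = None,
    max_draws: int = 40_000,
    filter_years: float = 50.0,
    run_years: float = 100.0,
    dt: float = DT,
) -> ResponseTally:
    """Draw plausible parameter sets and tally press-response sign classes."""
    rng = np.random.default_rng(rng)
    tally = ResponseTally.zeros(web.names)
    accepted = 0
    draws = 0
    excluded = 0
    while accepted < n_members:
        if draws >= max_draws:
            raise EnsembleError(
                f"exceeded {max_draws} draws with only {accepted} plausible "
                f"parameter sets (plausibility rate {accepted / draws:.2e})"
            )
        ps = sample_parameter_set(web, rng)
        draws += 1
        if not simulate_dynamics(ps, filter_years, dt=dt).persistent:
            continue
        accepted += 1
        baseline = run_baseline(ps, years=run_years, dt=dt)
        if not baseline.persistent:
            excluded += 1
            continue
        outcome = run_press(ps, scenario, baseline=baseline, years=run_years, dt=dt)
        if not outcome.persistent:
            excluded += 1
            continue
        tally.add(outcome.sign)
    tally.acceptance_rate = accepted / draws
    tally.n_excluded = excluded
    return tally
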
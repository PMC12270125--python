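"""Synthetic balanced food webs and the transcribed shelf-model fixture loader.

The generator emulates the statistical shape of the 28-element shelf
model the pipeline was built around: a handful of primary producers, one
detritus pool, exactly one fishing fleet, Dirichlet diet columns over
lower trophic levels, biomasses spanning orders of magnitude, and
per-parameter pedigree fractions.  Webs are balanced by construction
(biomasses are rescaled until every ecotrophic efficiency is at or below
the target), so every downstream stage can run on them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .foodweb import (
    FoodWeb,
    FunctionalGroup,
    Pedigree,
    Role,
    mass_balance,
    read_web,
    validate_web,
)

__all__ = ["WebSpec", "generate_foodweb", "load_wss28", "GenerationError"]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class WebSpec:
    """Recipe for a random balanced web (deterministic under ``seed``)."""

    n_groups: int = 28  # total elements, detritus and fleet included
    n_trophic_levels: int = 4  # producer level + consumer levels
    connectance: float = 0.5  # fraction of permitted prey links realized
    target_ee_max: float = 0.95
    pedigree_profile: dict = field(
        default_factory=lambda: {"biomass": 0.1, "pb": 0.1, "qb": 0.1, "diet": 0.1}
    )
    unassimilated_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 4:
            raise ValueError("need at least 4 elements: producer, consumer, detritus, fleet")
        if self.n_trophic_levels < 2:
            raise ValueError("need at least 2 trophic levels")
        if not 0 < self.connectance <= 1:
            raise ValueError("connectance must be in (0, 1]")
        if self.target_ee_max > 0.999:
            raise ValueError("target_ee_max too close to 1 to balance reliably")


def generate_foodweb(spec: WebSpec) -> FoodWeb:
    """Generate a balanced random web following ``spec``.

    Raises :class:`GenerationError` if iterative biomass rescaling fails
    to bring all ecotrophic efficiencies under the target within 100
    rounds (try a lower connectance or fewer levels).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_groups
    n_bio = n - 2  # minus detritus and fleet
    n_prod = max(1, round(n_bio * 0.15))
    n_cons = n_bio - n_prod
    if n_cons < 1:
        raise ValueError("spec leaves no room for a consumer")

    # trophic level per group: producers/detritus at 1, consumers at 2..L
    levels = np.empty(n, dtype=int)
    roles = np.empty(n, dtype=object)
    names = []
    for i in range(n_prod):
        names.append(f"Producer{i + 1}")
        roles[i] = Role.PRODUCER
        levels[i] = 1
    # contiguous consumer levels 2..L so every level has prey just below it
    max_level = min(spec.n_trophic_levels, n_cons + 1)
    cons_levels = np.concatenate(
        [
            np.arange(2, max_level + 1),
            rng.integers(2, max_level + 1, size=n_cons - (max_level - 1)),
        ]
    )
    cons_levels = np.sort(cons_levels)
    for k, lv in enumerate(cons_levels):
        i = n_prod + k
        names.append(f"Consumer{k + 1}_L{lv}")
        roles[i] = Role.CONSUMER
        levels[i] = lv
    names.append("Detritus")
    roles[n - 2] = Role.DETRITUS
    levels[n - 2] = 1
    names.append("Fleet")
    roles[n - 1] = Role.FLEET
    levels[n - 1] = 0

    # rate parameters: P/B and biomass fall off with trophic level
    biomass = np.full(n, np.nan)
    pb = np.full(n, np.nan)
    qb = np.full(n, np.nan)
    for i in range(n):
        if roles[i] == Role.PRODUCER:
            # modest turnover keeps the monthly integrator well-conditioned
            pb[i] = rng.uniform(10.0, 25.0)
            biomass[i] = 10 ** rng.uniform(0.8, 1.5)
        elif roles[i] == Role.CONSUMER:
            lv = levels[i]
            pb[i] = 5.0 * 0.35 ** (lv - 2) * np.exp(rng.normal(0.0, 0.3))
            qb[i] = pb[i] / rng.uniform(0.15, 0.3)
            biomass[i] = 10 ** rng.uniform(1.2 - lv, 2.2 - lv)
        elif roles[i] == Role.DETRITUS:
            biomass[i] = 10 ** rng.uniform(0.8, 1.5)

    # Dirichlet diet columns over permitted lower-level prey
    diet = np.zeros((n, n))
    for j in range(n):
        if roles[j] != Role.CONSUMER:
            continue
        lower = [
            i
            for i in range(n)
            if roles[i] in (Role.PRODUCER, Role.CONSUMER, Role.DETRITUS)
            and levels[i] < levels[j]
        ]
        chosen = [i for i in lower if rng.random() < spec.connectance]
        just_below = [i for i in lower if levels[i] == levels[j] - 1]
        if not any(i in chosen for i in just_below):
            chosen.append(int(rng.choice(just_below)))
        chosen = sorted(set(chosen))
        weights = rng.dirichlet(np.ones(len(chosen)))
        diet[chosen, j] = weights

    catch = np.zeros(n)

    groups = tuple(
        FunctionalGroup(
            name=names[i],
            role=roles[i],
            biomass=biomass[i],
            pb=pb[i],
            qb=qb[i],
            unassimilated_fraction=(
                spec.unassimilated_fraction if roles[i] == Role.CONSUMER else 0.0
            ),
        )
        for i in range(n)
    )
    prof = spec.pedigree_profile
    ped = Pedigree(
        biomass=np.where(roles == Role.FLEET, 0.0, prof.get("biomass", 0.0)),
        pb=np.where(
            (roles == Role.PRODUCER) | (roles == Role.CONSUMER), prof.get("pb", 0.0), 0.0
        ),
        qb=np.where(roles == Role.CONSUMER, prof.get("qb", 0.0), 0.0),
        diet=np.where(roles == Role.CONSUMER, prof.get("diet", 0.0), 0.0),
    )
    web = FoodWeb(groups=groups, diet=diet, catch=catch, pedigree=ped)

    # iterative rebalance: grow any over-demanded prey's biomass until all
    # EE sit under a pre-catch headroom target
    pre_target = 0.75 * spec.target_ee_max
    for _ in range(100):
        bal = mass_balance(web, check=False)
        living = web.mask(Role.PRODUCER, Role.CONSUMER)
        over = living & (bal.ee > pre_target)
        if not over.any():
            break
        scale = np.ones(web.n)
        scale[over] = bal.ee[over] / (0.9 * pre_target)
        groups = tuple(
            g if s == 1.0 else _with_biomass(g, g.biomass * s)
            for g, s in zip(web.groups, scale)
        )
        web = FoodWeb(groups=groups, diet=web.diet, catch=web.catch, pedigree=web.pedigree)
    else:
        raise GenerationError(
            "failed to balance in 100 rescaling rounds; try a lower connectance"
        )

    # size the detritus pool for a ~2/yr turnover of its inflows so the
    # detritus state is no stiffer than the living groups
    bal = mass_balance(web, check=False)
    living = web.mask(Role.PRODUCER, Role.CONSUMER)
    m0_flow = float(
        (web.pb[living] * (1.0 - bal.ee[living]) * web.biomass[living]).sum()
    )
    unassim_flow = float(
        (web.unassim * np.nan_to_num(web.qb) * np.nan_to_num(web.biomass)).sum()
    )
    det_idx = np.flatnonzero(roles == Role.DETRITUS)
    det_biomass = max((m0_flow + unassim_flow) / 2.0, 1.0) / det_idx.size
    groups = tuple(
        _with_biomass(g, det_biomass) if g.role == Role.DETRITUS else g
        for g in web.groups
    )
    web = FoodWeb(groups=groups, diet=web.diet, catch=web.catch, pedigree=web.pedigree)

    # fish 1–3 upper/mid consumers, spending half of the remaining EE headroom
    bal = mass_balance(web, check=False)
    top = max(levels[i] for i in range(n) if roles[i] == Role.CONSUMER)
    mid_up = [
        i
        for i in range(n)
        if roles[i] == Role.CONSUMER and levels[i] >= max(2, top - 1)
    ]
    n_fished = min(len(mid_up), int(rng.integers(1, 4)))
    fished = rng.choice(mid_up, size=n_fished, replace=False)
    catch = np.zeros(n)
    for i in fished:
        headroom = spec.target_ee_max - bal.ee[i]
        catch[i] = 0.5 * headroom * web.biomass[i] * web.pb[i]
    web = FoodWeb(groups=web.groups, diet=web.diet, catch=catch, pedigree=web.pedigree)

    issues = validate_web(web)
    if issues:  # pragma: no cover - generator contract
        raise GenerationError("generated web fails validation: " + "; ".join(map(str, issues)))
    mass_balance(web)  # raises if any EE still above 1
    return web


def _with_biomass(g: FunctionalGroup, b: float) -> FunctionalGroup:
    return FunctionalGroup(
        name=g.name,
        role=g.role,
        biomass=b,
        pb=g.pb,
        qb=g.qb,
        unassimilated_fraction=g.unassimilated_fraction,
    )


def load_wss28(path: str | Path) -> FoodWeb:
    """Load the transcribed 28-element western Scotian Shelf fixture.

    The fixture is the supplementary parameter and diet tables transcribed
    into the ``groups.csv``/``diet.csv`` dialect.  Raises a clear error if
    the transcription is absent, and validates the loaded web.
    """
    path = Path(path)
    if not path.exists() or not (path / "groups.csv").exists():
        raise FileNotFoundError(
            f"fixture not transcribed: {path} does not contain groups.csv/diet.csv; "
            "transcribe the supplementary parameter and diet tables there, or "
            "configure a synthetic web instead"
        )
    web = read_web(path)
    issues = validate_web(web)
    if issues:
        raise ValueError("fixture invalid: " + "; ".join(str(d) for d in issues))
    mass_balance(web)  # raises UnbalancedWebError if any EE > 1
    return web
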
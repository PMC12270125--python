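"""Mass-balanced food-web data model.

A :class:`FoodWeb` holds the static snapshot of an Ecopath-style model:
functional groups with biomass (``B``, t·km⁻²), production/biomass (``PB``,
yr⁻¹), consumption/biomass (``QB``, yr⁻¹), a diet-composition matrix,
landings per group, and per-parameter data-pedigree uncertainty fractions.

:func:`mass_balance` solves the standard balance identity

    B_i · PB_i · EE_i = Σ_j B_j · QB_j · DC[i, j] + catch_i

for the ecotrophic efficiency ``EE`` of every producer/consumer group and
additionally expresses each mortality component as a proportion of the
group's total mortality rate (taken as ``PB``, the Ecopath convention):
``m2prop[i, j] = M2_ij / PB_i`` and ``fprop[i] = F_i / PB_i``.

Biomass accumulation, migration and imports are assumed zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "FunctionalGroup",
    "FoodWeb",
    "BalanceResult",
    "Diagnostic",
    "UnbalancedWebError",
    "mass_balance",
    "validate_web",
    "read_web",
    "write_web",
]

DIET_SUM_TOL = 1e-9
EE_TOL = 1e-6

#: valid values for :attr:`FunctionalGroup.role`
ROLES = ("producer", "consumer", "detritus", "fleet")


class Role:
    PRODUCER = "producer"
    CONSUMER = "consumer"
    DETRITUS = "detritus"
    FLEET = "fleet"


class UnbalancedWebError(ValueError):
    """Raised when a group's ecotrophic efficiency exceeds 1."""

    def __init__(self, group: str, ee: float):
        self.group = group
        self.ee = ee
        super().__init__(f"unbalanced web: group {group!r} has EE = {ee:.6g} > 1")


@dataclass(frozen=True)
class FunctionalGroup:
    """One model element: producer, consumer, detritus pool or fishing fleet."""

    name: str
    role: str
    biomass: float = math.nan  # t·km⁻²; NaN for fleet
    pb: float = math.nan  # production/biomass, yr⁻¹
    qb: float = math.nan  # consumption/biomass, yr⁻¹ (consumers only)
    unassimilated_fraction: float = 0.2  # consumers only

    @property
    def is_living(self) -> bool:
        return self.role in (Role.PRODUCER, Role.CONSUMER)


@dataclass(frozen=True)
class Pedigree:
    """Per-parameter uncertainty fractions in [0, 1] (uniform prior half-widths)."""

    biomass: np.ndarray
    pb: np.ndarray
    qb: np.ndarray
    diet: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "biomass": self.biomass,
            "pb": self.pb,
            "qb": self.qb,
            "diet": self.diet,
        }


@dataclass(frozen=True)
class FoodWeb:
    """Ordered groups plus diet matrix, catches and pedigrees.

    ``diet[i, j]`` is the proportion of consumer ``j``'s diet made up of
    prey ``i``; columns of consumers sum to 1.  The matrix is indexed over
    *all* groups (fleet rows/columns are zero — the fleet's "diet" is the
    catch-composition vector, derived from ``catch``).
    """

    groups: tuple[FunctionalGroup, ...]
    diet: np.ndarray
    catch: np.ndarray
    pedigree: Pedigree

    def __post_init__(self):
        object.__setattr__(self, "diet", np.asarray(self.diet, dtype=float))
        object.__setattr__(self, "catch", np.asarray(self.catch, dtype=float))

    # -- indexing helpers ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no group named {name!r}") from None

    def roles(self) -> np.ndarray:
        return np.array([g.role for g in self.groups])

    def mask(self, *roles: str) -> np.ndarray:
        r = self.roles()
        out = np.zeros(self.n, dtype=bool)
        for role in roles:
            out |= r == role
        return out

    @property
    def biomass(self) -> np.ndarray:
        return np.array([g.biomass for g in self.groups])

    @property
    def pb(self) -> np.ndarray:
        return np.array([g.pb for g in self.groups])

    @property
    def qb(self) -> np.ndarray:
        return np.array([g.qb for g in self.groups])

    @property
    def unassim(self) -> np.ndarray:
        return np.array(
            [
                g.unassimilated_fraction if g.role == Role.CONSUMER else 0.0
                for g in self.groups
            ]
        )

    def catch_shares(self) -> np.ndarray:
        """Catch-composition vector (the fleet's pseudo-diet)."""
        total = self.catch.sum()
        if total <= 0:
            return np.zeros(self.n)
        return self.catch / total

    def permuted(self, order: np.ndarray) -> "FoodWeb":
        """Return the same web with groups relabelled by ``order``."""
        order = np.asarray(order)
        ped = self.pedigree
        return FoodWeb(
            groups=tuple(self.groups[i] for i in order),
            diet=self.diet[np.ix_(order, order)],
            catch=self.catch[order],
            pedigree=Pedigree(
                biomass=ped.biomass[order],
                pb=ped.pb[order],
                qb=ped.qb[order],
                diet=ped.diet[order],
            ),
        )


@dataclass(frozen=True)
class BalanceResult:
    """Solved mass-balance quantities.

    ``ee`` is NaN for detritus and fleet.  ``m2prop[i, j]`` is the fraction
    of prey ``i``'s total mortality (``PB_i``) attributable to predator
    ``j``; ``fprop[i]`` the fraction attributable to the fleet.
    """

    ee: np.ndarray
    m2prop: np.ndarray
    fprop: np.ndarray


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding; ``where`` is a group name or matrix cell."""

    code: str
    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.where}: {self.message}"


# ---------------------------------------------------------------------------


def mass_balance(web: FoodWeb, *, check: bool = True) -> BalanceResult:
    """Solve ecotrophic efficiencies and mortality proportions.

    Parameters
    ----------
    web:
        A validated food web.
    check:
        If true (default), raise :class:`UnbalancedWebError` when any
        living group's EE exceeds ``1 + 1e-6``.

    Raises
    ------
    UnbalancedWebError
        If ``check`` and some EE > 1.
    ValueError
        On zero/non-positive biomass of a living group.
    """
    n = web.n
    B, pb, qb = web.biomass, web.pb, web.qb
    living = web.mask(Role.PRODUCER, Role.CONSUMER)
    consumers = web.mask(Role.CONSUMER)

    if np.any(living & ~(B > 0)):
        bad = np.array(web.names)[living & ~(B > 0)]
        raise ValueError(f"non-positive biomass for group(s): {', '.join(bad)}")

    # consumption matrix: prey i eaten by consumer j, t·km⁻²·yr⁻¹
    cons = np.zeros((n, n))
    q_total = np.where(consumers, B * qb, 0.0)
    cons[:, consumers] = web.diet[:, consumers] * q_total[consumers]

    predation = cons.sum(axis=1)

    ee = np.full(n, np.nan)
    m2prop = np.zeros((n, n))
    fprop = np.zeros(n)

    prod = np.where(living, B * pb, np.nan)  # total production
    ee[living] = (predation[living] + web.catch[living]) / prod[living]
    m2prop[living, :] = cons[living, :] / prod[living][:, None]
    fprop[living] = web.catch[living] / prod[living]

    if check:
        for i in np.flatnonzero(living):
            if ee[i] > 1 + EE_TOL:
                raise UnbalancedWebError(web.names[i], ee[i])

    return BalanceResult(ee=ee, m2prop=m2prop, fprop=fprop)


def validate_web(web: FoodWeb) -> list[Diagnostic]:
    """Check all FoodWeb invariants; return one diagnostic per violation."""
    out: list[Diagnostic] = []
    n = web.n
    names = web.names

    if len(set(names)) != n:
        out.append(Diagnostic("dup-name", "<web>", "group names are not unique"))
    if web.diet.shape != (n, n):
        out.append(
            Diagnostic(
                "diet-shape",
                "<diet>",
                f"diet matrix shape {web.diet.shape} != ({n}, {n})",
            )
        )
        return out  # further checks index the matrix
    if web.catch.shape != (n,):
        out.append(Diagnostic("catch-shape", "<catch>", "catch vector length mismatch"))
        return out

    for i, g in enumerate(web.groups):
        if g.role not in ROLES:
            out.append(Diagnostic("role", g.name, f"unknown role {g.role!r}"))
            continue
        if g.role != Role.FLEET and not g.biomass > 0:
            out.append(Diagnostic("biomass", g.name, f"biomass {g.biomass} not > 0"))
        if g.is_living and not g.pb > 0:
            out.append(Diagnostic("pb", g.name, f"P/B {g.pb} not > 0"))
        if g.role == Role.CONSUMER:
            if not g.qb > 0:
                out.append(Diagnostic("qb", g.name, f"Q/B {g.qb} not > 0"))
            if not 0 <= g.unassimilated_fraction < 1:
                out.append(
                    Diagnostic(
                        "unassim",
                        g.name,
                        f"unassimilated fraction {g.unassimilated_fraction} outside [0, 1)",
                    )
                )
        colsum = web.diet[:, i].sum()
        if g.role == Role.CONSUMER and abs(colsum - 1.0) > DIET_SUM_TOL:
            out.append(
                Diagnostic("diet-sum", g.name, f"diet column sums to {colsum:.9g}, not 1")
            )
        if g.role != Role.CONSUMER and colsum > DIET_SUM_TOL:
            out.append(
                Diagnostic("diet-nonconsumer", g.name, "non-consumer has a diet column")
            )

    bad = np.argwhere((web.diet < 0) | (web.diet > 1))
    for i, j in bad:
        out.append(
            Diagnostic(
                "diet-range",
                f"({names[i]}, {names[j]})",
                f"diet entry {web.diet[i, j]:.6g} outside [0, 1]",
            )
        )
    if np.any(web.catch < 0):
        for i in np.flatnonzero(web.catch < 0):
            out.append(Diagnostic("catch", names[i], f"negative catch {web.catch[i]}"))

    n_fleet = int(web.mask(Role.FLEET).sum())
    if n_fleet != 1:
        out.append(Diagnostic("fleet", "<web>", f"expected exactly 1 fleet, found {n_fleet}"))

    for pname, vec in web.pedigree.as_dict().items():
        if np.any((vec < 0) | (vec > 1)):
            for i in np.flatnonzero((vec < 0) | (vec > 1)):
                out.append(
                    Diagnostic(
                        "pedigree", names[i], f"{pname} pedigree {vec[i]} outside [0, 1]"
                    )
                )
    return out


# ---------------------------------------------------------------------------
# CSV fixture dialect: groups.csv + diet.csv

GROUP_COLUMNS = [
    "name",
    "role",
    "biomass",
    "pb",
    "qb",
    "unassim",
    "catch",
    "pedigree_b",
    "pedigree_pb",
    "pedigree_qb",
    "pedigree_diet",
]


def read_web(directory: str | Path) -> FoodWeb:
    """Load a web from ``<dir>/groups.csv`` and ``<dir>/diet.csv``.

    ``diet.csv`` is a square matrix over the non-fleet groups (prey rows ×
    predator columns, header row and index column carry the group names).
    """
    directory = Path(directory)
    gpath, dpath = directory / "groups.csv", directory / "diet.csv"
    for p in (gpath, dpath):
        if not p.exists():
            raise FileNotFoundError(f"fixture not transcribed: missing {p}")

    gdf = pd.read_csv(gpath)
    missing = set(GROUP_COLUMNS) - set(gdf.columns)
    if missing:
        raise ValueError(f"groups.csv missing columns: {sorted(missing)}")

    groups = tuple(
        FunctionalGroup(
            name=str(r["name"]),
            role=str(r["role"]),
            biomass=float(r["biomass"]) if pd.notna(r["biomass"]) else math.nan,
            pb=float(r["pb"]) if pd.notna(r["pb"]) else math.nan,
            qb=float(r["qb"]) if pd.notna(r["qb"]) else math.nan,
            unassimilated_fraction=float(r["unassim"]) if pd.notna(r["unassim"]) else 0.0,
        )
        for _, r in gdf.iterrows()
    )
    names = [g.name for g in groups]
    n = len(groups)

    ddf = pd.read_csv(dpath, index_col=0)
    ddf.index = ddf.index.astype(str)
    ddf.columns = ddf.columns.astype(str)
    nonfleet = [g.name for g in groups if g.role != Role.FLEET]
    if sorted(ddf.index) != sorted(nonfleet) or sorted(ddf.columns) != sorted(nonfleet):
        extra = set(ddf.index).symmetric_difference(nonfleet)
        raise ValueError(f"diet.csv row/column names do not match groups.csv: {sorted(extra)}")
    ddf = ddf.reindex(index=nonfleet, columns=nonfleet).fillna(0.0)

    diet = np.zeros((n, n))
    idx = [names.index(x) for x in nonfleet]
    diet[np.ix_(idx, idx)] = ddf.to_numpy(dtype=float)

    catch = gdf["catch"].fillna(0.0).to_numpy(dtype=float)
    ped = Pedigree(
        biomass=gdf["pedigree_b"].fillna(0.0).to_numpy(dtype=float),
        pb=gdf["pedigree_pb"].fillna(0.0).to_numpy(dtype=float),
        qb=gdf["pedigree_qb"].fillna(0.0).to_numpy(dtype=float),
        diet=gdf["pedigree_diet"].fillna(0.0).to_numpy(dtype=float),
    )
    return FoodWeb(groups=groups, diet=diet, catch=catch, pedigree=ped)


def write_web(web: FoodWeb, directory: str | Path) -> None:
    """Write ``groups.csv`` and ``diet.csv`` for :func:`read_web`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ped = web.pedigree
    rows = []
    for i, g in enumerate(web.groups):
        rows.append(
            {
                "name": g.name,
                "role": g.role,
                "biomass": g.biomass,
                "pb": g.pb,
                "qb": g.qb,
                "unassim": g.unassimilated_fraction if g.role == Role.CONSUMER else "",
                "catch": web.catch[i],
                "pedigree_b": ped.biomass[i],
                "pedigree_pb": ped.pb[i],
                "pedigree_qb": ped.qb[i],
                "pedigree_diet": ped.diet[i],
            }
        )
    pd.DataFrame(rows, columns=GROUP_COLUMNS).to_csv(directory / "groups.csv", index=False)

    nonfleet = [i for i, g in enumerate(web.groups) if g.role != Role.FLEET]
    names = [web.names[i] for i in nonfleet]
    sub = web.diet[np.ix_(nonfleet, nonfleet)]
    pd.DataFrame(sub, index=names, columns=names).to_csv(directory / "diet.csv")
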
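"""Stochastic press-perturbation analysis of signed digraphs.

Community matrices are drawn by assigning independent Uniform(0, 1]
magnitudes to every edge and self-loop, keeping only draws whose
eigenvalues all have negative real part, and solving the standard
press-response system ``x = −A⁻¹ p``.  Outcome signs per element are
tallied over the accepted draws.

Matrix orientation: ``A[row=target, col=source]`` — the effect of node
``i`` on node ``j`` sits at ``A[j, i]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adjacency import SignedDigraph

__all__ = [
    "PressScenario",
    "ResponseTally",
    "LowAcceptanceError",
    "sample_community_matrix",
    "is_stable",
    "press_response",
    "simulate_press",
]

ZERO_TOL = 1e-9


class LowAcceptanceError(RuntimeError):
    """Stability rejection rate too high to collect the requested samples."""

    def __init__(self, accepted: int, draws: int):
        self.accepted = accepted
        self.draws = draws
        self.rate = accepted / draws if draws else 0.0
        super().__init__(
            f"low stability acceptance: {accepted} stable of {draws} draws "
            f"(rate {self.rate:.2e})"
        )


@dataclass(frozen=True)
class PressScenario:
    """A sustained press on one element in one direction (+1 or −1)."""

    element: str
    direction: int

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")


@dataclass
class ResponseTally:
    """Per-element counts of positive/negative/neutral outcomes."""

    elements: tuple[str, ...]
    positive: np.ndarray
    negative: np.ndarray
    neutral: np.ndarray
    n_sims: int
    acceptance_rate: float = float("nan")
    n_excluded: int = 0

    @classmethod
    def zeros(cls, elements: tuple[str, ...]) -> "ResponseTally":
        n = len(elements)
        return cls(
            elements=elements,
            positive=np.zeros(n, dtype=int),
            negative=np.zeros(n, dtype=int),
            neutral=np.zeros(n, dtype=int),
            n_sims=0,
        )

    def add(self, signs: np.ndarray) -> None:
        self.positive += signs > 0
        self.negative += signs < 0
        self.neutral += signs == 0
        self.n_sims += 1

    def counts(self, element: str) -> tuple[int, int, int]:
        i = self.elements.index(element)
        return int(self.positive[i]), int(self.negative[i]), int(self.neutral[i])

    def mirrored(self) -> "ResponseTally":
        """Positive/negative-swapped view (the expected tally of a flipped press)."""
        return ResponseTally(
            elements=self.elements,
            positive=self.negative.copy(),
            negative=self.positive.copy(),
            neutral=self.neutral.copy(),
            n_sims=self.n_sims,
            acceptance_rate=self.acceptance_rate,
            n_excluded=self.n_excluded,
        )


# ---------------------------------------------------------------------------


def sample_community_matrix(g: SignedDigraph, rng: np.random.Generator) -> np.ndarray:
    """One random community matrix consistent with the digraph's signs."""
    S = g.sign_matrix()
    mags = rng.uniform(0.0, 1.0, size=S.shape)
    # Uniform(0,1]: flip the half-open interval so 0 is excluded
    mags = 1.0 - mags
    return S * mags


def is_stable(A: np.ndarray) -> bool:
    """True iff every eigenvalue of ``A`` has strictly negative real part."""
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("community matrix has non-finite entries")
    return bool(np.max(np.linalg.eigvals(A).real) < 0)


def press_response(
    A: np.ndarray, scenario: PressScenario, elements: tuple[str, ...]
) -> np.ndarray:
    """Signed equilibrium response to the press: ``sign(−A⁻¹ p)`` per element.

    Returns an int vector in {−1, 0, +1}; magnitudes below ``1e-9`` count
    as neutral.  A numerically singular matrix raises
    :class:`numpy.linalg.LinAlgError` (callers treat it as rejection).
    """
    p = np.zeros(len(elements))
    p[elements.index(scenario.element)] = scenario.direction
    x = -np.linalg.solve(A, p)
    signs = np.zeros(len(elements), dtype=int)
    signs[x > ZERO_TOL] = 1
    signs[x < -ZERO_TOL] = -1
    return signs


def simulate_press(
    g: SignedDigraph,
    scenario: PressScenario,
    n_accepted: int = 1000,
    rng: np.random.Generator | int | None = None,
    max_draws: int = 1_000_000,
) -> ResponseTally:
    """Rejection-sample stable community matrices and tally press outcomes."""
    if n_accepted < 1:
        raise ValueError("n_accepted must be >= 1")
    if scenario.element not in g.nodes:
        raise KeyError(f"scenario element {scenario.element!r} is not a digraph node")
    rng = np.random.default_rng(rng)

    S = g.sign_matrix()
    tally = ResponseTally.zeros(g.nodes)
    draws = 0
    batch = 256
    while tally.n_sims < n_accepted:
        if draws >= max_draws:
            raise LowAcceptanceError(tally.n_sims, draws)
        k = min(batch, max_draws - draws)
        mats = S * (1.0 - rng.uniform(0.0, 1.0, size=(k,) + S.shape))
        stable = np.linalg.eigvals(mats).real.max(axis=1) < 0
        for idx in range(k):
            draws += 1
            if not stable[idx]:
                continue
            try:
                signs = press_response(mats[idx], scenario, g.nodes)
            except np.linalg.LinAlgError:
                continue  # singular: treat as unstable sample
            tally.add(signs)
            if tally.n_sims == n_accepted:
                break
    tally.acceptance_rate = tally.n_sims / draws
    return tally
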
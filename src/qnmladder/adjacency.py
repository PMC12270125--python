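"""Consolidated signed adjacency and the complexity ladder.

The quantitative web is collapsed into a single strength per directed
feeding pair (resource → consumer): the consumer's diet share *minus* the
resource's mortality share, a value in [−1, +1].  Thresholding that matrix
at 0, 0.1, …, 0.5 yields a nested ladder of progressively sparser signed
digraphs, each pair expanding into the usual +/− predator–prey edge pair
with a negative self-limiting loop on every node.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .foodweb import BalanceResult, FoodWeb, Role

__all__ = [
    "SignedAdjacency",
    "SignedDigraph",
    "LinkCounts",
    "LADDER_LEVELS",
    "build_adjacency",
    "apply_threshold",
    "link_counts",
    "to_signed_digraph",
    "ladder",
]

#: complexity-ladder threshold levels, weakest-link elimination fractions
LADDER_LEVELS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class SignedAdjacency:
    """Consolidated pair strengths ``strength[i, j]`` for resource i → consumer j."""

    elements: tuple[str, ...]
    strength: np.ndarray
    threshold_level: float = 0.0

    @property
    def n(self) -> int:
        return len(self.elements)

    def index(self, element: str) -> int:
        try:
            return self.elements.index(element)
        except ValueError:
            raise KeyError(f"no element named {element!r}") from None

    def n_pairs(self) -> int:
        return int(np.count_nonzero(self.strength))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.strength, index=self.elements, columns=self.elements)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, threshold_level: float = 0.0) -> "SignedAdjacency":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("adjacency CSV row and column labels differ")
        return cls(
            elements=tuple(str(x) for x in df.index),
            strength=df.to_numpy(dtype=float),
            threshold_level=threshold_level,
        )


@dataclass(frozen=True)
class SignedDigraph:
    """Unweighted signed digraph; every node carries a negative self-loop."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str, int]]  # (from, to, sign ∈ {+1, −1})

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"no node named {node!r}") from None

    def n_pair_edges(self) -> int:
        return len(self.edges)

    def n_feeding_pairs(self) -> int:
        return len(self.edges) // 2

    def incident(self, node: str) -> int:
        """Number of pair-edges touching ``node`` (self-loops excluded)."""
        return sum(1 for u, v, _ in self.edges if node in (u, v))

    def sign_matrix(self) -> np.ndarray:
        """Sign structure S with S[target, source] ∈ {−1, 0, +1}; diagonal −1."""
        n = self.n
        S = np.zeros((n, n), dtype=int)
        idx = {name: i for i, name in enumerate(self.nodes)}
        for u, v, s in self.edges:
            S[idx[v], idx[u]] = s
        np.fill_diagonal(S, -1)
        return S

    # -- text round-trip ----------------------------------------------------

    def to_edgelist(self, path: str | Path) -> None:
        """Write node manifest + one ``from,to,sign`` line per pair-edge."""
        lines = [f"# nodes: {','.join(self.nodes)}"]
        for u, v, s in sorted(self.edges):
            lines.append(f"{u},{v},{'+' if s > 0 else '-'}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_edgelist(cls, path: str | Path) -> "SignedDigraph":
        text = Path(path).read_text().strip().splitlines()
        if not text or not text[0].startswith("# nodes:"):
            raise ValueError("edge-list file must start with a '# nodes:' manifest line")
        nodes = tuple(text[0].split(":", 1)[1].strip().split(","))
        edges = set()
        for line in text[1:]:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v, s = line.split(",")
            edges.add((u, v, 1 if s == "+" else -1))
        return cls(nodes=nodes, edges=frozenset(edges))

    def to_dot(self, path: str | Path) -> None:
        """DOT writer for visual inspection (self-loops omitted)."""
        lines = ["digraph qnm {"]
        for u, v, s in sorted(self.edges):
            style = "" if s > 0 else ' [arrowhead=dot, color=red]'
            lines.append(f'  "{u}" -> "{v}"{style};')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, s in self.edges:
            g.add_edge(u, v, sign=s)
        for u in self.nodes:
            g.add_edge(u, u, sign=-1)
        return g


class LinkCounts(NamedTuple):
    inward: int
    outward: int
    all: int


# ---------------------------------------------------------------------------


def build_adjacency(web: FoodWeb, bal: BalanceResult) -> SignedAdjacency:
    """Consolidate diet shares and mortality proportions into pair strengths.

    ``v[i, j] = DC[i, j] − m2prop[i, j]`` for consumer columns; the fleet
    column uses catch shares minus fishing-mortality proportions.  The
    diagonal (cannibalism) is dropped — it lives in the self-limiting loops.
    """
    n = web.n
    if bal.m2prop.shape != web.diet.shape:
        raise RuntimeError(
            f"internal error: diet {web.diet.shape} vs m2prop {bal.m2prop.shape} shape mismatch"
        )
    v = web.diet - bal.m2prop
    fleet = np.flatnonzero(web.mask(Role.FLEET))
    for j in fleet:
        v[:, j] = web.catch_shares() - bal.fprop
        v[j, :] = 0.0
    np.fill_diagonal(v, 0.0)
    return SignedAdjacency(elements=web.names, strength=v, threshold_level=0.0)


def apply_threshold(adj: SignedAdjacency, level: float) -> SignedAdjacency:
    """Zero out pairs with ``|v| < level``; retain ``|v| >= level`` unchanged."""
    if not 0 <= level < 1:
        raise ValueError(f"threshold level {level} outside [0, 1)")
    v = np.where(np.abs(adj.strength) >= level, adj.strength, 0.0)
    return SignedAdjacency(elements=adj.elements, strength=v, threshold_level=level)


def link_counts(adj: SignedAdjacency, element: str) -> LinkCounts:
    """Inward (element as consumer), outward (element as resource) and total links."""
    i = adj.index(element)
    outward = int(np.count_nonzero(adj.strength[i, :]))
    inward = int(np.count_nonzero(adj.strength[:, i]))
    return LinkCounts(inward=inward, outward=outward, all=inward + outward)


def link_count_table(adj: SignedAdjacency, elements: Iterable[str] | None = None) -> pd.DataFrame:
    """Tidy IN/OUT/ALL counts for the given elements (default: all)."""
    elements = list(elements) if elements is not None else list(adj.elements)
    rows = []
    for e in elements:
        c = link_counts(adj, e)
        rows.append({"element": e, "in": c.inward, "out": c.outward, "all": c.all})
    return pd.DataFrame(rows)


def to_signed_digraph(adj: SignedAdjacency) -> SignedDigraph:
    """Expand each retained pair into (+) resource→consumer and (−) back-edge.

    The sign of the consolidated strength is irrelevant — it was only used
    for thresholding; every surviving pair is a predator–prey interaction.
    """
    edges = set()
    names = adj.elements
    for i, j in zip(*np.nonzero(adj.strength)):
        edges.add((names[i], names[j], +1))
        edges.add((names[j], names[i], -1))
    return SignedDigraph(nodes=names, edges=frozenset(edges))


def ladder(
    adj: SignedAdjacency, levels: Iterable[float] = LADDER_LEVELS
) -> list[SignedDigraph]:
    """Signed digraphs at each threshold level, most to least complex."""
    if adj.threshold_level != 0:
        raise ValueError("ladder must start from the unthresholded (level 0) adjacency")
    return [to_signed_digraph(apply_threshold(adj, lv)) for lv in levels]
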
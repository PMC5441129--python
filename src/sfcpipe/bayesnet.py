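"""Three-phase dependency analysis (TPDA) Bayesian-network structure learning.

An information-theoretic constraint-based learner over continuous variables:
dependency strength is measured by Gaussian (conditional) mutual information,
CMI = -0.5*ln(1 - rho^2) with rho the (partial) correlation, and a
dependency is declared significant when the Fisher-z test of rho rejects at
``alpha`` — replacing the absolute CMI threshold of the original discrete
formulation with a sample-size-aware test.

The three phases:

1. *Drafting* — rank all marginally dependent pairs by mutual information
   and add an edge whenever the current draft contains no open path between
   the pair; remaining dependent pairs are deferred.
2. *Thickening* — add each deferred pair as an edge unless a cut set found
   by the try-to-separate search renders the pair conditionally independent.
3. *Thinning* — each edge whose endpoints stay connected without it is
   temporarily removed and retested; separable edges are dropped for good.

The try-to-separate search conditions on path-adjacent nodes (neighbours of
either endpoint lying on a connecting path), searched exhaustively in
deterministic order — exact for the small variable sets this package deals
with.  Orientation uses collider (v-structure) detection with the recorded
cut sets followed by Meek-style propagation; edges whose direction remains
unresolved (or conflicts) are reported as bidirected.  Edge strength is
summarized by the determination coefficient R^2 (squared Pearson
correlation) of the joined variables.

Assumes monotone faithfulness of the data-generating distribution, as TPDA
does.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BNGraph", "TPDA", "BNResults", "gaussian_cmi", "tpda_learn", "edge_r2"]


def _partial_corr_from_R(R: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    idx = [i, j, *S]
    sub = R[np.ix_(idx, idx)]
    try:
        P = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate (collinear) conditioning set") from exc
    if not np.all(np.isfinite(P)):
        raise ValueError("degenerate (collinear) conditioning set")
    denom = P[0, 0] * P[1, 1]
    if denom <= 0:
        raise ValueError("degenerate (collinear) conditioning set")
    rho = float(-P[0, 1] / np.sqrt(denom))
    return min(1.0, max(-1.0, rho))


def gaussian_cmi(x, y, conditioning=None) -> tuple[float, float]:
    """Gaussian conditional mutual information of x and y given a set.

    CMI = -0.5*ln(1 - rho^2), rho the partial correlation given the
    conditioning columns; the p-value comes from the Fisher-z test of rho
    with n - |S| - 3 effective degrees of freedom.  Returns (cmi, p).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if conditioning is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(conditioning, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > |conditioning| + 3 (n={n}, k={k})")
    M = np.column_stack([x, y, C])
    sd = M.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column in CMI computation")
    R = np.corrcoef(M, rowvar=False)
    rho = _partial_corr_from_R(R, 0, 1, tuple(range(2, 2 + k)))
    cmi = -0.5 * np.log(max(1e-300, 1 - rho**2))
    z = np.arctanh(min(1 - 1e-15, max(-1 + 1e-15, rho)))
    p = float(2 * stats.norm.sf(abs(z) * np.sqrt(n - k - 3)))
    return float(cmi), p


def edge_r2(x, y) -> float:
    """Determination coefficient: squared Pearson correlation of two variables."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 3 or len(y) != len(x):
        raise ValueError("need aligned vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance variable")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


@dataclass
class BNGraph:
    """Learned structure: directed and bidirected edges with per-edge R^2."""

    nodes: list[str]
    edges: list[tuple[str, str, str]]  # (source, target, 'forward' | 'bidirected')
    edge_r2: dict[tuple[str, str], float] = field(default_factory=dict)
    edge_p: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, d in self.edges:
            if u == v:
                raise ValueError("self-loops are not allowed")
            if d not in ("forward", "bidirected"):
                raise ValueError(f"bad direction {d!r}")

    def skeleton(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v, _ in self.edges}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "direction": d,
                "r2": self.edge_r2.get((u, v), np.nan),
                "p": self.edge_p.get((u, v), np.nan),
            }
            for u, v, d in self.edges
        ]
        return pd.DataFrame(rows, columns=["source", "target", "direction", "r2", "p"])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, d in self.edges:
            g.add_edge(u, v, direction=d, r2=self.edge_r2.get((u, v)))
            if d == "bidirected":
                g.add_edge(v, u, direction=d, r2=self.edge_r2.get((u, v)))
        return g

    def to_dot(self) -> str:
        lines = ["digraph bn {"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for u, v, d in self.edges:
            r2 = self.edge_r2.get((u, v), np.nan)
            attr = f'label="R2={r2:.2f}"'
            if d == "bidirected":
                attr += ", dir=both"
            lines.append(f'  "{u}" -> "{v}" [{attr}];')
        lines.append("}")
        return "\n".join(lines)


class TPDA:
    """TPDA structure learner over the columns of a data table.

    Parameters
    ----------
    data : DataFrame (n >= 30 rows, >= 3 numeric columns)
    max_cond : largest conditioning-set size tried by try-to-separate
    """

    def __init__(self, data: pd.DataFrame, max_cond: int = 5):
        data = pd.DataFrame(data)
        if data.shape[1] < 3:
            raise ValueError("need at least 3 variables")
        if len(data) < 30:
            raise ValueError("need at least 30 observations")
        for col in data.columns:
            vals = data[col].to_numpy(float)
            if np.nanstd(vals) == 0:
                raise ValueError(f"variable {col!r} is constant")
        self.data = data.astype(float)
        self.nodes = sorted(str(c) for c in data.columns)
        self._X = self.data[self.nodes].to_numpy()
        self.n = len(data)
        self.R = np.corrcoef(self._X, rowvar=False)
        self.max_cond = max_cond
        self._index = {name: i for i, name in enumerate(self.nodes)}

    # -- dependency tests ---------------------------------------------------
    def _test(self, x: str, y: str, S: tuple[str, ...]) -> tuple[float, float]:
        """(cmi, p) of x against y given S, from the correlation matrix."""
        i, j = self._index[x], self._index[y]
        Sx = tuple(self._index[s] for s in S)
        rho = _partial_corr_from_R(self.R, i, j, Sx)
        cmi = -0.5 * np.log(max(1e-300, 1 - rho**2))
        z = np.arctanh(min(1 - 1e-15, max(-1 + 1e-15, rho)))
        p = float(2 * stats.norm.sf(abs(z) * np.sqrt(max(1, self.n - len(S) - 3))))
        return cmi, p

    def _try_to_separate(self, G: nx.Graph, x: str, y: str, alpha: float):
        """Search cut sets over path-adjacent neighbours; return sepset or None."""
        H = G.copy()
        if H.has_edge(x, y):
            H.remove_edge(x, y)
        if not nx.has_path(H, x, y):
            return tuple()
        cand = sorted(
            v
            for v in (set(H.neighbors(x)) | set(H.neighbors(y))) - {x, y}
            if nx.has_path(H, x, v) and nx.has_path(H, v, y)
        )
        for size in range(1, min(len(cand), self.max_cond) + 1):
            for S in itertools.combinations(cand, size):
                _, p = self._test(x, y, S)
                if p >= alpha:
                    return S
        return None

    # -- fitting ------------------------------------------------------------
    def fit(self, alpha: float = 0.05) -> "BNResults":
        pairs = []
        for x, y in itertools.combinations(self.nodes, 2):
            cmi, p = self._test(x, y, ())
            pairs.append((x, y, cmi, p))
        pairs.sort(key=lambda t: (-t[2], t[0], t[1]))

        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        sepsets: dict[frozenset, tuple[str, ...]] = {}
        deferred = []
        # phase 1: drafting
        for x, y, cmi, p in pairs:
            if p >= alpha:
                sepsets[frozenset((x, y))] = tuple()
                continue
            if not nx.has_path(G, x, y):
                G.add_edge(x, y)
            else:
                deferred.append((x, y))
        # phase 2: thickening
        for x, y in deferred:
            S = self._try_to_separate(G, x, y, alpha)
            if S is None:
                G.add_edge(x, y)
            else:
                sepsets[frozenset((x, y))] = S
        # phase 3: thinning
        for x, y in sorted(G.edges()):
            H = G.copy()
            H.remove_edge(x, y)
            if not nx.has_path(H, x, y):
                continue
            S = self._try_to_separate(G, x, y, alpha)
            if S is not None:
                G.remove_edge(x, y)
                sepsets[frozenset((x, y))] = S

        directed = self._orient(G, sepsets)
        graph = self._build_graph(G, directed)
        return BNResults(self, graph, sepsets, alpha)

    def _orient(self, G: nx.Graph, sepsets) -> dict[frozenset, tuple[str, str] | None]:
        """Collider detection + Meek propagation; None = unresolved."""
        direction: dict[frozenset, tuple[str, str] | None] = {frozenset(e): None for e in G.edges()}
        conflicted: set[frozenset] = set()

        def set_dir(u, v):
            key = frozenset((u, v))
            cur = direction.get(key)
            if cur is None:
                direction[key] = (u, v)
            elif cur != (u, v):
                conflicted.add(key)

        for z in self.nodes:
            nbrs = sorted(G.neighbors(z))
            for x, y in itertools.combinations(nbrs, 2):
                if G.has_edge(x, y):
                    continue
                sep = sepsets.get(frozenset((x, y)))
                if sep is not None and z not in sep:
                    set_dir(x, z)
                    set_dir(y, z)

        def dir_of(u, v):
            key = frozenset((u, v))
            if key in conflicted:
                return None
            return direction.get(key)

        changed = True
        while changed:
            changed = False
            for u, v in sorted(G.edges()):
                key = frozenset((u, v))
                if key in conflicted or direction[key] is not None:
                    continue
                for a, b in ((u, v), (v, u)):
                    # Meek R1: w -> a, a - b, w and b nonadjacent  =>  a -> b
                    r1 = any(
                        dir_of(w, a) == (w, a) and not G.has_edge(w, b)
                        for w in G.neighbors(a)
                        if w != b
                    )
                    # Meek R2: a -> w -> b with a - b  =>  a -> b
                    r2 = any(
                        dir_of(a, w) == (a, w) and dir_of(w, b) == (w, b)
                        for w in set(G.neighbors(a)) & set(G.neighbors(b))
                    )
                    if r1 or r2:
                        direction[key] = (a, b)
                        changed = True
                        break
        for key in conflicted:
            direction[key] = None
        return direction

    def _build_graph(self, G: nx.Graph, direction) -> BNGraph:
        edges = []
        r2s, ps = {}, {}
        for u, v in sorted(G.edges()):
            d = direction.get(frozenset((u, v)))
            if d is None:
                src, tgt, kind = u, v, "bidirected"
            else:
                (src, tgt), kind = d, "forward"
            i, j = self._index[u], self._index[v]
            r2s[(src, tgt)] = float(self.R[i, j] ** 2)
            _, p = self._test(u, v, ())
            ps[(src, tgt)] = p
            edges.append((src, tgt, kind))
        return BNGraph(nodes=list(self.nodes), edges=edges, edge_r2=r2s, edge_p=ps)


class BNResults:
    """Fitted TPDA structure with the cut sets found along the way."""

    def __init__(self, model: TPDA, graph: BNGraph, sepsets, alpha: float):
        self.model = model
        self.graph = graph
        self.sepsets = dict(sepsets)
        self.alpha = alpha

    def summary(self) -> str:
        lines = [
            f"TPDA structure over {len(self.graph.nodes)} variables (alpha={self.alpha}, n={self.model.n})",
            f"  edges: {len(self.graph.edges)}",
        ]
        for u, v, d in self.graph.edges:
            arrow = "<->" if d == "bidirected" else "-->"
            lines.append(f"  {u} {arrow} {v}   R2={self.graph.edge_r2[(u, v)]:.3f}")
        return "\n".join(lines)


def tpda_learn(data: pd.DataFrame, alpha: float = 0.05, max_cond: int = 5) -> BNGraph:
    """Functional wrapper: learn and return the BNGraph."""
    return TPDA(data, max_cond=max_cond).fit(alpha=alpha).graph
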
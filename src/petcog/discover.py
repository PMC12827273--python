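"""Constraint-based confounder verification.

Implements the Fisher-Z conditional-independence test, the PC skeleton
search with sepset recording, v-structure/Meek orientation with optional
tiered background knowledge (demographics -> imaging -> scores), and a
confounder report combining graph evidence with univariate regressions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    OrientationConflictError,
    RankDeficiencyError,
    SampleSizeError,
)

_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class CITestResult:
    var_x: str
    var_y: str
    conditioning_set: frozenset
    partial_corr: float
    z_stat: float
    p_value: float
    independent: bool
    alpha: float


def partial_correlation(data: pd.DataFrame, x: str, y: str, s: "tuple[str, ...]") -> float:
    """Partial correlation of x and y given s, via precision-matrix inversion."""
    cols = [x, y, *s]
    mat = np.corrcoef(data[cols].to_numpy(dtype=float), rowvar=False)
    mat = np.atleast_2d(mat)
    if not s:
        return float(mat[0, 1])
    try:
        prec = np.linalg.inv(mat)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            f"correlation submatrix for ({x},{y}|{s}) is singular"
        ) from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        raise RankDeficiencyError(f"ill-conditioned submatrix for ({x},{y}|{s})")
    return float(-prec[0, 1] / np.sqrt(denom))


def fisher_z_test(
    data: pd.DataFrame,
    x: str,
    y: str,
    s=(),
    alpha: float = 0.05,
) -> CITestResult:
    """Fisher-Z test of X _||_ Y | S on numeric columns.

    z = sqrt(n - |S| - 3) * atanh(r_partial), two-sided p from N(0,1).
    """
    s = tuple(sorted(s))
    n = len(data)
    if n <= len(s) + 3:
        raise SampleSizeError(f"need n > |S| + 3 (n={n}, |S|={len(s)})")
    r = partial_correlation(data, x, y, s)
    r = float(np.clip(r, -_CLAMP, _CLAMP))
    z = np.sqrt(n - len(s) - 3) * np.arctanh(r)
    p = 2.0 * stats.norm.sf(abs(z))
    return CITestResult(
        var_x=x, var_y=y, conditioning_set=frozenset(s),
        partial_corr=r, z_stat=float(z), p_value=float(p),
        independent=bool(p > alpha), alpha=alpha,
    )


@dataclass
class CausalGraph:
    """Mixed graph produced by skeleton search and orientation."""

    nodes: list[str]
    undirected: set = field(default_factory=set)      # frozenset pairs
    directed: set = field(default_factory=set)        # (tail, head) tuples
    sepsets: dict = field(default_factory=dict)       # frozenset pair -> set of vars

    def adjacent(self, v: str) -> set:
        out = {next(iter(e - {v})) for e in self.undirected if v in e}
        out |= {h for t, h in self.directed if t == v}
        out |= {t for t, h in self.directed if h == v}
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in self.undirected
            or (a, b) in self.directed
            or (b, a) in self.directed
        )

    def assert_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        if not nx.is_directed_acyclic_graph(g):
            raise OrientationConflictError("directed portion contains a cycle")

    def to_edge_list(self) -> list[str]:
        lines = [f"{t} -> {h}" for t, h in sorted(self.directed)]
        lines += [f"{a} -- {b}" for a, b in sorted(tuple(sorted(e)) for e in self.undirected)]
        return lines

    def save_edge_list(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.to_edge_list()) + "\n")

    def to_networkx(self) -> nx.DiGraph:
        """Standard interchange form: DiGraph, undirected edges as both arcs."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        for e in self.undirected:
            a, b = sorted(e)
            g.add_edge(a, b, undirected=True)
            g.add_edge(b, a, undirected=True)
        return g

    def save_gml(self, path: str | Path) -> None:
        nx.write_gml(self.to_networkx(), str(path))


def pc_skeleton(
    data: pd.DataFrame,
    alpha: float = 0.05,
    max_cond_size: int = 3,
    columns: "list[str] | None" = None,
) -> CausalGraph:
    """PC-stable skeleton search with sepset recording.

    Variables and conditioning subsets are enumerated in lexicographic order,
    so the result is deterministic and invariant to row order of ``data``.
    """
    cols = sorted(columns if columns is not None else data.columns)
    graph = CausalGraph(nodes=cols)
    graph.undirected = {frozenset(p) for p in itertools.combinations(cols, 2)}

    for level in range(max_cond_size + 1):
        # PC-stable: adjacency sets frozen at the start of each level
        adj = {v: sorted(graph.adjacent(v)) for v in cols}
        if all(len(a) - 1 < level for a in adj.values()):
            break
        for x, y in itertools.combinations(cols, 2):
            if frozenset((x, y)) not in graph.undirected:
                continue
            removed = False
            for base, other in ((x, y), (y, x)):
                candidates = [v for v in adj[base] if v != other]
                if len(candidates) < level:
                    continue
                for s in itertools.combinations(candidates, level):
                    res = fisher_z_test(data, x, y, s, alpha=alpha)
                    if res.independent:
                        graph.undirected.discard(frozenset((x, y)))
                        graph.sepsets[frozenset((x, y))] = set(s)
                        removed = True
                        break
                if removed:
                    break
    return graph


def _meek_closure(graph: CausalGraph) -> None:
    """Apply Meek rules 1-3 until fixpoint."""
    changed = True
    while changed:
        changed = False
        for e in list(graph.undirected):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # Rule 1: z -> x, z not adjacent y  =>  x -> y
                r1 = any(
                    (z, x) in graph.directed and not graph.has_edge(z, y)
                    for z in graph.nodes if z not in (x, y)
                )
                # Rule 2: x -> z -> y  =>  x -> y
                r2 = any(
                    (x, z) in graph.directed and (z, y) in graph.directed
                    for z in graph.nodes if z not in (x, y)
                )
                # Rule 3: x - z1 -> y, x - z2 -> y, z1 not adj z2  =>  x -> y
                r3 = False
                half = [
                    z for z in graph.nodes
                    if z not in (x, y)
                    and frozenset((x, z)) in graph.undirected
                    and (z, y) in graph.directed
                ]
                for z1, z2 in itertools.combinations(half, 2):
                    if not graph.has_edge(z1, z2):
                        r3 = True
                        break
                if r1 or r2 or r3:
                    graph.undirected.discard(e)
                    graph.directed.add((x, y))
                    changed = True
                    break


def orient_edges(
    skeleton: CausalGraph,
    tiers: "list[list[str]] | None" = None,
    on_conflict: str = "raise",
) -> CausalGraph:
    """Orient a skeleton: v-structures, tier background knowledge, Meek closure.

    ``tiers`` is an ordered partition (earlier tiers may cause later ones,
    never the reverse).  A tier assignment that contradicts a v-structure
    raises :class:`OrientationConflictError` (``on_conflict="raise"``) or
    gives the tiers precedence and skips the contradictory v-structure arm
    (``on_conflict="skip"``).
    """
    graph = CausalGraph(
        nodes=list(skeleton.nodes),
        undirected=set(skeleton.undirected),
        directed=set(skeleton.directed),
        sepsets=dict(skeleton.sepsets),
    )
    tier_of = {}
    if tiers:
        for i, tier in enumerate(tiers):
            for v in tier:
                tier_of[v] = i

    # v-structures: unshielded x - z - y with z not in sepset(x, y)
    for z in sorted(graph.nodes):
        neigh = sorted(
            next(iter(e - {z}))
            for e in graph.undirected if z in e
        )
        for x, y in itertools.combinations(neigh, 2):
            if graph.has_edge(x, y):
                continue
            sep = graph.sepsets.get(frozenset((x, y)), set())
            if z not in sep:
                for tail in (x, y):
                    if tier_of and tier_of.get(z, 0) < tier_of.get(tail, 0):
                        if on_conflict == "skip":
                            continue  # tiers take precedence over this arm
                        raise OrientationConflictError(
                            f"v-structure {tail} -> {z} contradicts tier ordering"
                        )
                    graph.undirected.discard(frozenset((tail, z)))
                    if (z, tail) in graph.directed:
                        raise OrientationConflictError(
                            f"conflicting orientations on edge ({tail}, {z})"
                        )
                    graph.directed.add((tail, z))

    # tier knowledge forces cross-tier undirected edges
    if tier_of:
        for t, h in graph.directed:
            if tier_of.get(t, 0) > tier_of.get(h, 0):
                raise OrientationConflictError(
                    f"data-driven edge {t} -> {h} contradicts tier ordering"
                )
        for e in list(graph.undirected):
            a, b = sorted(e)
            ta, tb = tier_of.get(a, 0), tier_of.get(b, 0)
            if ta != tb:
                tail, head = (a, b) if ta < tb else (b, a)
                graph.undirected.discard(e)
                graph.directed.add((tail, head))

    _meek_closure(graph)
    graph.assert_acyclic()
    return graph


@dataclass
class ConfounderReport:
    """Per-candidate backdoor evidence."""

    candidates: dict  # name -> {directed_to_treatments, directed_to_outcomes,
    #                            univariate_p, satisfies_backdoor}
    alpha: float
    graph: CausalGraph | None = None

    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = {
            "alpha": self.alpha,
            "candidates": {
                k: {
                    "directed_to_treatments": sorted(v["directed_to_treatments"]),
                    "directed_to_outcomes": sorted(v["directed_to_outcomes"]),
                    "univariate_p": v["univariate_p"],
                    "satisfies_backdoor": v["satisfies_backdoor"],
                }
                for k, v in self.candidates.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def univariate_regression_p(data: pd.DataFrame, x: str, y: str) -> float:
    """Two-sided p-value for the slope of y ~ x (simple linear regression)."""
    res = stats.linregress(data[x].to_numpy(float), data[y].to_numpy(float))
    return float(res.pvalue)


def verify_confounders(
    data: pd.DataFrame,
    candidates,
    treatments,
    outcomes,
    alpha: float = 0.05,
    max_cond_size: int = 3,
    tiers: bool = True,
) -> ConfounderReport:
    """Certify candidate confounders via PC + orientation + univariate checks.

    Runs the PC algorithm on candidates + treatments + outcomes (with tiered
    background knowledge demographics < imaging < scores unless disabled),
    then records which candidates have directed edges into at least one
    treatment and one outcome, alongside univariate-regression p-values.
    """
    candidates = sorted(candidates)
    treatments = sorted(treatments)
    outcomes = sorted(outcomes)
    if not candidates:
        return ConfounderReport(candidates={}, alpha=alpha, graph=None)
    cols = candidates + treatments + outcomes
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    skeleton = pc_skeleton(data, alpha=alpha, max_cond_size=max_cond_size, columns=cols)
    tier_spec = [candidates, treatments, outcomes] if tiers else None
    graph = orient_edges(skeleton, tiers=tier_spec, on_conflict="skip")

    report = {}
    for cand in candidates:
        to_t = sorted(h for t, h in graph.directed if t == cand and h in treatments)
        to_o = sorted(h for t, h in graph.directed if t == cand and h in outcomes)
        upv = {tgt: univariate_regression_p(data, cand, tgt) for tgt in treatments + outcomes}
        report[cand] = {
            "directed_to_treatments": to_t,
            "directed_to_outcomes": to_o,
            "univariate_p": upv,
            "satisfies_backdoor": bool(to_t and to_o),
        }
    return ConfounderReport(candidates=report, alpha=alpha, graph=graph)
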
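"""Recursive path-model specification (DAG) and identification checks."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import yaml

ROLES = ("exogenous", "mediator", "final-endogenous")


@dataclass(frozen=True)
class PathModel:
    """DAG over observed variables with free paths and exogenous covariances.

    ``edges`` are the free path coefficients (parent, child);
    ``covariances`` are free correlations among exogenous variables;
    ``candidates`` are fixed-to-zero paths offered to the modification step.
    """

    nodes: tuple[tuple[str, str], ...]         # (name, role)
    edges: tuple[tuple[str, str], ...]
    covariances: tuple[tuple[str, str], ...] = ()
    candidates: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple((str(a), str(b)) for a, b in self.nodes))
        object.__setattr__(self, "edges", tuple((str(a), str(b)) for a, b in self.edges))
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        for name, role in self.nodes:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for node {name}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model contains a cycle")
        roles = dict(self.nodes)
        for a, b in self.edges:
            if roles[a] == "final-endogenous":
                raise ValueError(f"final-endogenous node {a} has an outgoing edge")
            if roles[b] == "exogenous":
                raise ValueError(f"exogenous node {b} has an incoming edge")
        for name, role in self.nodes:
            if role == "mediator":
                if g.in_degree(name) < 1 or g.out_degree(name) < 1:
                    raise ValueError(f"mediator {name} needs incoming and outgoing edges")
        for a, b in self.covariances:
            if roles[a] != "exogenous" or roles[b] != "exogenous":
                raise ValueError("free covariances are only allowed between exogenous nodes")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.nodes]

    @property
    def roles(self) -> dict[str, str]:
        return dict(self.nodes)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        g.add_edges_from(self.edges)
        return g

    @property
    def exogenous(self) -> list[str]:
        return [n for n, r in self.nodes if r == "exogenous"]

    @property
    def endogenous(self) -> list[str]:
        return [n for n, r in self.nodes if r != "exogenous"]

    def parents(self, node: str) -> list[str]:
        return [a for a, b in self.edges if b == node]

    def topological_order(self) -> list[str]:
        order = list(nx.topological_sort(self.graph()))
        # stable: exogenous first in declaration order, then topological
        exo = [n for n in self.names if n in self.exogenous]
        return exo + [n for n in order if n not in exo]

    @property
    def n_free_parameters(self) -> int:
        return len(self.edges) + len(self.covariances)

    def with_edge(self, parent: str, child: str) -> "PathModel":
        if (parent, child) in self.edges:
            return self
        cands = tuple(c for c in self.candidates if c != (parent, child))
        return replace(self, edges=self.edges + ((parent, child),), candidates=cands)

    def would_be_acyclic(self, parent: str, child: str) -> bool:
        g = self.graph()
        g.add_edge(parent, child)
        return nx.is_directed_acyclic_graph(g)

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_config(cls, config) -> "PathModel":
        if isinstance(config, (str, bytes)):
            config = yaml.safe_load(config)
        elif hasattr(config, "read"):
            config = yaml.safe_load(config.read())
        return cls(
            nodes=tuple((d["name"], d["role"]) for d in config["nodes"]),
            edges=tuple((e["from"], e["to"]) for e in config.get("edges", [])),
            covariances=tuple((c["between"][0], c["between"][1])
                              for c in config.get("covariances", [])),
            candidates=tuple((e["from"], e["to"]) for e in config.get("candidates", [])),
        )

    def to_config(self) -> dict:
        return {
            "nodes": [{"name": n, "role": r} for n, r in self.nodes],
            "edges": [{"from": a, "to": b} for a, b in self.edges],
            "covariances": [{"between": list(c)} for c in self.covariances],
            "candidates": [{"from": a, "to": b} for a, b in self.candidates],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_config())


@dataclass
class IdentificationReport:
    """Order/rank counting and model degrees of freedom.

    The order condition treats every causally prior variable as predetermined
    (the models in scope are recursive with uncorrelated errors, so prior
    endogenous variables are valid instruments); an equation is exactly
    identified when no predetermined variable is excluded, over-identified
    otherwise.  The rank condition is the textbook check — rank of the generic
    structural-coefficient submatrix on excluded variables against M - 1 —
    reported per equation; for recursive models a failed textbook rank check
    does not void identification (``recursive`` is reported alongside).
    """

    order: dict[str, str]
    rank_ok: dict[str, bool]
    recursive: bool
    n_moments: int
    n_free: int

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    @property
    def verdict(self) -> str:
        if self.df < 0:
            return "under-identified"
        return "just-identified" if self.df == 0 else "over-identified"


def check_identification(model: PathModel, seed: int = 0) -> IdentificationReport:
    """Order/rank conditions and df = moments - free parameters."""
    names = model.names
    endo = model.endogenous
    exo = model.exogenous
    M = len(endo)
    order_pos = {n: i for i, n in enumerate(model.topological_order())}

    order = {}
    for eq in endo:
        prior = [v for v in names if order_pos[v] < order_pos[eq]]
        excluded = [v for v in prior if v not in model.parents(eq)]
        if len(excluded) < 0:  # unreachable for a DAG; kept for symmetry
            order[eq] = "under-identified"
        else:
            order[eq] = "exactly-identified" if not excluded else "over-identified"

    # generic structural matrix A = [I - B | -Gamma], rows = endogenous eqs
    rng = np.random.default_rng(seed)
    cols = endo + exo
    A = np.zeros((M, len(cols)))
    for i, eq in enumerate(endo):
        A[i, cols.index(eq)] = 1.0
        for par in model.parents(eq):
            A[i, cols.index(par)] = rng.uniform(0.5, 1.5)
    rank_ok = {}
    for i, eq in enumerate(endo):
        in_eq = set(model.parents(eq)) | {eq}
        excl_cols = [j for j, v in enumerate(cols) if v not in in_eq]
        rows = [r for r in range(M) if r != i]
        sub = A[np.ix_(rows, excl_cols)]
        rank = np.linalg.matrix_rank(sub) if sub.size else 0
        rank_ok[eq] = bool(rank >= M - 1)

    p = len(names)
    n_moments = p * (p - 1) // 2
    rep = IdentificationReport(
        order=order, rank_ok=rank_ok, recursive=True,
        n_moments=n_moments, n_free=model.n_free_parameters,
    )
    if rep.df < 0:
        raise ValueError(
            f"model under-identified: {rep.n_free} free parameters for {n_moments} moments"
        )
    return rep


def hypothesized_crash_model(with_misconduct_to_collision: bool = False) -> PathModel:
    """The study-style five-variable crash model.

    Two correlated exogenous drivers (passenger presence, vehicle age), two
    mediators (driver misconduct, collision type) and a binary fatality
    outcome.  The misconduct -> collision path is the modification candidate;
    freed, it drops the model df from 3 to 2.
    """
    edges = [
        ("passenger", "misconduct"),
        ("passenger", "collision"),
        ("passenger", "fatality"),
        ("vehicle_age", "fatality"),
        ("misconduct", "fatality"),
        ("collision", "fatality"),
    ]
    # candidate paths honour temporal ordering (misconduct precedes the
    # collision), so the reverse collision -> misconduct link is not offered
    candidates = [
        ("misconduct", "collision"),
        ("vehicle_age", "misconduct"),
        ("vehicle_age", "collision"),
    ]
    if with_misconduct_to_collision:
        edges.append(("misconduct", "collision"))
        candidates.remove(("misconduct", "collision"))
    return PathModel(
        nodes=(
            ("passenger", "exogenous"),
            ("vehicle_age", "exogenous"),
            ("misconduct", "mediator"),
            ("collision", "mediator"),
            ("fatality", "final-endogenous"),
        ),
        edges=tuple(edges),
        covariances=(("passenger", "vehicle_age"),),
        candidates=tuple(candidates),
    )
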
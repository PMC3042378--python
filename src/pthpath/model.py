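"""Directed path models over clinical variables.

A path model is a directed acyclic graph whose nodes are observed clinical
variables and whose edges are hypothesized direct dependencies.  Every
endogenous node induces one regression equation: linear (Gaussian) if the
node is continuous, logistic if binary.  Edges may carry a sex-moderation
flag, which adds a male-offset parameter to that path (females are the
reference category; male coded 1).

The two builders encode the structural hypotheses of a mediation study of
metabolic syndrome (MS) in morbidly obese patients: seven explanatory
variables (age, type 2 diabetes, PTH, 25-OH vitamin D, magnesium,
albumin-corrected calcium, phosphate) with parathyroid hormone (PTH) as the
putative mediator.  ``build_initial_model`` is the full literature-derived
hypothesis; ``build_final_model`` is the pruned, sex-moderated model retained
after DIC-guided selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import yaml

__all__ = [
    "VariableSpec",
    "PathEdge",
    "Pathway",
    "PathModel",
    "ValidationReport",
    "ModelValidationError",
    "validate_model",
    "build_initial_model",
    "build_final_model",
    "enumerate_pathways",
    "read_model",
    "write_model",
]

SCALES = ("continuous", "binary")
ROLES = ("exogenous", "endogenous")


class ModelValidationError(ValueError):
    """Raised when a path model violates its structural contract."""


@dataclass(frozen=True)
class VariableSpec:
    """A named observed variable in the path diagram.

    ``scale`` is 'continuous' or 'binary' (binary variables take values in
    {0,1}); ``role`` is 'exogenous' (no incoming edges, simulated from
    marginals) or 'endogenous' (has a regression equation).  ``unit`` is free
    text, e.g. 'pmol/l'.
    """

    name: str
    scale: str
    role: str
    unit: str = ""

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ModelValidationError(f"unknown scale {self.scale!r} for {self.name}")
        if self.role not in ROLES:
            raise ModelValidationError(f"unknown role {self.role!r} for {self.name}")


@dataclass(frozen=True)
class PathEdge:
    """A directed dependency ``source -> target``.

    ``sex_moderated`` adds a male-offset parameter to this path, so the
    coefficient for males is (female coefficient + offset).
    """

    source: str
    target: str
    sex_moderated: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        star = "*" if self.sex_moderated else ""
        return f"{self.source}->{self.target}{star}"


@dataclass(frozen=True)
class Pathway:
    """An ordered chain of edges from a source to a terminal variable.

    ``quantifiable`` is True iff no *intermediate* variable on the path is
    binary: products of regression coefficients along a path are meaningful
    only when every mediator is continuous.  A binary terminal outcome does
    not disqualify the path; the product is then read on the log-odds scale.
    """

    edges: tuple[PathEdge, ...]
    quantifiable: bool

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.edges[0].source,) + tuple(e.target for e in self.edges)

    @property
    def mediators(self) -> tuple[str, ...]:
        return self.variables[1:-1]

    def __len__(self) -> int:
        return len(self.edges)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return "->".join(self.variables)


@dataclass
class PathModel:
    """A validated collection of variables and directed edges."""

    variables: dict[str, VariableSpec]
    edges: list[PathEdge]
    name: str = "path_model"

    # ---- construction helpers -------------------------------------------------

    @classmethod
    def from_specs(
        cls,
        variables: Iterable[VariableSpec],
        edges: Iterable[PathEdge],
        name: str = "path_model",
    ) -> "PathModel":
        vmap: dict[str, VariableSpec] = {}
        for v in variables:
            if v.name in vmap:
                raise ModelValidationError(f"duplicate variable name {v.name!r}")
            vmap[v.name] = v
        return cls(variables=vmap, edges=list(edges), name=name)

    # ---- queries ---------------------------------------------------------------

    def variable(self, name: str) -> VariableSpec:
        try:
            return self.variables[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r} in model {self.name!r}") from None

    @property
    def endogenous(self) -> list[str]:
        return [v.name for v in self.variables.values() if v.role == "endogenous"]

    @property
    def exogenous(self) -> list[str]:
        return [v.name for v in self.variables.values() if v.role == "exogenous"]

    def parents(self, name: str) -> list[str]:
        return [e.source for e in self.edges if e.target == name]

    def children(self, name: str) -> list[str]:
        return [e.target for e in self.edges if e.source == name]

    def edge(self, source: str, target: str) -> PathEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source}->{target} in model {self.name!r}")

    def has_edge(self, source: str, target: str) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    def is_binary(self, name: str) -> bool:
        return self.variable(name).scale == "binary"

    @property
    def moderated_edges(self) -> list[PathEdge]:
        return [e for e in self.edges if e.sex_moderated]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(e.pair for e in self.edges)
        return g

    def topological_order(self) -> list[str]:
        """Deterministic topological order of all variables (lexicographic ties)."""
        return list(nx.lexicographical_topological_sort(self.graph()))

    def equations(self) -> dict[str, list[str]]:
        """Outcome -> ordered predictor list, one entry per endogenous variable."""
        return {y: self.parents(y) for y in self.endogenous}

    def copy(self, name: str | None = None) -> "PathModel":
        return PathModel(
            variables=dict(self.variables),
            edges=list(self.edges),
            name=name or self.name,
        )

    # ---- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variables": [
                {"name": v.name, "scale": v.scale, "role": v.role, "unit": v.unit}
                for v in self.variables.values()
            ],
            "edges": [
                {"source": e.source, "target": e.target, "sex_moderated": e.sex_moderated}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PathModel":
        variables = [
            VariableSpec(
                name=v["name"],
                scale=v["scale"],
                role=v["role"],
                unit=v.get("unit", ""),
            )
            for v in data["variables"]
        ]
        edges = [
            PathEdge(
                source=e["source"],
                target=e["target"],
                sex_moderated=bool(e.get("sex_moderated", False)),
            )
            for e in data["edges"]
        ]
        return cls.from_specs(variables, edges, name=data.get("name", "path_model"))


@dataclass
class ValidationReport:
    """Outcome of structural validation; ``ok`` iff no violations were found."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise ModelValidationError("; ".join(self.violations))

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_model(model: PathModel) -> ValidationReport:
    """Check DAG semantics: acyclicity, role/edge consistency, no duplicates.

    Returns a report listing every violation rather than stopping at the
    first, so a malformed model specification can be fixed in one pass.
    """
    report = ValidationReport()
    names = set(model.variables)

    seen_pairs: set[tuple[str, str]] = set()
    for e in model.edges:
        if e.source not in names:
            report.violations.append(f"edge {e}: unknown source variable {e.source!r}")
        if e.target not in names:
            report.violations.append(f"edge {e}: unknown target variable {e.target!r}")
        if e.source == e.target:
            report.violations.append(f"edge {e}: self-loop")
        if e.pair in seen_pairs:
            report.violations.append(f"duplicate edge {e.source}->{e.target}")
        seen_pairs.add(e.pair)
        if e.target in names and model.variable(e.target).role == "exogenous":
            report.violations.append(
                f"edge {e}: target {e.target!r} is declared exogenous"
            )

    for v in model.variables.values():
        # a self-loop is not a usable predictor, so it does not rescue an
        # otherwise orphaned equation
        proper_parents = [p for p in model.parents(v.name) if p != v.name]
        if v.role == "endogenous" and not proper_parents:
            report.violations.append(
                f"endogenous variable {v.name!r} has no incoming edge"
            )

    g = model.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        cyc = "->".join(u for u, _ in cycle) + "->" + cycle[-1][1]
        report.violations.append(f"cycle detected: {cyc}")

    return report


# ---------------------------------------------------------------------------
# Canonical variable set for the PTH / metabolic-syndrome mediation system
# ---------------------------------------------------------------------------

def _clinical_variables() -> list[VariableSpec]:
    return [
        VariableSpec("age", "continuous", "exogenous", "years"),
        VariableSpec("vitD", "continuous", "exogenous", "nmol/l"),
        VariableSpec("magnesium", "continuous", "exogenous", "mmol/l"),
        VariableSpec("phosphate", "continuous", "exogenous", "mmol/l"),
        VariableSpec("calcium", "continuous", "endogenous", "mmol/l"),
        VariableSpec("PTH", "continuous", "endogenous", "pmol/l"),
        VariableSpec("T2DM", "binary", "endogenous", ""),
        VariableSpec("MS", "binary", "endogenous", ""),
    ]


def build_initial_model() -> PathModel:
    """The full hypothesized model, assembled from the literature.

    All seven explanatory variables point directly at MS; the candidate
    regulators of PTH secretion (age, vitamin D, magnesium, calcium,
    phosphate) point at PTH; vitamin D and phosphate point at calcium; and
    age and magnesium point at type 2 diabetes.  Four endogenous equations
    result: MS and T2DM logistic, PTH and calcium linear.
    """
    edges = [
        # direct effects on MS
        PathEdge("age", "MS"),
        PathEdge("T2DM", "MS"),
        PathEdge("PTH", "MS"),
        PathEdge("vitD", "MS"),
        PathEdge("magnesium", "MS"),
        PathEdge("calcium", "MS"),
        PathEdge("phosphate", "MS"),
        # regulation of PTH secretion
        PathEdge("age", "PTH"),
        PathEdge("vitD", "PTH"),
        PathEdge("magnesium", "PTH"),
        PathEdge("calcium", "PTH"),
        PathEdge("phosphate", "PTH"),
        # calcium homeostasis
        PathEdge("vitD", "calcium"),
        PathEdge("phosphate", "calcium"),
        # type 2 diabetes
        PathEdge("age", "T2DM"),
        PathEdge("magnesium", "T2DM"),
    ]
    return PathModel.from_specs(_clinical_variables(), edges, name="initial")


def build_final_model() -> PathModel:
    """The pruned, sex-moderated model retained after DIC-guided selection.

    Non-significant direct paths into MS (vitamin D, magnesium, calcium) and
    the vitamin D -> calcium path are removed; four paths carry male-offset
    parameters (age->MS, PTH->MS, phosphate->MS, age->PTH), the female
    coefficient being the reference.
    """
    edges = [
        PathEdge("T2DM", "MS"),
        PathEdge("age", "MS", sex_moderated=True),
        PathEdge("PTH", "MS", sex_moderated=True),
        PathEdge("phosphate", "MS", sex_moderated=True),
        PathEdge("age", "PTH", sex_moderated=True),
        PathEdge("magnesium", "PTH"),
        PathEdge("vitD", "PTH"),
        PathEdge("phosphate", "PTH"),
        PathEdge("calcium", "PTH"),
        PathEdge("phosphate", "calcium"),
        PathEdge("magnesium", "T2DM"),
        PathEdge("age", "T2DM"),
    ]
    return PathModel.from_specs(_clinical_variables(), edges, name="final")


def _pathway_from_nodes(model: PathModel, nodes: Sequence[str]) -> Pathway:
    edges = tuple(model.edge(a, b) for a, b in zip(nodes[:-1], nodes[1:]))
    quantifiable = not any(model.is_binary(v) for v in nodes[1:-1])
    return Pathway(edges=edges, quantifiable=quantifiable)


def enumerate_pathways(model: PathModel, source: str, target: str) -> list[Pathway]:
    """All directed simple paths source -> target, lexicographically ordered.

    Each pathway carries its ``quantifiable`` flag (False iff a binary
    mediator lies strictly between source and target).  Returns an empty
    list when target is unreachable; source == target is an error.
    """
    model.variable(source)
    model.variable(target)
    if source == target:
        raise ValueError("pathway source and target must differ")
    node_paths = sorted(nx.all_simple_paths(model.graph(), source, target))
    return [_pathway_from_nodes(model, p) for p in node_paths]


# ---------------------------------------------------------------------------
# File I/O: JSON or YAML model specifications, lossless round trip
# ---------------------------------------------------------------------------

def read_model(path: str | Path) -> PathModel:
    """Read a model specification from a .json/.yaml/.yml file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    model = PathModel.from_dict(data)
    validate_model(model).raise_if_invalid()
    return model


def write_model(model: PathModel, path: str | Path) -> None:
    """Write a model specification; format chosen by extension (.json else YAML)."""
    path = Path(path)
    data = model.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
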
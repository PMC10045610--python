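"""One-shot supernet over the searchable FPN neck.

The neck search space is a fully connected DAG whose nodes hold feature
pyramids: node P is the pyramid projected from the backbone, X_1..X_N are
intermediate pyramids and O is the neck output.  Every forward-ordered
node pair carries one edge, and every edge can realise any of the six
information paths; the four parameterized kinds own private, per-edge
weight bundles, while null and skip are parameter-free.  A node's value is
the element-wise sum of its incoming edge outputs, which makes the null
path a true additive identity and a sequential chain a special case of the
DAG.

Training follows the Single Path One-Shot recipe: each step samples one
subnet code uniformly (one kind per edge, re-drawn until the code routes
information from P to O through non-null edges) and updates only the
weights that subnet touches.  Trained once, the shared weights let the
evolutionary search rank thousands of subnets by inference alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import SGD, Tensor
from .fpn_paths import (
    PARAMETERIZED_KINDS,
    FeaturePyramid,
    PathKind,
    PathParams,
    apply_path,
)

__all__ = [
    "Edge",
    "SubnetCode",
    "SupernetDAG",
    "enumerate_edges",
    "count_subnets",
    "build_supernet",
    "sample_subnet",
    "forward_subnet",
    "train_supernet_step",
]

Edge = tuple  # (source node name, target node name)


def node_names(n_intermediate: int) -> list[str]:
    return ["P"] + [f"X{i}" for i in range(1, n_intermediate + 1)] + ["O"]


def enumerate_edges(n_intermediate: int) -> list[Edge]:
    """All forward-ordered node pairs of [P, X_1..X_N, O], fixed order.

    This ordering defines the genotype layout: subnet codes list one path
    kind per edge in exactly this sequence.
    """
    if n_intermediate < 0:
        raise ValueError("N must be >= 0")
    names = node_names(n_intermediate)
    return [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]


def count_subnets(n_intermediate: int, kinds: int = 6) -> int:
    """Size of the raw search space: kinds^(number of edges)."""
    return kinds ** len(enumerate_edges(n_intermediate))


@dataclass(frozen=True)
class SubnetCode:
    """One path kind per supernet edge — the searchable genotype."""

    assignment: tuple  # tuple of (edge, PathKind), in enumerate_edges order

    @classmethod
    def from_dict(cls, edges: list[Edge], kinds: dict) -> "SubnetCode":
        return cls(tuple((e, kinds[e]) for e in edges))

    @property
    def edges(self) -> list[Edge]:
        return [e for e, _ in self.assignment]

    def kind(self, edge: Edge) -> PathKind:
        return dict(self.assignment)[edge]

    def kinds(self) -> dict:
        return dict(self.assignment)

    def replace(self, edge: Edge, kind: PathKind) -> "SubnetCode":
        return SubnetCode(
            tuple((e, kind if e == edge else k) for e, k in self.assignment)
        )

    def to_json(self) -> str:
        return json.dumps([[list(e), k.value] for e, k in self.assignment])

    @classmethod
    def from_json(cls, text: str) -> "SubnetCode":
        items = json.loads(text)
        return cls(tuple((tuple(e), PathKind(k)) for e, k in items))

    def is_valid(self) -> bool:
        """True iff some directed P -> ... -> O route uses only non-null edges."""
        adj: dict = {}
        for (src, dst), kind in self.assignment:
            if kind is not PathKind.NULL:
                adj.setdefault(src, []).append(dst)
        frontier, seen = ["P"], {"P"}
        while frontier:
            node = frontier.pop()
            if node == "O":
                return True
            for nxt in adj.get(node, ()):  # noqa: B909
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        return False


class SupernetDAG:
    """The weight-sharing container: per-edge parameter bundles per kind."""

    def __init__(self, n_intermediate: int, channels: int, rng: np.random.Generator):
        if n_intermediate < 1:
            raise ValueError("N must be >= 1")
        if channels < 1:
            raise ValueError("channels must be >= 1")
        self.n_intermediate = n_intermediate
        self.channels = channels
        self.nodes = node_names(n_intermediate)
        self.edges = enumerate_edges(n_intermediate)
        self.params = {
            edge: {kind: PathParams(kind, channels, rng) for kind in PARAMETERIZED_KINDS}
            for edge in self.edges
        }

    def parameters(self, code: SubnetCode | None = None) -> list[Tensor]:
        """All shared weights, or only those the given code touches."""
        out: list[Tensor] = []
        if code is None:
            for bundles in self.params.values():
                for p in bundles.values():
                    out.extend(p.parameters())
            return out
        for edge, kind in code.assignment:
            if kind in PARAMETERIZED_KINDS:
                out.extend(self.params[edge][kind].parameters())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_supernet(
    n_intermediate: int = 5,
    channels: int = 112,
    rng: np.random.Generator | int | None = None,
) -> SupernetDAG:
    """Construct the supernet holding all information paths on every edge."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return SupernetDAG(n_intermediate, channels, rng)


def sample_subnet(dag: SupernetDAG, rng: np.random.Generator) -> SubnetCode:
    """Uniform single-path sampling; invalid codes (no route) are re-drawn."""
    kinds = list(PathKind)
    while True:
        draw = {e: kinds[rng.integers(len(kinds))] for e in dag.edges}
        code = SubnetCode.from_dict(dag.edges, draw)
        if code.is_valid():
            return code


def forward_subnet(
    dag: SupernetDAG, code: SubnetCode, pyramid: FeaturePyramid
) -> FeaturePyramid:
    """Evaluate one subnet: nodes in topological order, sum-aggregation."""
    if pyramid.channels != dag.channels:
        raise ValueError(
            f"input has {pyramid.channels} channels, supernet expects {dag.channels}"
        )
    if set(code.edges) != set(dag.edges):
        raise ValueError("subnet code does not match the supernet edge set")
    if not code.is_valid():
        raise ValueError("invalid subnet code: no non-null route P -> O")
    values = {"P": pyramid}
    kinds = code.kinds()
    for node in dag.nodes[1:]:
        acc = pyramid.zeros_like()
        for edge in dag.edges:
            if edge[1] != node:
                continue
            kind = kinds[edge]
            if kind is PathKind.NULL:
                continue
            params = dag.params[edge].get(kind)
            acc = acc + apply_path(kind, values[edge[0]], params)
        values[node] = acc
    return values["O"]


def train_supernet_step(
    dag: SupernetDAG,
    detector,
    batch,
    rng: np.random.Generator,
    lr: float | None = None,
):
    """One SPOS step: sample a subnet, descend on the loss through it only.

    ``detector`` provides ``loss_on_batch(batch, code)`` and a ``config``
    with the default learning rate; all trainable parameters (backbone,
    neck weights the code touches, heads) receive one SGD update.
    Parameters of edges outside the sampled code keep zero gradient and
    are untouched.

    Returns (LossBreakdown, sampled code).
    """
    if not batch:
        raise ValueError("empty batch")
    code = sample_subnet(dag, rng)
    params = detector.parameters(code=code)
    opt = SGD(params, lr=detector.config.lr if lr is None else lr)
    opt.zero_grad()
    loss = detector.loss_on_batch(batch, code=code)
    loss.total_tensor.backward()
    opt.step()
    loss.total_tensor = None  # free the graph
    return loss, code
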
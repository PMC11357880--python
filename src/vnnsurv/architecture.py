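"""Compilation of gene sets plus a pathway hierarchy into a layered,
sparsely connected visible-network specification.

The visible network mirrors biology: input neurons are gene-alteration
indicators, hidden neurons are pathways, and a connection exists only when
the gene is a member of the pathway or the source pathway is a child of the
target pathway.  Parentless (root) pathways feed a root embedding.  Because
pathway hierarchies are not strict (a gene may belong to a deep pathway, a
child may sit several layers below its parent), frozen identity
*skip-through* channels carry values untouched across intermediate layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import FormatError, GeneSetCollection, HierarchyEdges

__all__ = [
    "PathwayGraph",
    "VNNSpec",
    "ArchitectureError",
    "build_pathway_graph",
    "assign_layers",
    "build_masks",
    "build_vnn_spec",
]


class ArchitectureError(ValueError):
    """The gene sets / hierarchy cannot be compiled into a valid network."""


@dataclass
class PathwayGraph:
    """Pathway universe pruned to what the input gene panel can reach.

    A pathway is retained when an input gene is a member, or when a
    retained pathway is its child (transitively).  Input genes belonging to
    no retained pathway are *orphans*: they bypass the hidden layers and
    connect straight to the root embedding so that no input is silently
    discarded.
    """

    nodes: tuple[str, ...]
    gene_membership: dict[str, frozenset[str]]   # input gene -> retained pathways
    parent_edges: tuple[tuple[str, str], ...]    # (child, parent), both retained
    roots: tuple[str, ...]                       # retained pathways with no parent
    input_genes: tuple[str, ...]
    orphan_genes: tuple[str, ...]

    def children_of(self, pathway: str) -> list[str]:
        return sorted(c for c, p in self.parent_edges if p == pathway)

    def members_of(self, pathway: str) -> list[str]:
        return sorted(g for g, ps in self.gene_membership.items() if pathway in ps)


def build_pathway_graph(
    gene_sets: GeneSetCollection,
    hierarchy: HierarchyEdges,
    input_genes,
) -> PathwayGraph:
    """Prune the pathway universe to the nodes reachable from ``input_genes``.

    Reachability runs from direct gene membership through child-to-parent
    edges.  Rejects an empty retained set and any cycle among retained
    pathways (the offending cycle is reported).
    """
    input_genes = tuple(input_genes)
    if not input_genes:
        raise ArchitectureError("input gene panel is empty")

    membership = {g: gene_sets.pathways_of(g) for g in input_genes}
    seeds = set().union(*membership.values()) if membership else set()
    orphans = tuple(g for g in input_genes if not membership[g])
    if not seeds:
        raise ArchitectureError("no input gene belongs to any pathway; retained set empty")

    parents_of: dict[str, set[str]] = {}
    for child, parent in hierarchy:
        parents_of.setdefault(child, set()).add(parent)

    retained: set[str] = set()
    frontier = list(seeds)
    while frontier:
        node = frontier.pop()
        if node in retained:
            continue
        retained.add(node)
        frontier.extend(parents_of.get(node, ()))

    edges = tuple(
        sorted((c, p) for c, p in set(hierarchy) if c in retained and p in retained)
    )
    dag = nx.DiGraph(edges)
    dag.add_nodes_from(retained)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ArchitectureError(f"pathway hierarchy contains a cycle: {cycle}")

    with_parent = {c for c, _ in edges}
    roots = tuple(sorted(retained - with_parent))
    gene_membership = {
        g: frozenset(p for p in ps if p in retained) for g, ps in membership.items()
    }
    return PathwayGraph(
        nodes=tuple(sorted(retained)),
        gene_membership=gene_membership,
        parent_edges=edges,
        roots=roots,
        input_genes=input_genes,
        orphan_genes=orphans,
    )


def assign_layers(graph: PathwayGraph) -> tuple[dict[str, int], int]:
    """Longest-chain layering: ``layer(p) = 1 +`` length of the longest
    child-chain below *p*.  Leaf pathways sit at layer 1 and every parent
    sits strictly above all of its children, which a shortest-path layering
    does not guarantee.  Returns ``(layer_of, n_layers)``.
    """
    children: dict[str, list[str]] = {p: [] for p in graph.nodes}
    for child, parent in graph.parent_edges:
        children[parent].append(child)

    layer: dict[str, int] = {}

    dag = nx.DiGraph(graph.parent_edges)
    dag.add_nodes_from(graph.nodes)
    for node in nx.topological_sort(dag):  # children before parents
        kids = children[node]
        layer[node] = 1 + max((layer[c] for c in kids), default=0)
    n_layers = max(layer.values())
    return layer, n_layers


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------

_G = "g:"   # unit owner prefixes
_P = "p:"


@dataclass
class VNNSpec:
    """Compiled visible architecture: per-layer connectivity masks plus the
    bookkeeping the model and the interpretation layer need.

    ``masks[k]`` marks learnable positions of layer ``k+1`` (sources are the
    units of interface ``k``); ``frozen[k]`` holds the constant identity
    entries of the skip-through channels.  ``passthrough[k]`` flags target
    units that are skip-through (no bias, no activation, no dropout).
    """

    n_layers: int
    layer_of: dict[str, int]
    node_width: int
    feature_order: tuple[str, ...]
    unit_names: list[list[str]]          # interface 0..L unit labels
    masks: list[np.ndarray]              # learnable-position masks, float {0,1}
    frozen: list[np.ndarray]             # frozen identity entries, float {0,1}
    passthrough: list[np.ndarray]        # bool per target unit, layers 1..L
    pathway_blocks: dict[str, tuple[int, int, int]]  # pathway -> (layer, start, stop)
    root_mode: str                       # "concat" | "dense"
    root_width: int
    orphan_genes: tuple[str, ...]
    roots: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return len(self.feature_order)

    def layer_shapes(self) -> list[tuple[int, int]]:
        return [m.shape for m in self.masks]

    def validate(self) -> None:
        for k, (mask, fro) in enumerate(zip(self.masks, self.frozen)):
            if mask.shape != fro.shape:
                raise ArchitectureError(f"layer {k + 1}: mask/frozen shape mismatch")
            if ((mask != 0) & (mask != 1)).any() or ((fro != 0) & (fro != 1)).any():
                raise ArchitectureError(f"layer {k + 1}: non-binary mask entry")
            if (mask * fro).any():
                raise ArchitectureError(f"layer {k + 1}: learnable and frozen overlap")

    # -- text serialization (sparse triplet form) -----------------------
    def to_json(self) -> str:
        def sparse(m):
            r, c = np.nonzero(m)
            return {"shape": list(m.shape), "rows": r.tolist(), "cols": c.tolist()}

        payload = {
            "format": "vnnsurv-spec-v1",
            "n_layers": self.n_layers,
            "layer_of": self.layer_of,
            "node_width": self.node_width,
            "feature_order": list(self.feature_order),
            "unit_names": self.unit_names,
            "masks": [sparse(m) for m in self.masks],
            "frozen": [sparse(m) for m in self.frozen],
            "passthrough": [p.tolist() for p in self.passthrough],
            "pathway_blocks": {p: list(v) for p, v in self.pathway_blocks.items()},
            "root_mode": self.root_mode,
            "root_width": self.root_width,
            "orphan_genes": list(self.orphan_genes),
            "roots": list(self.roots),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "VNNSpec":
        payload = json.loads(text)
        if payload.get("format") != "vnnsurv-spec-v1":
            raise FormatError("not a vnnsurv architecture file")

        def dense(d):
            m = np.zeros(tuple(d["shape"]))
            m[d["rows"], d["cols"]] = 1.0
            return m

        return cls(
            n_layers=payload["n_layers"],
            layer_of=payload["layer_of"],
            node_width=payload["node_width"],
            feature_order=tuple(payload["feature_order"]),
            unit_names=payload["unit_names"],
            masks=[dense(d) for d in payload["masks"]],
            frozen=[dense(d) for d in payload["frozen"]],
            passthrough=[np.asarray(p, dtype=bool) for p in payload["passthrough"]],
            pathway_blocks={p: tuple(v) for p, v in payload["pathway_blocks"].items()},
            root_mode=payload["root_mode"],
            root_width=payload["root_width"],
            orphan_genes=tuple(payload["orphan_genes"]),
            roots=tuple(payload["roots"]),
        )


def build_masks(
    graph: PathwayGraph,
    layers: dict[str, int] | None = None,
    node_width: int = 1,
    root_mode: str = "concat",
    root_width: int | None = None,
) -> VNNSpec:
    """Lay out units interface by interface and emit binary masks.

    Interface 0 carries one unit per input gene (in panel order).  For each
    layer ``k`` the targets are the neuron blocks of pathways assigned to
    layer ``k`` followed by skip-through channels for every value still
    needed deeper in the network.  Under ``concat`` root mode the root
    embedding is the full final interface (root-pathway blocks plus orphan
    gene channels); ``dense`` adds a learnable projection to ``root_width``.
    """
    if node_width < 1:
        raise ArchitectureError("node_width must be >= 1")
    if root_mode not in ("concat", "dense"):
        raise ArchitectureError(f"unknown root mode {root_mode!r}")
    if layers is None:
        layers, _ = assign_layers(graph)
    missing = [p for p in graph.nodes if p not in layers]
    if missing:
        raise ArchitectureError(f"pathways missing a layer assignment: {missing}")
    n_layers = max(layers.values())

    parents: dict[str, list[str]] = {p: [] for p in graph.nodes}
    for child, parent in graph.parent_edges:
        parents[child].append(parent)

    # Units are (owner, channel) pairs.  An owner's value becomes available
    # at interface `avail` and is consumed last at layer `last`; skip-through
    # copies exist at every interface strictly between the two.
    avail: dict[str, int] = {}
    last: dict[str, int] = {}
    root_sentinel = n_layers + 1
    for g in graph.input_genes:
        avail[_G + g] = 0
        consumer_layers = [layers[p] for p in graph.gene_membership[g]]
        if g in graph.orphan_genes:
            consumer_layers.append(root_sentinel)
        last[_G + g] = max(consumer_layers)
    for p in graph.nodes:
        avail[_P + p] = layers[p]
        consumer_layers = [layers[q] for q in parents[p]]
        if not consumer_layers:  # root pathway: feeds the root embedding
            consumer_layers = [root_sentinel]
        last[_P + p] = max(consumer_layers)

    def owner_width(owner: str) -> int:
        return 1 if owner.startswith(_G) else node_width

    # interface unit lists
    interfaces: list[list[tuple[str, int]]] = [
        [(_G + g, 0) for g in graph.input_genes]
    ]
    pathway_blocks: dict[str, tuple[int, int, int]] = {}
    passthrough_flags: list[np.ndarray] = []
    for k in range(1, n_layers + 1):
        units: list[tuple[str, int]] = []
        flags: list[bool] = []
        for p in sorted(graph.nodes):
            if layers[p] == k:
                start = len(units)
                units.extend((_P + p, c) for c in range(node_width))
                flags.extend([False] * node_width)
                pathway_blocks[p] = (k, start, start + node_width)
        for owner in sorted(avail):
            if avail[owner] < k < last[owner]:
                units.extend((owner, c) for c in range(owner_width(owner)))
                flags.extend([True] * owner_width(owner))
        interfaces.append(units)
        passthrough_flags.append(np.asarray(flags, dtype=bool))

    masks: list[np.ndarray] = []
    frozen: list[np.ndarray] = []
    for k in range(1, n_layers + 1):
        src = {u: i for i, u in enumerate(interfaces[k - 1])}
        tgt_units = interfaces[k]
        mask = np.zeros((len(src), len(tgt_units)))
        fro = np.zeros_like(mask)
        for j, (owner, chan) in enumerate(tgt_units):
            if passthrough_flags[k - 1][j]:
                fro[src[(owner, chan)], j] = 1.0
                continue
            p = owner[len(_P):]
            sources: list[tuple[str, int]] = []
            for g in graph.members_of(p):
                sources.append((_G + g, 0))
            for c in graph.children_of(p):
                sources.extend((_P + c, cc) for cc in range(node_width))
            for s in sources:
                mask[src[s], j] = 1.0
        masks.append(mask)
        frozen.append(fro)

    final_width = len(interfaces[n_layers])
    if root_mode == "concat":
        rw = final_width
    else:
        if root_width is None or root_width < 1:
            raise ArchitectureError("dense root mode requires a positive root_width")
        rw = int(root_width)

    unit_names = [
        [f"{owner}[{chan}]" if owner.startswith(_P) else owner[len(_G):]
         for owner, chan in iface]
        for iface in interfaces
    ]
    spec = VNNSpec(
        n_layers=n_layers,
        layer_of=dict(layers),
        node_width=node_width,
        feature_order=tuple(graph.input_genes),
        unit_names=unit_names,
        masks=masks,
        frozen=frozen,
        passthrough=passthrough_flags,
        pathway_blocks=pathway_blocks,
        root_mode=root_mode,
        root_width=rw,
        orphan_genes=graph.orphan_genes,
        roots=graph.roots,
    )
    spec.validate()
    return spec


def build_vnn_spec(
    gene_sets: GeneSetCollection,
    hierarchy: HierarchyEdges,
    input_genes,
    node_width: int = 1,
    root_mode: str = "concat",
    root_width: int | None = None,
) -> VNNSpec:
    """One-call pipeline: prune, layer and mask."""
    graph = build_pathway_graph(gene_sets, hierarchy, input_genes)
    layers, _ = assign_layers(graph)
    return build_masks(graph, layers, node_width, root_mode, root_width)
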
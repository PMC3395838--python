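"""Compartment-aware mixed interaction graphs.

A gene list plus a compendium of typed molecular interactions (predicted and
curated TF->target, miRNA->target, kinase->substrate, protein-protein) is
turned into a mixed graph whose nodes are *gene-product instances*: one node
per (gene, cellular compartment) pair, placed inside nested zones mirroring a
pruned Cellular Component hierarchy.  Layout is a force simulation (mutual
repulsion, edge springs, a pull toward the compartment anchor) with
per-step clamping into the compartment zone.  Filters remove orphan
instances, empty compartments and implausible intercompartmental physical
edges; graphs export to SIF, GraphML and a TSV edge list.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

CATEGORIES = {
    "tf_target_predicted", "tf_target_chip", "tf_target_curated",
    "mirna_target", "kinase_substrate", "ppi",
}
SIGNS = {"activation", "repression", "ambiguous", "none"}
REGULATORY = {"tf_target_predicted", "tf_target_chip", "tf_target_curated",
              "mirna_target"}

#: Edge rendering hints keyed by sign: (color, arrowhead shape).
SIGN_RENDERING = {
    "activation": ("green", "arrow"),
    "repression": ("red", "T"),
    "ambiguous": ("violet", "dot"),
    "none": ("grey", "none"),
}

FALLBACK_COMPARTMENT = "intracellular"


class InteractionFormatError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionRecord:
    """One typed, optionally signed molecular interaction."""

    source_id: str
    target_id: str
    category: str
    sign: str = "none"
    directed: bool = True
    provenance: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InteractionFormatError(f"unknown category {self.category!r}")
        if self.sign not in SIGNS:
            raise InteractionFormatError(f"unknown sign {self.sign!r}")
        if self.category == "ppi":
            if self.sign != "none":
                raise InteractionFormatError("ppi records cannot carry a sign")
            if self.directed:
                raise InteractionFormatError("ppi records are undirected")
        elif not self.directed:
            raise InteractionFormatError(
                f"{self.category} records are directed")


def make_record(source_id, target_id, category, sign=None, provenance=""):
    """Apply the defaulting rules: miRNA targets default to repression,
    regulatory records without a stated sign are ambiguous, ppi undirected."""
    if category == "ppi":
        return InteractionRecord(source_id, target_id, "ppi", "none",
                                 directed=False, provenance=provenance)
    if sign is None or sign == "":
        sign = "repression" if category == "mirna_target" else "ambiguous"
    return InteractionRecord(source_id, target_id, category, sign,
                             directed=True, provenance=provenance)


def load_interaction_table(source) -> list[InteractionRecord]:
    """Parse the tabulated flat-file dialect.

    Header line required; columns: source, target, category, sign (optional),
    provenance (optional).  Errors carry the 1-based line number.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    lines = stream.read().splitlines()
    if not lines:
        return []
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:3] != ["source", "target", "category"]:
        raise InteractionFormatError(
            "header must start with: source, target, category")
    records = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise InteractionFormatError(
                f"line {lineno}: expected >= 3 tab-separated fields")
        fields += [""] * (5 - len(fields))
        source_id, target_id, category, sign, prov = (f.strip() for f in fields[:5])
        if category == "ppi" and sign:
            raise InteractionFormatError(
                f"line {lineno}: ppi records cannot carry a sign")
        try:
            records.append(make_record(source_id, target_id, category,
                                       sign or None, prov))
        except InteractionFormatError as exc:
            raise InteractionFormatError(f"line {lineno}: {exc}") from None
    return records


def write_interaction_table(records, stream) -> None:
    stream.write("source\ttarget\tcategory\tsign\tprovenance\n")
    for r in records:
        sign = "" if r.category == "ppi" else r.sign
        stream.write(f"{r.source_id}\t{r.target_id}\t{r.category}\t{sign}\t"
                     f"{r.provenance}\n")


# ---------------------------------------------------------------------------
# Compartment tree


@dataclass
class CompartmentTree:
    """Rooted subset of the Cellular Component hierarchy used for layout."""

    parent: dict[str, str | None]  # term -> parent (root maps to None)
    labels: dict[str, str] = field(default_factory=dict)
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        roots = [t for t, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("compartment tree needs exactly one root")
        self.root = roots[0]
        for term, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValueError(f"parent {par!r} of {term!r} not in tree")
            # cycle check by walking up
            seen = {term}
            cur = par
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle through {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]

    def __contains__(self, term):
        return term in self.parent

    def depth(self, term) -> int:
        d = 0
        while self.parent[term] is not None:
            term = self.parent[term]
            d += 1
        return d

    def children(self, term):
        return sorted(t for t, p in self.parent.items() if p == term)

    def is_parent_child(self, a, b) -> bool:
        return self.parent.get(a) == b or self.parent.get(b) == a


def default_compartment_tree() -> CompartmentTree:
    """Bundled default: cell -> {extracellular region, plasma membrane,
    intracellular -> {cytosol, nucleus, mitochondrion, endoplasmic reticulum,
    Golgi apparatus}}."""
    parent = {
        "cell": None,
        "extracellular region": "cell",
        "plasma membrane": "cell",
        "intracellular": "cell",
        "cytosol": "intracellular",
        "nucleus": "intracellular",
        "mitochondrion": "intracellular",
        "endoplasmic reticulum": "intracellular",
        "Golgi apparatus": "intracellular",
    }
    return CompartmentTree(parent=parent)


#: Extra compartment pairs treated as adjacent by the intercompartmental
#: filter, besides identity and parent/child.
DEFAULT_EXTRA_ADJACENT = frozenset({
    frozenset({"extracellular region", "plasma membrane"}),
})


def read_compartment_tree_tsv(source) -> CompartmentTree:
    """Parse a parent-child TSV: child TAB parent (root has empty parent)."""
    stream = io.StringIO(source) if isinstance(source, str) else source
    parent: dict[str, str | None] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        child = fields[0].strip()
        par = fields[1].strip() if len(fields) > 1 and fields[1].strip() else None
        parent[child] = par
    return CompartmentTree(parent=parent)


def read_compartment_tree_obo(source, root: str | None = None) -> CompartmentTree:
    """Build the tree from an OBO subset via its is_a / part_of edges."""
    import obonet

    stream = io.StringIO(source) if isinstance(source, str) else source
    g = obonet.read_obo(stream)
    parent: dict[str, str | None] = {}
    labels = {}
    for node, data in g.nodes(data=True):
        labels[node] = data.get("name", node)
        parents = list(g.successors(node))
        parent[node] = parents[0] if parents else None
    if root is not None:
        for term, par in list(parent.items()):
            if term == root:
                parent[term] = None
    tree = CompartmentTree(parent=parent, labels=labels)
    return tree


def assign_compartments(gene_ids, cc_map: dict[str, list],
                        tree: CompartmentTree,
                        cc_ancestry: dict[str, str] | None = None,
                        fallback: str = FALLBACK_COMPARTMENT):
    """Per-gene sets of tree compartments.

    An annotated term maps to itself when present in the tree, otherwise it
    is walked up ``cc_ancestry`` (term -> parent outside the subset) to the
    nearest tree term; a gene without any mapping gets the fallback term, so
    poorly annotated products land in a generic high-level zone.
    """
    if fallback not in tree:
        raise ValueError(f"fallback term {fallback!r} not in tree")
    cc_ancestry = cc_ancestry or {}
    out: dict[str, set[str]] = {}
    for gene in gene_ids:
        mapped: set[str] = set()
        for term in cc_map.get(gene, []):
            cur = term
            seen = set()
            while cur is not None and cur not in tree and cur not in seen:
                seen.add(cur)
                cur = cc_ancestry.get(cur)
            if cur in tree:
                mapped.add(cur)
        out[gene] = mapped or {fallback}
    return out


def read_cc_map_tsv(source) -> dict[str, list[str]]:
    """gene_id TAB cc_term (one annotation per line)."""
    stream = io.StringIO(source) if isinstance(source, str) else source
    cc: dict[str, list[str]] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        gene, term = line.split("\t")[:2]
        cc.setdefault(gene.strip(), []).append(term.strip())
    return cc


# ---------------------------------------------------------------------------
# Mixed graph


@dataclass(frozen=True)
class ProductInstance:
    gene_id: str
    compartment: str
    has_regulatory_info: bool = False

    @property
    def key(self) -> str:
        return f"{self.gene_id}::{self.compartment}"


@dataclass
class Zone:
    """Axis-aligned layout rectangle of one compartment."""

    term: str
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def anchor(self):
        return np.array([(self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2])

    def contains(self, p, eps=1e-6) -> bool:
        return (self.x0 - eps <= p[0] <= self.x1 + eps
                and self.y0 - eps <= p[1] <= self.y1 + eps)


@dataclass
class GraphEdge:
    from_instance: str
    to_instance: str
    record: InteractionRecord


@dataclass
class MixedGraph:
    instances: dict[str, ProductInstance]
    edges: list[GraphEdge]
    zones: dict[str, Zone]
    tree: CompartmentTree
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return {inst.gene_id for inst in self.instances.values()}

    def degree(self, key) -> int:
        return sum(1 for e in self.edges
                   if e.from_instance == key or e.to_instance == key)


def compute_zones(tree: CompartmentTree, width: float = 1200.0,
                  height: float = 800.0, margin: float = 0.06) -> dict[str, Zone]:
    """Nested rectangles mirroring the tree: children tiled in a grid strictly
    inside their parent, shrunk by ``margin`` of the parent's extent."""
    zones = {tree.root: Zone(tree.root, 0.0, 0.0, width, height)}

    def recurse(term):
        kids = tree.children(term)
        if not kids:
            return
        z = zones[term]
        mx = (z.x1 - z.x0) * margin
        my = (z.y1 - z.y0) * margin
        x0, y0, x1, y1 = z.x0 + mx, z.y0 + my, z.x1 - mx, z.y1 - my
        ncols = int(np.ceil(np.sqrt(len(kids))))
        nrows = int(np.ceil(len(kids) / ncols))
        cw = (x1 - x0) / ncols
        ch = (y1 - y0) / nrows
        pad_x, pad_y = cw * margin, ch * margin
        for i, kid in enumerate(kids):
            r, c = divmod(i, ncols)
            zones[kid] = Zone(
                kid,
                x0 + c * cw + pad_x, y0 + r * ch + pad_y,
                x0 + (c + 1) * cw - pad_x, y0 + (r + 1) * ch - pad_y)
            recurse(kid)

    recurse(tree.root)
    return zones


def build_mixed_graph(gene_list, records, compartments: dict[str, set],
                      tree: CompartmentTree | None = None) -> MixedGraph:
    """Materialize instances and edges for a gene list.

    One instance per (gene, compartment); an interaction record yields one
    edge between *every* instance pair of its two genes (implausible ones are
    left to the intercompartmental filter).  ``has_regulatory_info`` marks
    genes appearing as the source of a regulatory record anywhere in the
    compendium.
    """
    tree = tree or default_compartment_tree()
    genes = list(dict.fromkeys(gene_list))
    gene_set = set(genes)
    regulators = {r.source_id for r in records if r.category in REGULATORY}
    instances: dict[str, ProductInstance] = {}
    for gene in genes:
        for comp in sorted(compartments.get(gene, {FALLBACK_COMPARTMENT})):
            inst = ProductInstance(gene_id=gene, compartment=comp,
                                   has_regulatory_info=gene in regulators)
            instances[inst.key] = inst
    by_gene: dict[str, list[str]] = {}
    for key, inst in instances.items():
        by_gene.setdefault(inst.gene_id, []).append(key)
    edges = []
    for rec in records:
        if rec.source_id in gene_set and rec.target_id in gene_set:
            for a in by_gene[rec.source_id]:
                for b in by_gene[rec.target_id]:
                    if a != b:
                        edges.append(GraphEdge(a, b, rec))
    return MixedGraph(instances=instances, edges=edges,
                      zones=compute_zones(tree), tree=tree)


# ---------------------------------------------------------------------------
# Layout


def compartment_layout(graph: MixedGraph, repulsion: float = 2000.0,
                       spring: float = 0.02, anchor_pull: float = 2.0,
                       iterations: int = 200, seed: int = 0,
                       rest_length: float = 60.0, step: float = 1.0,
                       tolerance: float = 1e-3) -> MixedGraph:
    """Force-directed placement with compartment anchoring.

    Nodes repel pairwise (inverse-square), edges act as springs toward
    ``rest_length``, and every node feels a pull toward its compartment
    anchor (constant beyond a softening radius, linear within, so isolated
    nodes settle exactly on the anchor).  After each step positions are
    clamped inside the compartment zone, which guarantees containment
    irrespective of force equilibrium.  Deterministic given ``seed``.
    """
    if min(repulsion, spring, anchor_pull, step) <= 0 or iterations < 1:
        raise ValueError("layout parameters must be positive")
    keys = sorted(graph.instances)
    n = len(keys)
    if n == 0:
        graph.positions = {}
        return graph
    idx = {k: i for i, k in enumerate(keys)}
    rng = np.random.default_rng(seed)
    anchors = np.array([graph.zones[graph.instances[k].compartment].anchor
                        for k in keys])
    pos = anchors + rng.uniform(-10, 10, size=(n, 2))
    bounds = np.array([
        [graph.zones[graph.instances[k].compartment].x0,
         graph.zones[graph.instances[k].compartment].y0,
         graph.zones[graph.instances[k].compartment].x1,
         graph.zones[graph.instances[k].compartment].y1]
        for k in keys])
    pairs = np.array([[idx[e.from_instance], idx[e.to_instance]]
                      for e in graph.edges], dtype=int).reshape(-1, 2)
    d_soft = 5.0
    for _ in range(iterations):
        force = np.zeros((n, 2))
        # pairwise inverse-square repulsion
        delta = pos[:, None, :] - pos[None, :, :]
        dist2 = (delta ** 2).sum(-1)
        np.fill_diagonal(dist2, np.inf)
        dist2 = np.maximum(dist2, 1.0)
        force += (repulsion / dist2[..., None]
                  * delta / np.sqrt(dist2)[..., None]).sum(axis=1)
        # edge springs
        if len(pairs):
            d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            dist = np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
            f = spring * (dist - rest_length) * d / dist
            np.add.at(force, pairs[:, 0], -f)
            np.add.at(force, pairs[:, 1], f)
        # anchor pull: constant far away, linear inside the softening radius
        d = anchors - pos
        dist = np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
        force += anchor_pull * d / dist * np.minimum(dist / d_soft, 1.0)
        move = step * np.clip(force, -30, 30)
        pos = pos + move
        pos[:, 0] = np.clip(pos[:, 0], bounds[:, 0] + 1.0, bounds[:, 2] - 1.0)
        pos[:, 1] = np.clip(pos[:, 1], bounds[:, 1] + 1.0, bounds[:, 3] - 1.0)
        if np.abs(move).max() < tolerance:
            break
    graph.positions = {k: pos[i].copy() for k, i in idx.items()}
    return graph


# ---------------------------------------------------------------------------
# Filters / expansion / export


def compartments_adjacent(tree: CompartmentTree, a: str, b: str,
                          extra_pairs=DEFAULT_EXTRA_ADJACENT) -> bool:
    if a == b:
        return True
    if tree.is_parent_child(a, b):
        return True
    return frozenset({a, b}) in extra_pairs


def apply_graph_filters(graph: MixedGraph, hide_orphans: bool = False,
                        hide_empty_compartments: bool = False,
                        hide_intercompartmental: bool = False,
                        extra_adjacent=DEFAULT_EXTRA_ADJACENT) -> MixedGraph:
    """Apply the display filters; returns a new graph, input untouched.

    The intercompartmental filter removes only *undirected physical* edges
    whose endpoint compartments are not identical, parent/child, or listed as
    adjacent; directed regulatory and kinase edges always survive it.
    """
    edges = list(graph.edges)
    instances = dict(graph.instances)
    if hide_intercompartmental:
        def keep(e):
            if e.record.directed:
                return True
            ca = instances[e.from_instance].compartment
            cb = instances[e.to_instance].compartment
            return compartments_adjacent(graph.tree, ca, cb, extra_adjacent)
        edges = [e for e in edges if keep(e)]
    if hide_orphans:
        deg: dict[str, int] = {}
        for e in edges:
            deg[e.from_instance] = deg.get(e.from_instance, 0) + 1
            deg[e.to_instance] = deg.get(e.to_instance, 0) + 1
        instances = {k: v for k, v in instances.items() if deg.get(k, 0) > 0}
        edges = [e for e in edges
                 if e.from_instance in instances and e.to_instance in instances]
    zones = dict(graph.zones)
    if hide_empty_compartments:
        occupied = {inst.compartment for inst in instances.values()}
        # keep ancestors of occupied zones so nesting stays drawable
        keep_terms = set()
        for term in occupied:
            cur = term
            while cur is not None:
                keep_terms.add(cur)
                cur = graph.tree.parent[cur]
        zones = {t: z for t, z in zones.items() if t in keep_terms}
    out = MixedGraph(instances=instances, edges=edges, zones=zones,
                     tree=graph.tree,
                     positions={k: v for k, v in graph.positions.items()
                                if k in instances})
    return out


def expand_neighbors(graph: MixedGraph, selected, records,
                     compartments: dict[str, set] | None = None,
                     mode: str = "all_interactors") -> MixedGraph:
    """Grow the graph from a compendium.

    ``all_interactors`` adds every partner of any selected gene;
    ``common_interactors`` only genes interacting with *every* selected gene.
    New edges among all displayed genes are then materialized.
    """
    if mode not in ("all_interactors", "common_interactors"):
        raise ValueError(f"unknown expansion mode {mode!r}")
    selected = set(selected)
    current = graph.genes()
    if not selected:
        return graph
    if not selected <= current:
        raise ValueError("selected genes must already be in the graph")
    partners: dict[str, set[str]] = {g: set() for g in selected}
    for r in records:
        if r.source_id in selected:
            partners[r.source_id].add(r.target_id)
        if r.target_id in selected:
            partners[r.target_id].add(r.source_id)
    if mode == "all_interactors":
        new = set().union(*partners.values())
    else:
        new = set.intersection(*partners.values())
    new -= current
    all_genes = sorted(current) + sorted(new)
    comp = dict(compartments or {})
    for inst in graph.instances.values():
        comp.setdefault(inst.gene_id, set()).add(inst.compartment)
    return build_mixed_graph(all_genes, records, comp, graph.tree)


def _sif_relation(record: InteractionRecord) -> str:
    if record.category == "ppi":
        return "binds"
    if record.category == "kinase_substrate":
        return "phosphorylates"
    if record.category == "mirna_target":
        return "targets"
    return {"activation": "activates", "repression": "represses"}.get(
        record.sign, "regulates")


def export_graph(graph: MixedGraph, format: str = "sif") -> str:
    """Serialize for downstream network tools (Cytoscape-compatible)."""
    if format == "sif":
        lines = []
        seen = set()
        for e in graph.edges:
            a = graph.instances[e.from_instance].gene_id
            b = graph.instances[e.to_instance].gene_id
            rel = _sif_relation(e.record)
            key = (a, rel, b) if e.record.directed else (
                min(a, b), rel, max(a, b))
            if key not in seen:
                seen.add(key)
                lines.append(f"{key[0]}\t{rel}\t{key[2]}")
        return "\n".join(lines) + ("\n" if lines else "")
    if format == "tsv":
        lines = ["from\tto\tcategory\tsign\tdirected\tprovenance"]
        for e in graph.edges:
            r = e.record
            lines.append(f"{e.from_instance}\t{e.to_instance}\t{r.category}\t"
                         f"{r.sign}\t{int(r.directed)}\t{r.provenance}")
        return "\n".join(lines) + "\n"
    if format == "graphml":
        g = nx.MultiDiGraph()
        for key, inst in graph.instances.items():
            p = graph.positions.get(key)
            g.add_node(key, gene_id=inst.gene_id, compartment=inst.compartment,
                       has_regulatory_info=inst.has_regulatory_info,
                       x=float(p[0]) if p is not None else 0.0,
                       y=float(p[1]) if p is not None else 0.0)
        for e in graph.edges:
            color, arrowhead = SIGN_RENDERING[e.record.sign]
            g.add_edge(e.from_instance, e.to_instance,
                       category=e.record.category, sign=e.record.sign,
                       directed=e.record.directed,
                       provenance=e.record.provenance,
                       color=color, arrowhead=arrowhead)
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()
    raise ValueError(f"unknown export format {format!r}")
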
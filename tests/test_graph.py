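"""Mixed interaction graphs: records, compartments, layout, filters, export."""

import io

import networkx as nx
import numpy as np
import pytest

from phylofoot import (
    apply_graph_filters,
    assign_compartments,
    build_mixed_graph,
    compartment_layout,
    default_compartment_tree,
    expand_neighbors,
    export_graph,
    load_interaction_table,
)
from phylofoot.graph import (
    CompartmentTree,
    InteractionFormatError,
    compute_zones,
    make_record,
    read_compartment_tree_tsv,
    write_interaction_table,
)
from phylofoot.simulate import generate_cc_map, generate_interaction_table

HEADER = "source\ttarget\tcategory\tsign\tprovenance\n"


def simple_graph(records, compartments=None, genes=None):
    tree = default_compartment_tree()
    genes = genes or sorted({r.source_id for r in records}
                            | {r.target_id for r in records})
    compartments = compartments or {g: {"nucleus"} for g in genes}
    return build_mixed_graph(genes, records, compartments, tree)


class TestInteractionRecords:
    def test_curated_activation_is_directed_positive(self):
        recs = load_interaction_table(
            HEADER + "Notch1\tHes1\ttf_target_curated\tactivation\tLymphTF-DB\n")
        assert recs[0].directed and recs[0].sign == "activation"

    def test_mirna_defaults_to_repression(self):
        recs = load_interaction_table(HEADER + "Mir17\tMycn\tmirna_target\n")
        assert recs[0].directed and recs[0].sign == "repression"

    def test_ppi_is_undirected_unsigned(self):
        recs = load_interaction_table(HEADER + "A\tB\tppi\n")
        assert not recs[0].directed and recs[0].sign == "none"

    @pytest.mark.parametrize("line,msg", [
        ("A\tB\tppi\tactivation\n", "line 2"),
        ("A\tB\tteleportation\n", "line 2"),
        ("A\tB\n", "line 2"),
    ])
    def test_malformed_lines_name_the_line(self, line, msg):
        with pytest.raises(InteractionFormatError, match=msg):
            load_interaction_table(HEADER + line)

    def test_table_round_trip(self):
        text, records = generate_interaction_table(15, seed=9)
        assert load_interaction_table(text) == records
        buf = io.StringIO()
        write_interaction_table(records, buf)
        assert load_interaction_table(buf.getvalue()) == records

    def test_densities_zero_gives_header_only(self):
        text, records = generate_interaction_table(
            10, densities={"ppi": 0.0}, seed=0)
        assert records == []
        assert text == HEADER


class TestCompartments:
    def test_multi_compartment_gene_gets_two_instances(self):
        tree = default_compartment_tree()
        comp = assign_compartments(
            ["A"], {"A": ["nucleus", "cytosol"]}, tree)
        assert comp["A"] == {"nucleus", "cytosol"}

    def test_unannotated_gene_falls_back_to_intracellular(self):
        tree = default_compartment_tree()
        comp = assign_compartments(["A"], {}, tree)
        assert comp["A"] == {"intracellular"}

    def test_walk_up_to_nearest_tree_term(self):
        tree = default_compartment_tree()
        ancestry = {"nucleolus": "nucleus"}
        comp = assign_compartments(["A"], {"A": ["nucleolus"]}, tree, ancestry)
        assert comp["A"] == {"nucleus"}
        # dead-end walk falls back
        comp = assign_compartments(["A"], {"A": ["mystery"]}, tree, ancestry)
        assert comp["A"] == {"intracellular"}

    def test_tree_validation(self):
        with pytest.raises(ValueError, match="root"):
            CompartmentTree(parent={"a": None, "b": None})
        with pytest.raises(ValueError, match="cycle"):
            CompartmentTree(parent={"r": None, "a": "b", "b": "a"})
        tree = read_compartment_tree_tsv("cell\t\nnucleus\tcell\n")
        assert tree.root == "cell" and "nucleus" in tree

    def test_zone_nesting_mirrors_tree(self):
        tree = default_compartment_tree()
        zones = compute_zones(tree)
        for term, parent in tree.parent.items():
            if parent is None:
                continue
            z, pz = zones[term], zones[parent]
            assert pz.x0 < z.x0 < z.x1 < pz.x1
            assert pz.y0 < z.y0 < z.y1 < pz.y1


class TestBuildGraph:
    def test_single_ppi_two_instances_one_edge(self):
        g = simple_graph([make_record("A", "B", "ppi")])
        assert len(g.instances) == 2
        assert len(g.edges) == 1

    def test_instance_fan_out_across_compartments(self):
        g = simple_graph([make_record("A", "B", "ppi")],
                         compartments={"A": {"nucleus", "cytosol"},
                                       "B": {"nucleus"}})
        assert len(g.instances) == 3
        assert len(g.edges) == 2

    def test_instance_uniqueness(self):
        g = simple_graph([make_record("A", "B", "ppi")],
                         compartments={"A": {"nucleus"}, "B": {"nucleus"}})
        keys = [(i.gene_id, i.compartment) for i in g.instances.values()]
        assert len(keys) == len(set(keys))

    def test_empty_records_all_orphans(self):
        g = simple_graph([], genes=["A", "B", "C"])
        assert len(g.instances) == 3 and g.edges == []

    def test_regulatory_info_flag(self):
        g = simple_graph([
            make_record("A", "B", "tf_target_curated", "activation"),
            make_record("B", "C", "ppi")])
        flags = {i.gene_id: i.has_regulatory_info
                 for i in g.instances.values()}
        assert flags == {"A": True, "B": False, "C": False}


class TestLayout:
    def test_single_node_settles_on_anchor(self):
        g = simple_graph([], genes=["A"])
        g = compartment_layout(g, seed=1, iterations=500)
        key = next(iter(g.positions))
        anchor = g.zones["nucleus"].anchor
        assert np.linalg.norm(g.positions[key] - anchor) < 1.0

    def test_seed_determinism(self):
        text, records = generate_interaction_table(25, seed=4)
        genes = sorted({r.source_id for r in records}
                       | {r.target_id for r in records})
        tree = default_compartment_tree()
        cc = generate_cc_map(genes, [t for t in tree.parent if t != "cell"],
                             seed=2)
        comp = assign_compartments(genes, cc, tree)
        runs = [compartment_layout(
            build_mixed_graph(genes, records, comp, tree), seed=11)
            for _ in range(2)]
        for k in runs[0].positions:
            assert np.array_equal(runs[0].positions[k], runs[1].positions[k])
        other = compartment_layout(
            build_mixed_graph(genes, records, comp, tree), seed=12)
        assert any(not np.array_equal(runs[0].positions[k], other.positions[k])
                   for k in runs[0].positions)

    def test_zone_containment_on_random_graphs(self):
        tree = default_compartment_tree()
        terms = [t for t in tree.parent if t != "cell"]
        for seed in range(10):
            text, records = generate_interaction_table(30, seed=seed)
            genes = sorted({r.source_id for r in records}
                           | {r.target_id for r in records})
            if not genes:
                continue
            cc = generate_cc_map(genes, terms, seed=seed)
            comp = assign_compartments(genes, cc, tree)
            g = compartment_layout(
                build_mixed_graph(genes, records, comp, tree), seed=seed)
            for key, pos in g.positions.items():
                zone = g.zones[g.instances[key].compartment]
                assert zone.contains(pos)

    def test_parameter_validation(self):
        g = simple_graph([], genes=["A"])
        with pytest.raises(ValueError):
            compartment_layout(g, repulsion=-1.0)


class TestFilters:
    def test_intercompartmental_removes_distant_ppi_keeps_directed(self):
        recs = [make_record("A", "B", "ppi"),
                make_record("A", "B", "tf_target_curated", "activation"),
                make_record("C", "D", "ppi")]
        comp = {"A": {"nucleus"}, "B": {"extracellular region"},
                "C": {"extracellular region"}, "D": {"plasma membrane"}}
        g = simple_graph(recs, compartments=comp, genes=list("ABCD"))
        f = apply_graph_filters(g, hide_intercompartmental=True)
        cats = sorted((e.record.category,
                       f.instances[e.from_instance].compartment,
                       f.instances[e.to_instance].compartment)
                      for e in f.edges)
        # nucleus<->extracellular ppi removed; directed tf edge kept;
        # extracellular<->plasma membrane ppi kept (configured adjacency)
        assert cats == [
            ("ppi", "extracellular region", "plasma membrane"),
            ("tf_target_curated", "nucleus", "extracellular region")]

    def test_parent_child_ppi_survives(self):
        recs = [make_record("A", "B", "ppi")]
        comp = {"A": {"intracellular"}, "B": {"nucleus"}}
        g = simple_graph(recs, compartments=comp)
        f = apply_graph_filters(g, hide_intercompartmental=True)
        assert len(f.edges) == 1

    def test_orphan_and_empty_compartment_filters(self):
        recs = [make_record("A", "B", "ppi")]
        comp = {"A": {"nucleus"}, "B": {"nucleus"}, "C": {"cytosol"}}
        g = simple_graph(recs, compartments=comp, genes=list("ABC"))
        f = apply_graph_filters(g, hide_orphans=True,
                                hide_empty_compartments=True)
        assert set(i.gene_id for i in f.instances.values()) == {"A", "B"}
        assert "cytosol" not in f.zones
        assert "nucleus" in f.zones and "cell" in f.zones

    def test_filters_idempotent(self):
        text, records = generate_interaction_table(20, seed=3)
        g = simple_graph(records)
        kwargs = dict(hide_orphans=True, hide_empty_compartments=True,
                      hide_intercompartmental=True)
        once = apply_graph_filters(g, **kwargs)
        twice = apply_graph_filters(once, **kwargs)
        assert set(once.instances) == set(twice.instances)
        assert [(e.from_instance, e.to_instance, e.record)
                for e in once.edges] == [
            (e.from_instance, e.to_instance, e.record) for e in twice.edges]


class TestExpansion:
    COMPENDIUM = [
        make_record("A", "B", "ppi"),
        make_record("A", "C", "ppi"),
        make_record("B", "C", "ppi"),
        make_record("A", "D", "tf_target_curated", "activation"),
    ]

    def test_all_interactors_adds_every_partner(self):
        g = simple_graph([], genes=["A", "B"])
        out = expand_neighbors(g, ["A"], self.COMPENDIUM,
                               mode="all_interactors")
        assert out.genes() == {"A", "B", "C", "D"}
        assert out.genes() >= g.genes()

    def test_common_interactors_is_intersection(self):
        g = simple_graph([], genes=["A", "B"])
        out = expand_neighbors(g, ["A", "B"], self.COMPENDIUM,
                               mode="common_interactors")
        # C interacts with both A and B; D only with A
        assert out.genes() == {"A", "B", "C"}
        allmode = expand_neighbors(g, ["A", "B"], self.COMPENDIUM,
                                   mode="all_interactors")
        assert out.genes() <= allmode.genes()

    def test_no_partners_and_empty_selection(self):
        g = simple_graph([], genes=["X"])
        assert expand_neighbors(g, ["X"], self.COMPENDIUM).genes() == {"X"}
        assert expand_neighbors(g, [], self.COMPENDIUM) is g


class TestExport:
    def test_sif_relation_tokens(self):
        recs = [make_record("Notch1", "Hes1", "tf_target_curated", "activation"),
                make_record("Mir17", "Mycn", "mirna_target"),
                make_record("K", "S", "kinase_substrate", "ambiguous"),
                make_record("P", "Q", "ppi")]
        g = simple_graph(recs)
        sif = export_graph(g, "sif")
        assert "Notch1\tactivates\tHes1" in sif
        assert "Mir17\ttargets\tMycn" in sif
        assert "K\tphosphorylates\tS" in sif
        assert "P\tbinds\tQ" in sif

    def test_empty_graph_documents(self):
        g = simple_graph([], genes=[])
        assert export_graph(g, "sif") == ""
        assert export_graph(g, "tsv").startswith("from\tto\t")
        nx.parse_graphml(export_graph(g, "graphml"))  # valid XML document

    def test_unknown_format_rejected(self):
        g = simple_graph([], genes=[])
        with pytest.raises(ValueError, match="format"):
            export_graph(g, "dot")

    def test_graphml_round_trip_preserves_attributes(self):
        text, records = generate_interaction_table(15, seed=6)
        g = compartment_layout(simple_graph(records), seed=1)
        back = nx.parse_graphml(export_graph(g, "graphml"))
        nodes = {n: d for n, d in back.nodes(data=True)}
        assert len(nodes) == len(g.instances)
        for key, inst in g.instances.items():
            assert nodes[key]["gene_id"] == inst.gene_id
            assert nodes[key]["compartment"] == inst.compartment
            assert nodes[key]["has_regulatory_info"] == inst.has_regulatory_info
            assert nodes[key]["x"] == pytest.approx(g.positions[key][0])
        got = sorted((u, v, d["category"], d["sign"], d["color"],
                      d["arrowhead"]) for u, v, d in back.edges(data=True))
        from phylofoot.graph import SIGN_RENDERING
        want = sorted((e.from_instance, e.to_instance, e.record.category,
                       e.record.sign, *SIGN_RENDERING[e.record.sign])
                      for e in g.edges)
        assert got == want
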
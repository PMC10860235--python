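"""Marker cascades: term frequencies, top-term windows, connectivity,
co-occurrence gates, and the staged NA / HA filtering pipelines."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pcoskg import cascade, simulate
from pcoskg.litmine import TermIncidence, build_cooccurrence


def make_terms(rows):
    """rows: (term_id, term_name, category, source, p, genes-iterable)."""
    return pd.DataFrame(
        [
            {
                "term_id": t, "term_name": n, "category": c,
                "source": s, "p_value": p, "genes": frozenset(g),
            }
            for t, n, c, s, p, g in rows
        ]
    )


class TestTermFrequency:
    def test_counts(self):
        terms = make_terms(
            [(f"T{i}", f"t{i}", "immunity", "BP", 0.01,
              ["g1"] + (["g2"] if i < 6 else [])) for i in range(10)]
        )
        freq = cascade.term_frequency({"g1", "g2", "g3"}, terms)
        assert freq == {"g1": 10, "g2": 6, "g3": 0}

    def test_matches_bruteforce_on_random_tables(self, rng):
        genes = [f"g{i}" for i in range(20)]
        terms = make_terms(
            [
                (f"T{i}", f"t{i}", "other", "BP", 0.01,
                 rng.choice(genes, size=rng.integers(0, 10), replace=False))
                for i in range(30)
            ]
        )
        freq = cascade.term_frequency(genes, terms)
        # brute-force double loop
        for g in genes:
            count = 0
            for members in terms["genes"]:
                if g in members:
                    count += 1
            assert freq[g] == count


class TestSelectTopTerms:
    def test_sort_contract(self, rng):
        terms = make_terms(
            [(f"T{i:02d}", f"t{i}", "other", "BP",
              float(p), ["g"]) for i, p in enumerate(rng.uniform(0, 0.2, 30))]
        )
        survivors = terms[terms["p_value"] < 0.05]
        top = cascade.select_top_terms(terms, k=20)
        assert len(top) == min(20, len(survivors))
        assert (top["p_value"] < 0.05).all()
        assert top["p_value"].is_monotonic_increasing
        excluded = set(survivors["term_id"]) - set(top["term_id"])
        if excluded:
            max_in = top["p_value"].max()
            min_out = survivors.set_index("term_id").loc[sorted(excluded), "p_value"].min()
            assert max_in <= min_out

    def test_all_nonsignificant_empty(self):
        terms = make_terms([("T1", "t", "other", "BP", 0.5, ["g"])])
        with pytest.warns(UserWarning):
            assert cascade.select_top_terms(terms, k=20).empty

    def test_ties_break_by_term_id(self):
        terms = make_terms(
            [("T2", "b", "other", "BP", 0.01, ["g"]),
             ("T1", "a", "other", "BP", 0.01, ["g"]),
             ("T3", "c", "other", "BP", 0.02, ["g"])]
        )
        top = cascade.select_top_terms(terms, k=2)
        assert list(top["term_id"]) == ["T1", "T2"]


class TestConnectivityFilter:
    def test_definition(self):
        edges = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"], "evidence": ["e"]})
        assert cascade.connectivity_filter({"a", "b", "c"}, edges) == {"a", "b"}

    def test_no_edges_empty(self):
        edges = pd.DataFrame({"gene_a": [], "gene_b": [], "evidence": []})
        assert cascade.connectivity_filter({"a", "b"}, edges) == set()

    def test_matches_induced_subgraph_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        pairs = [
            tuple(rng.choice(genes, size=2, replace=False)) for _ in range(60)
        ]
        edges = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
        subset = set(rng.choice(genes, size=15, replace=False))
        got = cascade.connectivity_filter(subset, edges)
        # oracle: explicit induced subgraph, keep nonzero-degree nodes
        g = nx.Graph()
        g.add_nodes_from(subset)
        g.add_edges_from(p for p in pairs if p[0] in subset and p[1] in subset)
        expected = {n for n in g.nodes if g.degree(n) > 0}
        assert got == expected


class TestCooccurrenceFilter:
    def test_positive_counts_reserved(self):
        assert cascade.cooccurrence_filter({"g1", "g2"}, {"g1": 3, "g2": 0}) == {"g1"}

    def test_min_count_zero_is_identity(self):
        genes = {"g1", "g2"}
        assert cascade.cooccurrence_filter(genes, {}, min_count=0) == genes

    def test_missing_key_excluded(self):
        assert cascade.cooccurrence_filter({"gX"}, {"g1": 5}) == set()


def hand_fixture():
    """A fixture whose stage-by-stage survivors are enumerable by hand.

    Genes m1, m2 pass every stage; f1 fails only the frequency gate (on 2
    immunity terms per window); c1 passes frequency but has no PPI edge; z1
    passes everything except the co-occurrence gate.
    """
    passers = ["m1", "m2", "z1"]
    rows = []
    for src in ("BP", "KEGG"):
        for i in range(7):
            rows.append(
                (f"{src}I{i}", f"{src} immune {i}", "immunity", src,
                 0.001 + i * 1e-4, passers + (["f1"] if i < 2 else []) + ["c1"])
            )
        rows.append((f"{src}O", f"{src} other", "other", src, 0.001, ["m1", "f1"]))
        rows.append((f"{src}NS", f"{src} weak", "immunity", src, 0.5, ["f1"]))
    terms = make_terms(rows)
    edges = pd.DataFrame(
        {"gene_a": ["m1", "z1"], "gene_b": ["m2", "m1"], "evidence": ["e", "e"]}
    )
    co = {"m1": 3, "m2": 1, "z1": 0, "c1": 9, "f1": 9,
          "BP immune 0": 7, "BP immune 1": 2}
    specific = {"m1", "m2", "f1", "c1", "z1", "absent"}
    return specific, terms, edges, co


class TestNaCascade:
    def test_hand_enumerated_stages(self):
        specific, terms, edges, co = hand_fixture()
        res = cascade.na_cascade(specific, terms, edges, co)
        # frequency: m1, m2, z1, c1 on 7 immunity terms per window (> 5 and
        # > 2); f1 on only 2 (fails both windows)
        for window in ("BP_all", "BP_top20", "KEGG_all", "KEGG_top20"):
            assert res.stages[f"frequency[{window}]"] == {"m1", "m2", "z1", "c1"}
            # connectivity: c1 has no edge
            assert res.stages[f"connectivity[{window}]"] == {"m1", "m2", "z1"}
        assert res.stages["intersection"] == {"m1", "m2", "z1"}
        # co-occurrence: z1 has count 0
        assert res.stages["cooccurrence"] == {"m1", "m2"}
        # term choice: among immunity terms with >= 2 survivors, "BP immune 0"
        # has the largest term-PCOS count (7)
        assert res.chosen_term == "BPI0"
        assert res.markers == {"m1", "m2"}

    def test_frequency_failure_absent_from_output(self):
        specific, terms, edges, co = hand_fixture()
        res = cascade.na_cascade(specific, terms, edges, co)
        assert "f1" not in res.markers

    def test_empty_stage_warns(self):
        specific, terms, edges, co = hand_fixture()
        co = {g: 0 for g in co}  # kill the co-occurrence stage
        with pytest.warns(UserWarning, match="cooccurrence"):
            res = cascade.na_cascade(specific, terms, edges, co)
        assert res.markers == set()

    def test_monotone_in_input_set(self):
        specific, terms, edges, co = hand_fixture()
        full = cascade.na_cascade(specific, terms, edges, co).markers
        smaller = cascade.na_cascade(specific - {"m2"}, terms, edges, co)
        assert smaller.markers <= full

    def test_output_subset_of_input(self, small_config):
        terms = simulate.generate_annotations(small_config)
        edges = simulate.generate_ppi(small_config)
        inc, truth = simulate.generate_corpus(small_config)
        specific = set(truth.specific_na)
        co = build_cooccurrence(
            inc, sorted(specific) + list(terms["term_name"]), "PCOS"
        )
        res = cascade.na_cascade(specific, terms, edges, co)
        assert res.markers <= specific

    def test_planted_markers_recovered_end_to_end(self, small_config):
        terms = simulate.generate_annotations(small_config)
        edges = simulate.generate_ppi(small_config)
        inc, truth = simulate.generate_corpus(small_config)
        na_markers, _ = simulate.marker_gene_ids(small_config)
        co = build_cooccurrence(
            inc, sorted(truth.specific_na) + list(terms["term_name"]), "PCOS"
        )
        res = cascade.na_cascade(set(truth.specific_na), terms, edges, co)
        assert res.markers == set(na_markers)


class TestHaCascade:
    def _fixture(self):
        terms = make_terms(
            [
                ("G1", "glucose a", "glucose", "BP", 0.001, ["h1", "h2", "one"]),
                ("G2", "glucose b", "glucose", "BP", 0.002, ["h1", "h2"]),
                ("G3", "glucose kegg", "glucose", "KEGG", 0.001, ["one"]),
                ("O1", "other", "other", "BP", 0.001, ["h1", "one"]),
            ]
        )
        co = {"h1": 5, "h2": 0, "one": 4}
        return terms, co

    def test_both_thresholds_met(self):
        terms, co = self._fixture()
        res = cascade.ha_cascade({"h1", "h2", "one"}, terms, co)
        assert res.markers == {"h1"}

    def test_single_term_dropped(self):
        # "one" sits on one glucose BP term only (KEGG does not count)
        terms, co = self._fixture()
        res = cascade.ha_cascade({"one"}, terms, co)
        assert res.stages["frequency"] == set()

    def test_zero_cooccurrence_dropped(self):
        terms, co = self._fixture()
        res = cascade.ha_cascade({"h2"}, terms, co)
        assert res.stages["frequency"] == {"h2"}
        assert res.markers == set()


class TestAnnotationRoundTrip:
    def test_tsv_round_trip(self, small_config, tmp_path):
        terms = simulate.generate_annotations(small_config)
        path = tmp_path / "ann.tsv"
        cascade.write_annotations(terms, path)
        back = cascade.read_annotations(path)
        pd.testing.assert_frame_equal(
            terms.sort_values("term_id").reset_index(drop=True),
            back.sort_values("term_id").reset_index(drop=True),
        )
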
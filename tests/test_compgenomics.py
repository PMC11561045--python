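"""Alignment engine, AAI/POCP/ANI metrics, clustering and pangenome curves."""

import numpy as np
import pandas as pd
import pytest

from streamscan import compgenomics as cg
from streamscan import synthetic
from streamscan.align import global_align_nuc, local_align

from conftest import sw_oracle_score, transitive_closure_clusters

AA = "ACDEFGHIKLMNPQRSTVWY"


def hit_row(q, qg, s, sg, identity, qcov, scov=100.0, score=100.0):
    return (q, qg, s, sg, identity, qcov, scov, score)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=cg.HIT_COLUMNS)


class TestLocalAlign:
    def test_self_alignment(self):
        res = local_align("M" + AA * 5, "M" + AA * 5)
        assert res.identity == 100.0
        assert res.query_coverage == 100.0

    def test_matches_dp_oracle_on_classic_pair(self):
        assert local_align("HEAGAWGHEE", "PAWHEAE").score == \
            sw_oracle_score("HEAGAWGHEE", "PAWHEAE")

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=rng.integers(3, 13)))
            b = "".join(rng.choice(list(AA), size=rng.integers(3, 13)))
            assert local_align(a, b).score == sw_oracle_score(a, b)

    def test_no_positive_alignment(self):
        res = local_align("AAAA", "CCCC")
        assert res.score == 0.0 and res.query_coverage == 0.0

    def test_x_scores_zero(self):
        assert local_align("XXXX", "XXXX").score == 0.0

    def test_illegal_characters(self):
        with pytest.raises(ValueError):
            local_align("ACDU", "ACD")
        with pytest.raises(ValueError):
            local_align("", "ACD")


class TestGlobalAlignNuc:
    def test_identical(self):
        res = global_align_nuc("ACGTACGT", "ACGTACGT")
        assert res.identity == 100.0

    def test_mismatch_identity(self):
        res = global_align_nuc("ACGTACGTAC", "ACGTACGTAG")
        assert res.identity == pytest.approx(90.0)


class TestAllVsAll:
    def test_identical_proteins_full_cross_product(self):
        prot = [(f"p{i}", "M" + AA * 6) for i in range(3)]
        proteomes = {"GA": [(f"GA|{p}", s) for p, s in prot],
                     "GB": [(f"GB|{p}", s) for p, s in prot]}
        hits = cg.all_vs_all(proteomes)
        forward = hits[hits.query_genome == "GA"]
        assert len(forward) == 9 and (forward.identity == 100.0).all()
        # direction-complete
        pairs = {(r.query_id, r.subject_id) for r in hits.itertuples()}
        assert all((b, a) in pairs for a, b in pairs)

    def test_unrelated_proteomes_empty(self):
        rng = np.random.default_rng(2)
        proteomes = {g: [(f"{g}|p", "".join(rng.choice(list(AA), size=100)))]
                     for g in ("GA", "GB")}
        hits = cg.all_vs_all(proteomes)
        assert hits.empty

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            cg.all_vs_all({"GA": [("GA|p", "MKL")]})


class TestPOCP:
    def test_identical_proteomes_100(self):
        prot = [(f"p{i}", "M" + AA * 6) for i in range(4)]
        a = [(f"GA|{p}", s) for p, s in prot]
        b = [(f"GB|{p}", s) for p, s in prot]
        assert cg.compute_pocp(a, b, cg.all_vs_all({"GA": a, "GB": b})) == 100.0

    def test_formula_arithmetic(self):
        a = [(f"a{i}", "M" * 10) for i in range(10)]
        b = [(f"b{i}", "M" * 10) for i in range(10)]
        rows = [hit_row(f"a{i}", "GA", "b0", "GB", 80, 90) for i in range(4)]
        rows += [hit_row(f"b{i}", "GB", "a0", "GA", 80, 90) for i in range(5)]
        assert cg.compute_pocp(a, b, hits_frame(rows)) == pytest.approx(45.0)

    def test_thresholds_strict(self):
        a = [("a0", "M" * 10)]
        b = [("b0", "M" * 10)]
        boundary = hits_frame([hit_row("a0", "GA", "b0", "GB", 50.0, 50.0)])
        assert cg.compute_pocp(a, b, boundary) == 0.0
        above = hits_frame([hit_row("a0", "GA", "b0", "GB", 50.1, 50.1)])
        assert cg.compute_pocp(a, b, above) == pytest.approx(50.0)

    def test_no_hits_zero(self):
        assert cg.compute_pocp([("a0", "M" * 10)], [("b0", "M" * 10)],
                               hits_frame([])) == 0.0

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            cg.compute_pocp([], [("b0", "M")], hits_frame([]))


class TestAAI:
    def test_identical_proteomes_100(self):
        prot = [(f"p{i}", AA * 6) for i in range(3)]
        a = [(f"GA|{p}", s) for p, s in prot]
        b = [(f"GB|{p}", s) for p, s in prot]
        assert cg.compute_aai(a, b, cg.all_vs_all({"GA": a, "GB": b})) == 100.0

    def test_symmetry_on_synthetic_pair(self):
        proteomes, _ = synthetic.generate_proteome_family(2, 15, 0, 0.8, seed=4)
        hits = cg.all_vs_all(proteomes)
        ab = cg.compute_aai(proteomes["G00"], proteomes["G01"], hits)
        ba = cg.compute_aai(proteomes["G01"], proteomes["G00"], hits)
        assert ab == pytest.approx(ba)

    def test_recovers_generator_identity(self):
        proteomes, _ = synthetic.generate_proteome_family(2, 25, 0, 0.8, seed=5)
        hits = cg.all_vs_all(proteomes)
        aai = cg.compute_aai(proteomes["G00"], proteomes["G01"], hits)
        assert 75.0 <= aai <= 85.0

    def test_no_rbh_is_missing(self):
        assert cg.compute_aai([("a", "M" * 10)], [("b", "M" * 10)],
                              hits_frame([])) is None


class TestGeneANI:
    @pytest.fixture(scope="class")
    @staticmethod
    def gene_sets():
        rng = np.random.default_rng(6)
        genes = [(f"g{i}", "".join(rng.choice(list("ACGT"), size=500)))
                 for i in range(8)]

        def mutate(seq, rate):
            out = list(seq)
            for i in np.flatnonzero(rng.random(len(seq)) < rate):
                out[i] = "ACGT".replace(out[i], "")[rng.integers(0, 3)]
            return "".join(out)

        mutated = [(gid, mutate(seq, 0.02)) for gid, seq in genes]
        return genes, mutated

    def test_identical_sets_100(self, gene_sets):
        genes, _ = gene_sets
        assert cg.compute_gene_ani(genes, genes) == 100.0

    def test_two_percent_divergence(self, gene_sets):
        genes, mutated = gene_sets
        ani = cg.compute_gene_ani(genes, mutated)
        assert 97.0 <= ani <= 99.0

    def test_symmetry(self, gene_sets):
        genes, mutated = gene_sets
        assert cg.compute_gene_ani(genes, mutated) == pytest.approx(
            cg.compute_gene_ani(mutated, genes))


class TestClusterOrthologues:
    def test_thresholds_inclusive(self):
        hits = hits_frame([hit_row("a", "GA", "b", "GB", 50.0, 50.0)])
        clusters = cg.cluster_orthologues(hits, ["a", "b"])
        assert clusters == [["a", "b"]]
        below = hits_frame([hit_row("a", "GA", "b", "GB", 49.9, 50.0)])
        assert cg.cluster_orthologues(below, ["a", "b"]) == [["a"], ["b"]]

    def test_singletons_for_unhit_proteins(self):
        clusters = cg.cluster_orthologues(hits_frame([]), ["a", "b", "c"])
        assert clusters == [["a"], ["b"], ["c"]]

    def test_matches_brute_force_transitive_closure(self):
        rng = np.random.default_rng(7)
        nodes = [f"p{i}" for i in range(40)]
        rows = []
        edges = []
        for _ in range(60):
            i, j = rng.choice(40, size=2, replace=False)
            ident = float(rng.uniform(30, 90))
            cov = float(rng.uniform(30, 90))
            rows.append(hit_row(nodes[i], "GA", nodes[j], "GB", ident, cov))
            if ident >= 50 and cov >= 50:
                edges.append((nodes[i], nodes[j]))
        assert cg.cluster_orthologues(hits_frame(rows), nodes) == \
            transitive_closure_clusters(edges, nodes)

    def test_recovers_planted_families(self):
        proteomes, truth = synthetic.generate_proteome_family(4, 20, 10, 0.9,
                                                              seed=8)
        hits = cg.all_vs_all(proteomes)
        clusters = cg.cluster_orthologues(hits, list(truth.protein_id))
        expected = sorted(sorted(g) for g in
                          truth.groupby("family_id").protein_id.apply(list))
        assert clusters == expected


class TestCorePanCurves:
    @pytest.fixture(scope="class")
    @staticmethod
    def matrix():
        proteomes, truth = synthetic.generate_proteome_family(5, 12, 8, 0.9,
                                                              seed=9)
        hits = cg.all_vs_all(proteomes)
        clusters = cg.cluster_orthologues(hits, list(truth.protein_id))
        return cg.pangenome_matrix(
            clusters, dict(zip(truth.protein_id, truth.genome_id)))

    def test_endpoint_identities(self, matrix):
        curves = cg.core_pan_curves(matrix, 20, seed=1)
        last = curves.iloc[-1]
        assert last.pan_mean == len(matrix)
        assert last.core_mean == ((matrix > 0).all(axis=1)).sum()
        assert last.pan_sd == 0.0 and last.core_sd == 0.0

    def test_monotone_curves(self, matrix):
        curves = cg.core_pan_curves(matrix, 20, seed=2)
        assert (np.diff(curves.pan_mean) >= 0).all()
        assert (np.diff(curves.core_mean) <= 0).all()

    def test_core_converges_to_planted_core(self, matrix):
        curves = cg.core_pan_curves(matrix, 20, seed=3)
        assert curves.iloc[-1].core_mean == 12


class TestDereplicate:
    def stats(self, rows):
        return pd.DataFrame(rows, columns=["genome_id", "completeness",
                                           "contamination", "length"])

    def ani(self, ids, pairs):
        m = pd.DataFrame(0.0, index=ids, columns=ids)
        np.fill_diagonal(m.values, 100.0)
        for a, b, v in pairs:
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def test_representative_by_completeness(self):
        stats = self.stats([("A", 95, 0, 1000), ("B", 80, 0, 1000)])
        ani = self.ani(["A", "B"], [("A", "B", 99.9)])
        assert cg.dereplicate(stats, ani) == ["A"]

    def test_threshold_strict(self):
        stats = self.stats([("A", 95, 0, 1000), ("B", 80, 0, 1000)])
        ani = self.ani(["A", "B"], [("A", "B", 99.0)])  # exactly 99: separate
        assert cg.dereplicate(stats, ani) == ["A", "B"]

    def test_single_linkage_chain(self):
        stats = self.stats([("A", 90, 0, 1000), ("B", 85, 0, 1000),
                            ("C", 80, 0, 1000)])
        ani = self.ani(["A", "B", "C"],
                       [("A", "B", 99.5), ("B", "C", 99.5), ("A", "C", 98.0)])
        assert cg.dereplicate(stats, ani) == ["A"]

    def test_contamination_penalty(self):
        stats = self.stats([("A", 95, 4, 1000), ("B", 90, 0, 1000)])
        ani = self.ani(["A", "B"], [("A", "B", 99.9)])
        # 95 - 20 = 75 < 90 - 0
        assert cg.dereplicate(stats, ani) == ["B"]


class TestSelectSCGs:
    def test_selection_rules(self):
        counts = pd.DataFrame(
            {"g1": [1, 1, 1], "g2": [1, 2, 0], "g3": [1, 1, 1]},
            index=["famA", "famB", "famC"])
        # famB is multi-copy in g2, famC is missing from g2
        assert cg.select_scgs(counts) == ["famA"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cg.select_scgs(pd.DataFrame())
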
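"""Generator contracts: conservation, determinism, planted-truth counts."""

import io as stdio

import numpy as np
import pytest

from streamscan import rhodopsin, synthetic
from streamscan.io import write_fasta

from conftest import make_bin


class TestGenerateGenome:
    def test_total_length_conserved(self):
        spec = synthetic.SyntheticGenomeSpec(total_length=100_000, n_contigs=5, seed=1)
        g = synthetic.generate_genome(spec)
        assert sum(len(s) for _, s in g.contigs) == 100_000

    def test_gc_within_binomial_bound(self):
        spec = synthetic.SyntheticGenomeSpec(total_length=200_000, gc=0.46, seed=2)
        g = synthetic.generate_genome(spec)
        seq = g.sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.46) < 0.01

    def test_same_seed_byte_identical_fasta(self):
        spec = synthetic.SyntheticGenomeSpec(total_length=50_000, n_contigs=3, seed=7)
        outputs = []
        for _ in range(2):
            g = synthetic.generate_genome(spec)
            buf = stdio.StringIO()
            write_fasta(g.contigs, buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_genes_non_overlapping_with_strands(self):
        g = synthetic.generate_genome(
            synthetic.SyntheticGenomeSpec(total_length=60_000, n_contigs=2, seed=3))
        assert set(g.genes["strand"]) <= {"+", "-"}
        for _, group in g.genes.groupby("contig_id"):
            group = group.sort_values("start")
            assert (group["end"].values[:-1] < group["start"].values[1:]).all()

    @pytest.mark.parametrize("kwargs", [
        {"total_length": 3000, "n_contigs": 5},   # under 1 kb per contig
        {"total_length": 10_000, "gc": 0.0},
        {"total_length": 10_000, "gene_density": 1.5},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.SyntheticGenomeSpec(**kwargs)


class TestPlantForeignContent:
    def test_full_fraction_leaves_no_dominant_genes(self):
        bin_ = make_bin({f"c{i}": [("taxA", False)] * 10 for i in range(4)})
        dirty, truth = synthetic.plant_foreign_content(bin_, 2, 1.0, seed=5)
        planted = set(truth[truth.is_contaminant].contig_id)
        assert len(planted) == 2
        for cid in planted:
            on_contig = dirty.genes[dirty.genes.contig_id == cid]
            assert (on_contig["taxon"] == synthetic.FOREIGN_TAXON).all()

    def test_partial_fraction_exact_count(self):
        bin_ = make_bin({"c0": [("taxA", False)] * 10, "c1": [("taxA", False)] * 10})
        dirty, truth = synthetic.plant_foreign_content(bin_, 1, 0.8, seed=1)
        cid = truth[truth.is_contaminant].contig_id.iloc[0]
        on_contig = dirty.genes[dirty.genes.contig_id == cid]
        assert (on_contig["taxon"] == synthetic.FOREIGN_TAXON).sum() == 8
        assert (on_contig["taxon"] == "taxA").sum() == 2

    def test_zero_contigs_is_identity(self):
        bin_ = make_bin({"c0": [("taxA", False)] * 5, "c1": [("taxA", False)] * 5})
        dirty, truth = synthetic.plant_foreign_content(bin_, 0, 0.5, seed=1)
        assert dirty.genes.equals(bin_.genes)
        assert not truth.is_contaminant.any()

    def test_fraction_out_of_range(self):
        bin_ = make_bin({"c0": [("taxA", False)] * 5, "c1": [("taxA", False)] * 5})
        with pytest.raises(ValueError):
            synthetic.plant_foreign_content(bin_, 1, 1.2, seed=1)


class TestSimulateReads:
    def test_read_count_poisson_bound(self):
        genome = synthetic.generate_genome(
            synthetic.SyntheticGenomeSpec(total_length=100_000, seed=1)).sequence
        reads, truth = synthetic.simulate_reads(genome, 10, 100, seed=4)
        assert abs(len(reads) - 10_000) <= 300  # 3 sigma of Poisson(10000)
        assert len(truth) == len(reads)

    def test_error_free_reads_are_exact_substrings(self):
        genome = synthetic.generate_genome(
            synthetic.SyntheticGenomeSpec(total_length=20_000, n_contigs=1, seed=2)).sequence
        reads, truth = synthetic.simulate_reads(genome, 1, 80, subst_rate=0.0, seed=3)
        for (rid, seq), row in zip(reads[:200], truth.itertuples()):
            assert genome[row.start - 1:row.end] == seq

    def test_substitutions_change_reads(self):
        genome = synthetic.generate_genome(
            synthetic.SyntheticGenomeSpec(total_length=20_000, n_contigs=1, seed=2)).sequence
        reads, truth = synthetic.simulate_reads(genome, 1, 80, subst_rate=0.05, seed=3)
        mismatches = sum(
            a != b for (_, seq), row in zip(reads, truth.itertuples())
            for a, b in zip(genome[row.start - 1:row.end], seq))
        total = sum(len(s) for _, s in reads)
        assert 0.03 < mismatches / total < 0.07

    def test_flat_coverage_low_cv_at_depth_50(self):
        from streamscan.recruitment import coverage_profile
        starts = synthetic.simulate_read_positions(100_000, 50, 100,
                                                   ori_ter_ratio=1.0, seed=6)
        prof = coverage_profile(starts, 100, 100_000)
        assert prof.std() / prof.mean() < 0.15

    def test_ori_ter_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_read_positions(10_000, 5, 100, ori_ter_ratio=0.5)


class TestProteomeFamily:
    def test_identity_one_gives_identical_members(self):
        proteomes, truth = synthetic.generate_proteome_family(3, 5, 0, 1.0, seed=1)
        for fam, group in truth.groupby("family_id"):
            seqs = {dict(proteomes[g])[p] for g, p in
                    zip(group.genome_id, group.protein_id)}
            assert len(seqs) == 1

    def test_family_counts_by_construction(self):
        proteomes, truth = synthetic.generate_proteome_family(4, 50, 30, 0.9, seed=2)
        assert truth.family_id.nunique() == 80
        core = truth[truth.is_core]
        assert core.family_id.nunique() == 50
        for _, group in core.groupby("family_id"):
            assert set(group.genome_id) == set(proteomes)
        for _, group in truth[~truth.is_core].groupby("family_id"):
            assert 1 <= group.genome_id.nunique() < len(proteomes)

    def test_realised_identity_near_target(self):
        # no indels by construction, so per-site agreement IS the exact
        # global-alignment identity — an independent oracle of the generator
        proteomes, truth = synthetic.generate_proteome_family(4, 30, 0, 0.8, seed=3)
        seq_of = {p: s for g in proteomes for p, s in proteomes[g]}
        idents = []
        for _, group in truth.groupby("family_id"):
            pids = list(group.protein_id)
            for i in range(len(pids)):
                for j in range(i + 1, len(pids)):
                    a, b = seq_of[pids[i]], seq_of[pids[j]]
                    idents.append(sum(x == y for x, y in zip(a, b)) / len(a))
        assert 0.75 <= np.mean(idents) <= 0.85

    def test_empty_family_set_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_proteome_family(3, 0, 0, 0.9)


class TestGenerateRhodopsin:
    def test_type1_helix7_motif_planted(self):
        seq, truth = synthetic.generate_rhodopsin("type1_DTE", 220, seed=1)
        s, e = truth.helices[-1]
        window = seq[s - 1:e]
        assert any(window[i] == "D" and window[i + 4] == "K"
                   for i in range(len(window) - 4))

    def test_heliorhodopsin_motif_is_sxxxk_not_dxxxk(self):
        seq, truth = synthetic.generate_rhodopsin("heliorhodopsin", 220, seed=2)
        s, e = truth.helices[-1]
        window = seq[s - 1:e]
        assert any(window[i] == "S" and window[i + 4] == "K"
                   for i in range(len(window) - 4))
        assert not any(window[i] == "D" and window[i + 4] == "K"
                       for i in range(len(window) - 4))

    @pytest.mark.parametrize("cls", synthetic.RHODOPSIN_CLASSES)
    def test_hydropathy_scan_finds_exactly_seven_peaks(self, cls):
        seq, _ = synthetic.generate_rhodopsin(cls, 200, seed=9)
        assert rhodopsin.predict_tm(seq).n_helices == 7

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_rhodopsin("type1_DTE", 120)

    def test_determinism(self):
        a, _ = synthetic.generate_rhodopsin("type1_DTE", 220, seed=5)
        b, _ = synthetic.generate_rhodopsin("type1_DTE", 220, seed=5)
        assert a == b


class TestAnnotationTable:
    @pytest.fixture(scope="class")
    @staticmethod
    def defs():
        from streamscan.pathways import load_pathway_definitions
        return load_pathway_definitions()

    def test_full_plan_hits_every_step(self, defs):
        table = synthetic.generate_annotation_table(
            ["G0"], defs, {"G0": {"ppp_nonoxidative": 1.0}}, seed=1)
        assert len(table) == defs["ppp_nonoxidative"].n_steps

    def test_rounding_rule(self, defs):
        table = synthetic.generate_annotation_table(
            ["G0"], defs, {"G0": {"ppp_nonoxidative": 0.75}}, seed=1)
        assert len(table) == 3  # 4-step pathway at 0.75 -> 3 steps hit

    def test_zero_plan_empty(self, defs):
        table = synthetic.generate_annotation_table(
            ["G0"], defs, {"G0": {"ppp_nonoxidative": 0.0}}, seed=1)
        assert table.empty

    def test_unknown_pathway_rejected(self, defs):
        with pytest.raises(KeyError):
            synthetic.generate_annotation_table(
                ["G0"], defs, {"G0": {"not_a_pathway": 1.0}}, seed=1)
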
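"""Junction windows, position matrices, background comparison, composition."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescreen.annotation import IntronRecord
from splicescreen.seqfeatures import (
    compare_to_background,
    composition_stats,
    extract_junction_windows,
    splice_site_matrix,
)


def _flip(genome, introns):
    """Reverse-complement every chromosome and flip all coordinates/strands."""
    flipped_genome = {c: str(Seq(s).reverse_complement()) for c, s in genome.items()}
    flipped = []
    for i in introns:
        L = len(genome[i.chrom])
        flipped.append(
            IntronRecord(
                i.gene_id,
                i.intron_index,
                i.chrom,
                L - i.end + 1,
                L - i.start + 1,
                "-" if i.strand == "+" else "+",
            )
        )
    return flipped_genome, flipped


class TestWindows:
    def test_donor_window_ends_with_consensus(self, three_intron_gene):
        genome, gene = three_intron_gene
        windows = extract_junction_windows(gene.introns, genome, (3, 6), "5p")
        assert len(windows) == 3
        for w in windows:
            assert len(w) == 9 and w[-6:] == "GTAAGT"

    def test_acceptor_window_starts_with_consensus_tail(self, three_intron_gene):
        genome, gene = three_intron_gene
        windows = extract_junction_windows(gene.introns, genome, (3, 4), "3p")
        for w in windows:
            assert len(w) == 7 and w[:3] == "TAG"

    def test_strand_symmetry(self, small_genome):
        genome, genes = small_genome
        introns = [i for g in genes for i in g.introns]
        flipped_genome, flipped_introns = _flip(genome, introns)
        for side, window in (("5p", (3, 8)), ("3p", (8, 3))):
            w1 = extract_junction_windows(introns, genome, window, side)
            w2 = extract_junction_windows(flipped_introns, flipped_genome, window, side)
            assert w1 == w2

    def test_truncated_window_skipped_with_warning(self, caplog):
        genome = {"chr1": "ACGTACGTACGTACGTACGT"}
        intron = IntronRecord("g", 1, "chr1", 3, 12, "+")  # only 2 nt upstream
        with caplog.at_level("WARNING"):
            windows = extract_junction_windows([intron], genome, (3, 6), "5p")
        assert windows == [] and "truncated" in caplog.text

    def test_unknown_chromosome_is_input_error(self):
        with pytest.raises(KeyError):
            extract_junction_windows(
                [IntronRecord("g", 1, "chrX", 10, 20, "+")], {"chr1": "A" * 50}, (1, 1)
            )


class TestSpliceSiteMatrix:
    def test_single_window_is_degenerate(self):
        m = splice_site_matrix(["GTAAGT"])
        assert set(np.unique(m.ppm.to_numpy())) <= {0.0, 1.0}
        assert np.allclose(m.info, 2.0)

    def test_two_window_hand_computation(self):
        m = splice_site_matrix(["GT", "GA"])
        assert m.ppm.loc["G", 0] == 1.0
        assert m.ppm.loc["T", 1] == 0.5 and m.ppm.loc["A", 1] == 0.5
        assert m.info == pytest.approx([2.0, 1.0])

    def test_uniform_column_has_zero_information(self):
        m = splice_site_matrix(["A", "C", "G", "T"])
        assert m.info == pytest.approx([0.0])

    def test_n_bases_excluded_from_counts(self):
        m = splice_site_matrix(["GA", "NA"])
        assert m.counts[0].sum() == 1 and m.ppm.loc["G", 0] == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            splice_site_matrix([])
        with pytest.raises(ValueError):
            splice_site_matrix(["AC", "ACG"])

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=5, max_size=5), min_size=1, max_size=30
        )
    )
    def test_ppm_columns_stochastic_and_info_bounded(self, windows):
        m = splice_site_matrix(windows)
        assert np.allclose(m.ppm.sum(axis=0), 1.0, atol=1e-9)
        assert (m.info >= -1e-12).all() and (m.info <= 2.0 + 1e-12).all()


class TestCompareToBackground:
    def test_identical_matrices_have_zero_kl(self):
        m = splice_site_matrix(["GTAAGT", "GTATGT", "GTGAGT"] * 10)
        out = compare_to_background(m, m)
        assert np.allclose(out["kl_bits"], 0.0)
        assert (out["p_adj"] >= 0.05).all()

    def test_forced_position_flagged_against_uniform_background(self):
        rng = np.random.default_rng(0)
        bg_windows = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(4000)]
        set_windows = [w[:2] + "A" + w[3:] for w in bg_windows[:300]]  # force pos 3 to A
        out = compare_to_background(
            splice_site_matrix(set_windows), splice_site_matrix(bg_windows)
        )
        assert bool(out.loc[out["position"] == 3, "significant"].iloc[0])
        assert not out.loc[out["position"] != 3, "significant"].any()

    def test_null_draws_rarely_flagged(self):
        rng = np.random.default_rng(7)
        probs = np.array([0.4, 0.1, 0.2, 0.3])
        bg_windows = [
            "".join(rng.choice(list("ACGT"), 6, p=probs)) for _ in range(3000)
        ]
        bg = splice_site_matrix(bg_windows)
        n_clean = 0
        for _ in range(100):
            idx = rng.choice(len(bg_windows), 60, replace=False)
            sub = splice_site_matrix([bg_windows[i] for i in idx])
            out = compare_to_background(sub, bg)
            n_clean += int(not out["significant"].any())
        assert n_clean >= 90

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_to_background(
                splice_site_matrix(["ACG"]), splice_site_matrix(["ACGT"])
            )


class TestCompositionStats:
    def test_boundary_at_fractions(self):
        genome = {"chr1": "AAAAGCGCGATTACA"}
        sets = {
            "at": [IntronRecord("g1", 1, "chr1", 1, 4, "+")],  # AAAA
            "gc": [IntronRecord("g2", 1, "chr1", 5, 8, "+")],  # GCGC
            "mix": [IntronRecord("g3", 1, "chr1", 9, 15, "+")],  # GATTACA
        }
        per_intron, _ = composition_stats(sets, genome)
        by = per_intron.set_index("set")["at_fraction"]
        assert by["at"] == 1.0 and by["gc"] == 0.0
        assert by["mix"] == pytest.approx(5 / 7)

    def test_inclusive_length_arithmetic(self):
        genome = {"chr1": "A" * 300}
        per_intron, _ = composition_stats(
            {"one": [IntronRecord("g", 1, "chr1", 101, 183, "+")]}, genome
        )
        assert per_intron["length"].iloc[0] == 83

    def test_strand_invariance_of_composition(self, small_genome):
        genome, genes = small_genome
        introns = [i for g in genes for i in g.introns]
        flipped_genome, flipped_introns = _flip(genome, introns)
        a, _ = composition_stats({"all": introns}, genome)
        b, _ = composition_stats({"all": flipped_introns}, flipped_genome)
        assert a["length"].tolist() == b["length"].tolist()
        assert a["at_fraction"].tolist() == pytest.approx(b["at_fraction"].tolist())

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            composition_stats({"none": []}, {"chr1": "ACGT"})
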
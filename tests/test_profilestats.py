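import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hairmeth.io_formats import GeneModel, GenomicInterval
from hairmeth.methcore import ANAGEN, TELOGEN, revcomp
from hairmeth.profilestats import (
    ChromSummary,
    chrom_feature_correlations,
    cpg_oe,
    metaprofile,
    sample_correlation,
    summarize_chromosomes,
    window_density,
)
from conftest import matrix_from_counts


class TestWindowDensity:
    def test_constant_level_everywhere(self):
        pos = np.arange(0, 1000, 10)
        n = len(pos)
        m = matrix_from_counts(pos, np.full((n, 6), 5), np.full((n, 6), 10))
        wd = window_density(m, window=100)
        assert (wd["level"] == 0.5).all()

    def test_empty_matrix_gives_no_windows(self):
        m = matrix_from_counts([], np.empty((0, 6), int),
                               np.empty((0, 6), int))
        assert len(window_density(m, window=100)) == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_pooling(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(2000, size=80, replace=False))
        total = rng.integers(0, 20, size=(80, 6))
        meth = rng.integers(0, total + 1)
        m = matrix_from_counts(pos, meth, total)
        wd = window_density(m, window=500)
        for row in wd.itertuples():
            g_idx = m.group_samples(row.group)
            in_w = (pos >= row.start) & (pos < row.end)
            ms = meth[np.ix_(in_w, g_idx)].sum()
            ts = total[np.ix_(in_w, g_idx)].sum()
            assert row.level == pytest.approx(ms / ts)

    def test_window_totals_conserve_genome_counts(self, small_dataset):
        body = small_dataset.matrix.drop_chrom("lambda").for_context("CG")
        wd = window_density(body, window=300_000)
        for group in (ANAGEN, TELOGEN):
            mg, tg = body.group_pooled(group)
            sel = (wd["group"] == group) & (wd["context"] == "CG")
            assert wd.loc[sel, "meth_sum"].sum() == mg.sum()
            assert wd.loc[sel, "total_sum"].sum() == tg.sum()


class TestMetaprofile:
    def _flat_matrix(self, pos, level=0.7, chrom="chr1"):
        n = len(pos)
        total = np.full((n, 6), 10)
        meth = np.full((n, 6), int(level * 10))
        return matrix_from_counts(pos, meth, total, chrom=chrom)

    def test_flat_methylome_gives_flat_bins(self):
        pos = np.arange(0, 20_000, 7)
        m = self._flat_matrix(pos, 0.7)
        genes = [GeneModel("g1", "chr1", "+", 5000, 9000,
                           [(5000, 6000), (8000, 9000)])]
        cgis = [GenomicInterval("chr1", 12_000, 12_800, ".", "CGI")]
        profs = metaprofile(m, genes, cgis)
        for prof in profs.values():
            vals = prof.values.to_numpy()
            assert np.allclose(vals[~np.isnan(vals)], 0.7)

    def test_gene_list_permutation_invariance(self, small_dataset):
        body = small_dataset.matrix.for_chrom("chr1").for_context("CG")
        genes = [g for g in small_dataset.genes if g.chrom == "chr1"][:10]
        cgis = [c for c in small_dataset.cgis if c.chrom == "chr1"]
        a = metaprofile(body, genes, cgis)
        b = metaprofile(body, genes[::-1], cgis)
        for cls in a:
            pd.testing.assert_frame_equal(a[cls].values, b[cls].values)

    def test_strand_mirror_symmetry(self):
        """A minus-strand gene over the mirrored methylome profiles
        identically to its plus-strand counterpart."""
        L = 30_000
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(L, size=600, replace=False))
        total = np.full((600, 6), 12)
        meth = rng.integers(0, 13, size=(600, 6))
        m_fwd = matrix_from_counts(pos, meth, total)
        # mirrored methylome: site at p maps to L-1-p
        mir = np.argsort(L - 1 - pos)
        m_rev = matrix_from_counts((L - 1 - pos)[mir], meth[mir],
                                   total[mir])
        g_fwd = GeneModel("g", "chr1", "+", 10_000, 18_000,
                          [(10_000, 12_000), (15_000, 18_000)])
        g_rev = GeneModel("g", "chr1", "-", L - 18_000, L - 10_000,
                          [(L - 18_000, L - 15_000),
                           (L - 12_000, L - 10_000)])
        p_fwd = metaprofile(m_fwd, [g_fwd], [])
        p_rev = metaprofile(m_rev, [g_rev], [])
        for cls in ("promoter", "exon", "intron", "gene_body_flank"):
            pd.testing.assert_frame_equal(p_fwd[cls].values,
                                          p_rev[cls].values)

    def test_tss_dip_in_synthetic_data(self, small_dataset):
        body = small_dataset.matrix.drop_chrom("lambda").for_context("CG")
        profs = metaprofile(body, small_dataset.genes, small_dataset.cgis)
        v = profs["gene_body_flank"].values
        n_f = 20
        for group in (ANAGEN, TELOGEN):
            curve = v[(group, "CG")].to_numpy()
            promoter_proximal = np.nanmean(curve[n_f - 5:n_f + 2])
            gene_body = np.nanmean(curve[n_f + 15:n_f + 40])
            assert promoter_proximal < gene_body

    def test_short_gene_counted_not_dropped(self):
        pos = np.arange(0, 5000, 3)
        m = self._flat_matrix(pos, 0.5)
        tiny = GeneModel("tiny", "chr1", "+", 2000, 2030, [(2000, 2030)])
        profs = metaprofile(m, [tiny], [])
        assert profs["gene_body_flank"].n_short == 1
        body = profs["gene_body_flank"].values[(ANAGEN, "CG")].to_numpy()
        assert np.any(~np.isnan(body[20:70]))


class TestCpgOe:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 0.0),
        ("CGCG", 2.0),        # (2*4)/(2*2)
        ("ACGT", 4.0),        # (1*4)/(1*1)
    ])
    def test_hand_counts(self, seq, expected):
        assert cpg_oe(seq) == pytest.approx(expected)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_reverse_complement_preserves_ratio(self, seq):
        assert cpg_oe(seq) == pytest.approx(cpg_oe(revcomp(seq)))

    def test_higher_inside_cgis(self, small_dataset):
        seq = small_dataset.seqs["chr1"]
        cgis = [c for c in small_dataset.cgis if c.chrom == "chr1"]
        inside = np.mean([cpg_oe(seq[c.start:c.end]) for c in cgis])
        rng = np.random.default_rng(0)
        outs = []
        while len(outs) < 30:
            s = int(rng.integers(0, len(seq) - 1000))
            if not any(c.start - 1000 < s < c.end for c in cgis):
                outs.append(cpg_oe(seq[s:s + 1000]))
        assert inside > np.mean(outs)


class TestCorrelations:
    def _summaries(self, levels, lengths):
        return [ChromSummary(f"c{i}", int(l), float(v), 10, 0.5, 3, 4)
                for i, (v, l) in enumerate(zip(levels, lengths))]

    def test_perfect_positive(self):
        s = self._summaries([0.1, 0.2, 0.3, 0.4], [100, 200, 300, 400])
        assert chrom_feature_correlations(s).loc["length", "r"] == \
            pytest.approx(1.0)

    def test_perfect_negative(self):
        s = self._summaries([0.4, 0.3, 0.2, 0.1], [100, 200, 300, 400])
        assert chrom_feature_correlations(s).loc["length", "r"] == \
            pytest.approx(-1.0)

    def test_textbook_value(self):
        # r for x=(1,2,3), y=(2,4,7) by the closed formula
        x = np.array([1, 2, 3.0]); y = np.array([2, 4, 7.0])
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        s = self._summaries(y, x)
        assert chrom_feature_correlations(s).loc["length", "r"] == \
            pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gives_nan(self):
        s = self._summaries([0.1, 0.2, 0.3], [100, 100, 100])
        assert np.isnan(chrom_feature_correlations(s).loc["length", "r"])

    def test_needs_three_chromosomes(self):
        with pytest.raises(ValueError):
            chrom_feature_correlations(self._summaries([0.1, 0.2],
                                                       [1, 2]))

    def test_summaries_from_synthetic(self, small_dataset):
        s = summarize_chromosomes(
            small_dataset.matrix, small_dataset.seqs, small_dataset.genes,
            small_dataset.repeats)
        by = {x.chrom: x for x in s}
        assert by["chr1"].length == 1_000_000
        assert by["lambda"].mean_level < 0.02   # unmethylated spike-in
        assert all(x.cpg_oe >= 0 for x in s)


class TestSampleCorrelation:
    def test_unit_diagonal_and_symmetry(self, small_dataset):
        sub = small_dataset.matrix.for_context("CG")
        sub = sub.subset(np.arange(sub.n_sites) % 29 == 0)
        r = sample_correlation(sub)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T, equal_nan=True)

    def test_identical_level_vectors_correlate(self):
        rng = np.random.default_rng(3)
        levels = rng.uniform(0.05, 0.95, size=3000)
        total = np.full((3000, 6), 30)
        meth = np.column_stack([rng.binomial(30, levels)
                                for _ in range(6)])
        m = matrix_from_counts(np.arange(3000) * 5, meth, total)
        r = sample_correlation(m)
        off = r.to_numpy()[~np.eye(6, dtype=bool)]
        assert (off > 0.9).all()

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(4)
        total = np.full((200, 6), 20)
        meth = rng.integers(0, 21, size=(200, 6))
        pos = np.arange(200) * 3
        r1 = sample_correlation(matrix_from_counts(pos, meth, total))
        perm = rng.permutation(200)
        # permute sites of all samples together; re-sort restores order,
        # so r must not change
        r2 = sample_correlation(matrix_from_counts(pos[perm], meth[perm],
                                                   total[perm]))
        pd.testing.assert_frame_equal(r1, r2)
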
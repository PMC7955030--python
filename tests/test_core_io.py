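import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mregulome.core_io import (
    GenomicInterval,
    GenotypePanel,
    LDMatrix,
    MonomorphicVariantError,
    ParseError,
    SummaryStatRecord,
    bh_fdr,
    cluster_ld_blocks,
    compute_ld_matrix,
    harmonize_alleles,
    parse_bed_intervals,
    read_sumstats,
    write_bed_intervals,
    write_sumstats,
)


def make_stat(ea="A", oa="G", beta=0.1, eaf=None, vid="rs1"):
    return SummaryStatRecord(
        variant_id=vid, chrom="chr1", pos=100, effect_allele=ea, other_allele=oa,
        beta=beta, se=0.05, p=0.05, n=1000, eaf=eaf,
    )


class TestBedParsing:
    def test_flank_arithmetic(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t1000\t2000\n")
        (iv,) = parse_bed_intervals(bed, flank=0)
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 1000, 2000)
        (iv,) = parse_bed_intervals(bed, flank=500)
        assert (iv.start, iv.end) == (500, 2500)
        # flank never pushes start below zero
        bed.write_text("chr1\t100\t200\n")
        (iv,) = parse_bed_intervals(bed, flank=500)
        assert (iv.start, iv.end) == (0, 700)

    def test_inverted_interval_rejected_with_warning(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t300\t200\nchr1\t400\t500\n")
        with pytest.warns(UserWarning, match="start >= end"):
            ivs = parse_bed_intervals(bed)
        assert len(ivs) == 1 and ivs[0].start == 400

    def test_malformed_line_names_line_number(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\nchr1\tnot_a_number\t300\n")
        with pytest.raises(ParseError, match=":2"):
            parse_bed_intervals(bed)

    def test_roundtrip(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 10, 50, "+", "peak1", 3.5),
            GenomicInterval("chr2", 0, 7, "-", "peak2", None),
        ]
        path = tmp_path / "rt.bed"
        write_bed_intervals(ivs, path)
        back = parse_bed_intervals(path)
        assert [(i.chrom, i.start, i.end, i.strand, i.name) for i in back] == [
            (i.chrom, i.start, i.end, i.strand, i.name) for i in ivs
        ]


def test_sumstats_roundtrip(tmp_path):
    recs = [
        make_stat(vid="rs1", beta=0.123456, eaf=0.3),
        make_stat(vid="rs2", ea="C", oa="T", beta=-0.05),
    ]
    path = tmp_path / "ss.tsv"
    write_sumstats(recs, path)
    back = read_sumstats(path)
    for a, b in zip(recs, back):
        assert a.variant_id == b.variant_id
        assert a.effect_allele == b.effect_allele
        assert np.isclose(a.beta, b.beta, rtol=1e-5)
        assert (a.eaf is None) == (b.eaf is None)


def test_sumstat_invariants():
    with pytest.raises(ValueError, match="se"):
        SummaryStatRecord("v", "chr1", 1, "A", "G", 0.1, -1.0, 0.5, 100)
    with pytest.raises(ValueError, match="p"):
        SummaryStatRecord("v", "chr1", 1, "A", "G", 0.1, 0.1, 0.0, 100)
    with pytest.raises(ValueError, match="inconsistent z"):
        SummaryStatRecord("v", "chr1", 1, "A", "G", 0.1, 0.1, 0.5, 100, z=5.0)


class TestHarmonize:
    def test_already_aligned(self):
        b, reason = harmonize_alleles(make_stat(beta=0.1), make_stat(beta=0.2))
        assert reason == "ok" and b.beta == 0.2

    def test_flip_negates(self):
        b, _ = harmonize_alleles(make_stat(beta=0.1), make_stat("G", "A", beta=0.2, eaf=0.3))
        assert b.beta == -0.2
        assert b.effect_allele == "A" and np.isclose(b.eaf, 0.7)

    def test_strand_complement(self):
        # b reported on the opposite strand: A/G vs T/C
        b, reason = harmonize_alleles(make_stat(), make_stat("T", "C", beta=0.2))
        assert reason == "ok" and b.beta == 0.2 and b.effect_allele == "A"

    def test_palindromic_uninformative_dropped(self):
        b, reason = harmonize_alleles(
            make_stat("A", "T", eaf=0.5), make_stat("A", "T", eaf=0.5)
        )
        assert b is None and reason == "ambiguous_palindromic"

    def test_palindromic_informative_concordant_kept(self):
        b, reason = harmonize_alleles(
            make_stat("A", "T", eaf=0.2), make_stat("A", "T", beta=0.3, eaf=0.25)
        )
        assert reason == "ok" and b.beta == 0.3

    def test_palindromic_informative_discordant_flipped(self):
        b, _ = harmonize_alleles(
            make_stat("A", "T", eaf=0.2), make_stat("A", "T", beta=0.3, eaf=0.8)
        )
        assert b.beta == -0.3

    def test_irreconcilable(self):
        b, reason = harmonize_alleles(make_stat("A", "G"), make_stat("A", "C"))
        assert b is None and reason == "irreconcilable"

    @given(
        alleles=st.sampled_from([("A", "G"), ("G", "A"), ("T", "C"), ("C", "T")]),
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.one_of(st.none(), st.floats(0.01, 0.99)),
    )
    def test_involutive(self, alleles, beta, eaf):
        """Harmonizing an already-harmonized record changes nothing."""
        a = make_stat("A", "G", beta=0.1, eaf=0.4)
        b = make_stat(alleles[0], alleles[1], beta=beta or 0.1, eaf=eaf)
        once, reason = harmonize_alleles(a, b)
        if once is None:
            return
        twice, reason2 = harmonize_alleles(a, once)
        assert reason2 == "ok"
        assert twice.beta == once.beta
        assert (twice.effect_allele, twice.other_allele) == (
            once.effect_allele, once.other_allele)


class TestLDMatrix:
    def _panel(self, cols):
        X = np.column_stack(cols).astype(float)
        m = X.shape[1]
        return GenotypePanel(
            sample_ids=[f"i{k}" for k in range(X.shape[0])],
            variant_ids=[f"v{k}" for k in range(m)],
            positions=np.arange(1, m + 1),
            dosages=X,
        )

    def test_identical_columns(self):
        c = np.array([0, 1, 2, 1, 0])
        ld = compute_ld_matrix(self._panel([c, c]))
        assert np.isclose(ld.r[0, 1], 1.0)

    def test_reflected_column(self):
        c = np.array([0, 1, 2, 1, 0])
        ld = compute_ld_matrix(self._panel([c, 2 - c]))
        assert np.isclose(ld.r[0, 1], -1.0)

    def test_independent_columns_near_zero(self, rng):
        X = rng.binomial(2, 0.4, size=(10000, 2)).astype(float)
        ld = compute_ld_matrix(self._panel([X[:, 0], X[:, 1]]))
        assert abs(ld.r[0, 1]) < 0.05

    def test_monomorphic_error_names_variant(self):
        c = np.array([0, 1, 2, 1, 0])
        with pytest.raises(MonomorphicVariantError, match="v1"):
            compute_ld_matrix(self._panel([c, np.ones(5)]))

    def test_symmetric_and_psd_after_ridge(self, default_panel):
        ld = compute_ld_matrix(default_panel)
        assert np.allclose(ld.r, ld.r.T)
        assert np.allclose(np.diag(ld.r), 1.0)
        eigs = np.linalg.eigvalsh(ld.regularized(1e-4))
        assert eigs.min() > 0


def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        vals = [m * p[order[j - 1]] / j for j in range(rank_i, m + 1)]
        q[idx] = min(1.0, min(vals))
    return q


class TestBH:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.001, 0.5], [0.002, 0.5]),
            ([0.05], [0.05]),
        ],
    )
    def test_hand_computed(self, pvals, expected):
        assert np.allclose(bh_fdr(pvals), expected)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=50))
    def test_matches_brute_force(self, pvals):
        assert np.allclose(bh_fdr(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def brute_force_blocks(r, r2_cut):
    """Independent scan of the seed-extension rule."""
    m = r.shape[0]
    assignment = []
    seed = None
    block = -1
    for j in range(m):
        if seed is None or r[seed, j] ** 2 < r2_cut:
            block += 1
            seed = j
        assignment.append(block)
    return np.array(assignment)


class TestLDBlocks:
    def test_identity_every_variant_own_block(self):
        ld = LDMatrix([f"v{i}" for i in range(5)], np.eye(5))
        assert list(cluster_ld_blocks(ld)) == [0, 1, 2, 3, 4]

    def test_perfect_ld_single_block(self):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert list(cluster_ld_blocks(ld)) == [0, 0]

    def test_ar1_matches_brute_force(self):
        m, rho = 20, 0.95
        r = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        ld = LDMatrix([f"v{i}" for i in range(m)], r)
        got = cluster_ld_blocks(ld, r2_cut=0.5)
        assert np.array_equal(got, brute_force_blocks(r, 0.5))
        # every variant assigned exactly one block
        assert len(got) == m
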
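import numpy as np
import pytest

from mcanary.io_formats import FragmentSet, FragmentRecord, PipelineConfig, TSSRecord
from mcanary import synthetic_cohort as sc
from mcanary.tss_npcc import (
    NPCCVector,
    RDPKMProfile,
    bin_copy_ratio,
    cnv_normalize_depth,
    compute_npcc,
    core_windows_for_chrom,
    coverage_profile,
    filter_genes,
    fragment_5prime_start,
    gene_rdpkm,
    npcc_pipeline,
    nucleosome_core_window,
    site_depth,
)


def _fs(recs, genome=None):
    return FragmentSet.from_records(recs, genome=genome)


class TestFivePrimeStart:
    def test_forward(self):
        assert fragment_5prime_start(1000, 1100, "+") == 1000

    def test_reverse_is_end_minus_one(self):
        assert fragment_5prime_start(2000, 2100, "-") == 2099

    def test_length_one_same_both_strands(self):
        assert fragment_5prime_start(500, 501, "+") == fragment_5prime_start(500, 501, "-")


class TestCoreWindow:
    def test_forward_offsets(self):
        w = nucleosome_core_window(1000, "+")
        assert (w.start, w.end) == (1052, 1113)

    def test_reverse_mirror(self):
        w = nucleosome_core_window(2099, "-")
        assert (w.start, w.end) == (1987, 2048)

    def test_length_61_both_strands(self):
        for strand, pos in (("+", 1234), ("-", 9876)):
            w = nucleosome_core_window(pos, strand)
            assert w.end - w.start == 61

    def test_off_chromosome_returns_none(self):
        assert nucleosome_core_window(50, "-") is None

    def test_strand_mirror_symmetry(self):
        # reflecting the genome around pivot maps forward windows to
        # reverse windows exactly
        pivot = 100_000
        for pos in (1000, 5000, 77_777):
            fw = nucleosome_core_window(pos, "+")
            rv = nucleosome_core_window(pivot - 1 - pos, "-")
            assert rv.start == pivot - fw.end
            assert rv.end == pivot - fw.start

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(2)
        pos = rng.integers(200, 10_000, 100)
        strands = np.where(rng.uniform(size=100) < 0.5, "+", "-").astype(object)
        ws, we, dropped = core_windows_for_chrom(pos, strands)
        assert dropped == 0
        scalar = [nucleosome_core_window(int(p), s) for p, s in zip(pos, strands)]
        assert list(ws) == [w.start for w in scalar]
        assert list(we) == [w.end for w in scalar]

    def test_vectorized_drops_off_chromosome(self):
        ws, we, dropped = core_windows_for_chrom(
            np.array([50, 5000]), np.array(["-", "-"], dtype=object)
        )
        assert dropped == 1
        assert len(ws) == 1


class TestSiteDepth:
    def test_single_window(self):
        d = site_depth([100], [161], 0, 300)
        assert d.sum() == 61
        assert (d[100:161] == 1).all()

    def test_two_identical_windows(self):
        d = site_depth([100, 100], [161, 161], 0, 300)
        assert (d[100:161] == 2).all()

    def test_random_windows_match_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 4000, 1000)
        ends = starts + 61
        d = site_depth(starts, ends, 0, 4100)
        # O(n*L) per-base oracle
        oracle = np.zeros(4100, dtype=int)
        for s, e in zip(starts, ends):
            for p in range(s, min(e, 4100)):
                oracle[p] += 1
        assert (d == oracle).all()

    def test_region_clipping(self):
        d = site_depth([90], [151], 100, 160)
        assert (d == 1).sum() == 51


class TestBinCopyRatio:
    def test_uniform_coverage_ratio_one(self):
        genome = {"chr1": 500_000}
        recs = [FragmentRecord("chr1", p, p + 100, "+") for p in range(0, 500_000 - 100, 50)]
        bins = bin_copy_ratio(_fs(recs), genome)
        assert np.allclose(bins.ratios["chr1"], 1.0, atol=0.01)
        assert np.allclose(bins.log2_ratios["chr1"], 0.0, atol=0.02)

    def test_doubled_bin(self):
        genome = {"chr1": 300_000}
        recs = [FragmentRecord("chr1", p, p + 100, "+") for p in range(0, 300_000 - 100, 100)]
        # double the middle bin [100k, 200k)
        recs += [FragmentRecord("chr1", p, p + 100, "+") for p in range(100_000, 200_000 - 100, 100)]
        bins = bin_copy_ratio(_fs(recs), genome)
        assert bins.ratios["chr1"][1] == pytest.approx(2.0, rel=0.02)
        assert bins.log2_ratios["chr1"][1] == pytest.approx(1.0, abs=0.05)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            bin_copy_ratio(_fs([]), {"chr1": 100_000})

    def test_three_copy_segment_recovered(self):
        # generative oracle: 1.5x rate over 10 bins on a 2x baseline genome
        genome = {"chr1": 3_000_000}
        rng = np.random.default_rng(9)
        n_base = rng.poisson(2 * 0.01 * 3_000_000)
        pos = rng.integers(0, 3_000_000, n_base)
        seg = (1_000_000, 2_000_000)
        extra = rng.integers(seg[0], seg[1], rng.poisson(0.01 * (seg[1] - seg[0])))
        allpos = np.concatenate([pos, extra])
        recs = _fs([FragmentRecord("chr1", int(p), int(p) + 100, "+") for p in allpos])
        bins = bin_copy_ratio(recs, genome)
        seg_bins = bins.ratios["chr1"][10:20]
        assert np.allclose(seg_bins, 1.5, atol=0.1)

    def test_ratio_clamped(self):
        genome = {"chr1": 300_000}
        recs = [FragmentRecord("chr1", p, p + 100, "+") for p in range(0, 1000, 2)]
        recs += [FragmentRecord("chr1", 100_500, 100_600, "+")]
        recs += [FragmentRecord("chr1", 200_500, 200_600, "+")]
        bins = bin_copy_ratio(_fs(recs), genome)
        assert bins.ratios["chr1"].min() >= 0.1
        assert bins.ratios["chr1"].max() <= 10.0


class TestCnvNormalize:
    def test_identity_at_ratio_one(self):
        genome = {"chr1": 200_000}
        recs = [FragmentRecord("chr1", p, p + 100, "+") for p in range(0, 200_000 - 100, 100)]
        bins = bin_copy_ratio(_fs(recs), genome)
        depth = np.ones(200_000)
        out = cnv_normalize_depth(depth, "chr1", bins)
        assert np.allclose(out, depth, rtol=2e-3)

    def test_divides_by_linear_ratio(self):
        # bins 0 and 1 at baseline density, bin 2 doubled -> median is the
        # baseline, so bin 2 gets ratio 2 and its depth is halved
        bins = bin_copy_ratio(
            _fs(
                [FragmentRecord("chr1", p, p + 50, "+") for p in range(0, 200_000, 100)]
                + [FragmentRecord("chr1", p, p + 50, "+") for p in range(200_000, 300_000, 50)]
            ),
            {"chr1": 300_000},
        )
        depth = np.full(300_000, 10.0)
        out = cnv_normalize_depth(depth, "chr1", bins)
        assert out[250_000] == pytest.approx(5.0, rel=0.02)
        assert out[50_000] == pytest.approx(10.0, rel=0.02)

    def test_normalization_removes_cnv_effect(self):
        # doubled-coverage simulation: after normalization bin means agree to 5%
        genome = {"chr1": 1_000_000}
        rng = np.random.default_rng(9)
        base = rng.integers(0, 1_000_000, 40_000)
        extra = rng.integers(400_000, 600_000, 8_000)
        pos = np.concatenate([base, extra])
        strands = np.where(rng.uniform(size=len(pos)) < 0.5, "+", "-").astype(object)
        lens = np.full(len(pos), 167)
        starts = np.where(strands == "+", pos, pos - lens + 1)
        ends = np.where(strands == "+", pos + lens, pos + 1)
        ok = (starts >= 0) & (ends <= 1_000_000)
        fs = FragmentSet(
            np.full(int(ok.sum()), "chr1", dtype=object), starts[ok], ends[ok], strands[ok]
        )
        bins = bin_copy_ratio(fs, genome)
        starts5p = np.where(fs.strands == "+", fs.starts, fs.ends - 1)
        ws, we, _ = core_windows_for_chrom(starts5p, fs.strands)
        depth = site_depth(ws, we, 0, 1_000_000).astype(float)
        norm = cnv_normalize_depth(depth, "chr1", bins)
        inside = norm[420_000:580_000].mean()
        outside = np.concatenate([norm[20_000:380_000], norm[620_000:980_000]]).mean()
        assert inside == pytest.approx(outside, rel=0.05)


class TestGeneRDPKM:
    def test_direct_definition_oracle(self):
        # accumulated depth 500 over 2000 bp, 1e6 mapped reads -> 250
        depth = np.zeros(10_000)
        depth[4000:4500] = 1.0  # sums to 500 over the window [3000, 5000)
        prof = gene_rdpkm(
            {"chr1": depth},
            [TSSRecord("g1", "t1", "chr1", 4000, "+")],
            total_mapped=1_000_000,
            flank=1000,
        )
        assert prof.rdpkm["g1"] == pytest.approx(500 / (2.0 * 1.0))

    def test_zero_depth(self):
        prof = gene_rdpkm(
            {"chr1": np.zeros(5000)},
            [TSSRecord("g1", "t1", "chr1", 2000, "+")],
            total_mapped=10_000,
        )
        assert prof.rdpkm["g1"] == 0.0

    def test_multi_transcript_mean(self):
        depth = np.zeros(20_000)
        depth[4000:6000] = 1.0  # t1 window sum 2000
        depth[12_000:14_000] = 3.0  # t2 window sum 6000
        prof = gene_rdpkm(
            {"chr1": depth},
            [
                TSSRecord("g1", "t1", "chr1", 5000, "+"),
                TSSRecord("g1", "t2", "chr1", 13_000, "+"),
            ],
            total_mapped=1_000_000,
        )
        # RDPKMs 1000 and 3000 -> gene mean 2000
        assert prof.rdpkm["g1"] == pytest.approx(2000.0)

    def test_off_chromosome_transcript_skipped(self):
        prof = gene_rdpkm(
            {"chr1": np.ones(5000)},
            [
                TSSRecord("g1", "t1", "chr1", 500, "+"),  # window [-500, 1500) off
                TSSRecord("g2", "t1", "chr1", 2500, "+"),
            ],
            total_mapped=10_000,
        )
        assert "g1" not in prof.rdpkm
        assert "g2" in prof.rdpkm

    def test_invariant_to_joint_doubling(self):
        depth = np.random.default_rng(1).uniform(0, 5, 10_000)
        tss = [TSSRecord("g1", "t1", "chr1", 5000, "+")]
        p1 = gene_rdpkm({"chr1": depth}, tss, total_mapped=100_000)
        p2 = gene_rdpkm({"chr1": 2 * depth}, tss, total_mapped=200_000)
        assert p1.rdpkm["g1"] == pytest.approx(p2.rdpkm["g1"], rel=1e-12)

    def test_total_mapped_positive_required(self):
        with pytest.raises(ValueError):
            gene_rdpkm({"chr1": np.ones(10)}, [], total_mapped=0)


def _profile(rdpkm):
    return RDPKMProfile(rdpkm, total_mapped_reads=1_000_000, window_flank=1000)


def _refs(fpkm_by_type):
    from mcanary.io_formats import ExpressionReference

    return {t: ExpressionReference(t, dict(v)) for t, v in fpkm_by_type.items()}


class TestFilterGenes:
    def test_low_rdpkm_removed(self):
        refs = _refs({"BRCA": {"g1": 10.0, "g2": 10.0}})
        prof = _profile({"g1": 99.9, "g2": 150.0})
        assert filter_genes(prof, refs) == {"g2"}

    def test_low_fpkm_removed(self):
        # mean FPKM 1.0 -> log2 = 0 < 0.1 -> removed
        refs = _refs({"BRCA": {"g1": 1.0, "g2": 2.0}})
        prof = _profile({"g1": 500.0, "g2": 500.0})
        assert filter_genes(prof, refs) == {"g2"}

    def test_boundaries_are_strict(self):
        # RDPKM exactly 100 and log2(FPKM)=0.1 exactly are retained
        refs = _refs({"BRCA": {"g1": 2**0.1, "g2": 5.0}})
        prof = _profile({"g1": 100.0, "g2": 100.0})
        assert filter_genes(prof, refs) == {"g1", "g2"}

    def test_must_pass_all_references(self):
        refs = _refs({"BRCA": {"g1": 10.0}, "DLBC": {"g1": 0.5}})
        prof = _profile({"g1": 500.0})
        with pytest.raises(ValueError, match="no genes retained"):
            filter_genes(prof, refs)

    def test_empty_retained_is_error(self):
        refs = _refs({"BRCA": {"g1": 10.0}})
        prof = _profile({"g1": 5.0})
        with pytest.raises(ValueError):
            filter_genes(prof, refs)


class TestComputeNPCC:
    def test_equal_references_give_equal_thirds(self):
        genes = {f"g{i}": float(100 + 17 * i) for i in range(10)}
        fpkm = {f"g{i}": float(3 + i) for i in range(10)}
        refs = _refs({"BRCA": fpkm, "DLBC": fpkm, "LIHC": fpkm})
        vec = compute_npcc(_profile(genes), refs)
        for t in refs:
            assert vec.npcc[t] == pytest.approx(1 / 3, abs=1e-9)

    def test_npcc_is_r_over_sum(self):
        rng = np.random.default_rng(4)
        genes = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(100, 1000, 30))}
        refs = _refs(
            {
                t: {g: float(v) for g, v in zip(genes, rng.uniform(2, 50, 30))}
                for t in ("BRCA", "DLBC", "LIHC")
            }
        )
        vec = compute_npcc(_profile(genes), refs)
        total = sum(vec.r_raw.values())
        for t in refs:
            assert vec.npcc[t] == pytest.approx(vec.r_raw[t] / total, abs=1e-12)
        assert sum(vec.npcc.values()) == pytest.approx(1.0, abs=1e-9)

    def test_pearson_matches_two_pass_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(100, 900, 50)
        y = rng.uniform(1, 40, 50)
        genes = {f"g{i}": float(v) for i, v in enumerate(x)}
        refs = _refs({"BRCA": {g: float(v) for g, v in zip(genes, y)}})
        vec = compute_npcc(_profile(genes), refs)
        # textbook two-pass oracle
        xs = np.array([genes[g] for g in sorted(genes)])
        ys = np.array([refs["BRCA"].mean_fpkm[g] for g in sorted(genes)])
        xc, yc = xs - xs.mean(), ys - ys.mean()
        oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert vec.r_raw["BRCA"] == pytest.approx(oracle, abs=1e-12)

    def test_cancelling_coefficients_error(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]) * 200
        genes = {f"g{i}": float(v) for i, v in enumerate(x)}
        up = {g: float(v) for g, v in zip(genes, [2.0, 3.0, 4.0, 5.0])}
        down = {g: float(v) for g, v in zip(genes, [5.0, 4.0, 3.0, 2.0])}
        refs = _refs({"A": up, "B": down})
        with pytest.raises(ValueError, match="cancel"):
            compute_npcc(_profile(genes), refs)

    def test_constant_reference_error(self):
        genes = {f"g{i}": float(100 + i) for i in range(5)}
        refs = _refs({"BRCA": {g: 5.0 for g in genes}})
        with pytest.raises(ValueError, match="constant"):
            compute_npcc(_profile(genes), refs)

    def test_too_few_genes_error(self):
        genes = {"g1": 200.0, "g2": 300.0}
        refs = _refs({"BRCA": {"g1": 5.0, "g2": 9.0}})
        with pytest.raises(ValueError, match=">= 3"):
            compute_npcc(_profile(genes), refs)

    def test_formula_example(self):
        vec = NPCCVector(
            r_raw={"BRCA": 0.1, "DLBC": 0.2, "LIHC": 0.3},
            npcc={"BRCA": 1 / 6, "DLBC": 1 / 3, "LIHC": 1 / 2},
            n_genes_used=10,
        )
        assert sum(vec.npcc.values()) == pytest.approx(1.0)


class TestEndToEnd:
    def test_liver_sample_dominant_lihc(self, toy_genome, tss_records, expression_refs):
        spec = sc.FragmentSimSpec(
            tissue="LIHC",
            genome=toy_genome,
            tss_records=tss_records,
            expression=expression_refs,
            seed=11,
        )
        frags, _ = sc.simulate_fragments(spec)
        _, vec = npcc_pipeline(frags, tss_records, expression_refs, toy_genome)
        assert max(vec.npcc, key=lambda t: abs(vec.npcc[t])) == "LIHC"
        assert min(vec.r_raw, key=vec.r_raw.get) == "LIHC"

    def test_known_tissue_recovery_across_seeds(self, toy_genome, tss_records, expression_refs):
        hits = 0
        n_runs = 8
        for seed in range(100, 100 + n_runs):
            spec = sc.FragmentSimSpec(
                tissue="BRCA",
                genome=toy_genome,
                tss_records=tss_records,
                expression=expression_refs,
                seed=seed,
            )
            frags, _ = sc.simulate_fragments(spec)
            _, vec = npcc_pipeline(frags, tss_records, expression_refs, toy_genome)
            if min(vec.r_raw, key=vec.r_raw.get) == "BRCA":
                hits += 1
        assert hits >= int(0.8 * n_runs)

    def test_coverage_profile_scale(self, toy_genome, tss_records, expression_refs, liver_fragments):
        prof = coverage_profile(liver_fragments, tss_records, toy_genome)
        assert prof.total_mapped_reads == len(liver_fragments)
        assert all(v >= 0 for v in prof.rdpkm.values())
        assert len(prof.rdpkm) == len({r.gene_id for r in tss_records})
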
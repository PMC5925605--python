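"""Intensity log ratios, segmentation, and recurrent CNV aggregation."""

import numpy as np
import pandas as pd
import pytest

from methylforge import cnv, synth
from methylforge.cnv import _max_arc_t, _max_t_split
from methylforge.datatypes import SignalMatrix


def _manifest(n, chrom="chr1", step=100):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * step,
            "gene": "",
            "island_relation": "open_sea",
            "enhancer": False,
            "snp_flag": False,
        },
        index=pd.Index([f"p{i}" for i in range(n)], name="probe_id"),
    )


class TestTotalIntensity:
    def test_sum_and_symmetry(self):
        idx = pd.Index(["p0"], name="probe_id")
        m = pd.DataFrame([[300.0]], index=idx, columns=["s"])
        u = pd.DataFrame([[200.0]], index=idx, columns=["s"])
        d = pd.DataFrame([[0.001]], index=idx, columns=["s"])
        assert cnv.total_intensity(SignalMatrix(m, u, d)).iloc[0, 0] == 500.0
        assert cnv.total_intensity(SignalMatrix(u, m, d)).iloc[0, 0] == 500.0


class TestLogRatio:
    def _toy(self, rng, n=100, tumor_factor=None):
        # probe-specific brightness, identical across samples
        brightness = rng.lognormal(mean=7, sigma=1, size=n)
        cols = {f"n{i}": brightness for i in range(4)}
        tumor = brightness * (tumor_factor if tumor_factor is not None else 1.0)
        cols["t0"] = tumor
        return pd.DataFrame(cols, index=_manifest(n).index)

    def test_normal_identical_to_median_maps_to_zero(self, rng):
        T = self._toy(rng)
        L = cnv.log_ratio(T, ["n0", "n1", "n2", "n3"])
        assert np.allclose(L["n0"], 0.0, atol=1e-12)

    def test_doubled_and_halved_intensity(self, rng):
        # small aberrant fraction; rank normalization slightly attenuates
        # probes near the brightness extremes, hence the 0.05 tolerance
        n = 1000
        T = self._toy(rng, n)
        T.loc[T.index[:10], "t0"] *= 2.0
        T.loc[T.index[100:110], "t0"] *= 0.5
        L = cnv.log_ratio(T, ["n0", "n1", "n2", "n3"])
        assert np.allclose(L["t0"].iloc[:10], np.log10(2.0), atol=0.05)
        assert np.allclose(L["t0"].iloc[100:110], np.log10(0.5), atol=0.05)
        assert L["t0"].iloc[:10].mean() == pytest.approx(np.log10(2.0), abs=0.03)

    def test_all_zero_probe_excluded(self, rng):
        T = self._toy(rng)
        T.iloc[3] = 0.0
        L = cnv.log_ratio(T, ["n0", "n1", "n2", "n3"])
        assert "p3" not in L.index


class TestSmoothOutliers:
    def test_isolated_spike_shrunk_neighbors_untouched(self):
        m = _manifest(21)
        vals = np.zeros((21, 1))
        vals[10] = 3.0
        L = pd.DataFrame(vals, index=m.index, columns=["s"])
        out = cnv.smooth_outliers(L, m, k_sd=3.0)
        sd = L["s"].std(ddof=0)
        assert out.loc["p10", "s"] == pytest.approx(3.0 * sd)
        assert (out.drop(index="p10")["s"] == 0).all()

    def test_no_outliers_is_identity(self, rng):
        m = _manifest(30)
        L = pd.DataFrame(
            rng.normal(0, 0.05, size=(30, 2)), index=m.index, columns=["a", "b"]
        )
        out = cnv.smooth_outliers(L, m, k_sd=5.0)
        pd.testing.assert_frame_equal(out, L)

    def test_short_chromosome_passed_through(self, rng):
        m = _manifest(4)
        L = pd.DataFrame(
            np.array([[0.0], [0.0], [9.0], [0.0]]), index=m.index, columns=["s"]
        )
        out = cnv.smooth_outliers(L, m, k_sd=1.0)
        pd.testing.assert_frame_equal(out, L)


class TestSegment:
    def test_constant_vector_no_change_points(self):
        assert cnv.segment(np.full(40, 0.2), n_perm=100, seed=1) == []

    def test_clean_step_found_exactly(self):
        v = np.concatenate([np.zeros(25), np.full(25, 0.5)])
        cps = cnv.segment(v, alpha=0.01, n_perm=200, seed=2)
        assert cps == [25]

    def test_interior_segment_found_both_boundaries(self, rng):
        v = rng.normal(0, 0.05, 300)
        v[120:150] += 0.4
        cps = cnv.segment(v, alpha=0.01, n_perm=200, seed=3)
        assert any(abs(c - 120) <= 2 for c in cps)
        assert any(abs(c - 150) <= 2 for c in cps)

    def test_binary_split_matches_exhaustive_search(self, rng):
        # oracle: argmax of the pooled two-sample t over all splits
        for trial in range(20):
            n = int(rng.integers(8, 50))
            v = rng.normal(size=n)
            split, t = _max_t_split(v, min_side=2)
            best_t, best_i = -1.0, -1
            for i in range(2, n - 1):
                a, b = v[:i], v[i:]
                sp = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n - 2)
                ti = abs(a.mean() - b.mean()) / np.sqrt(sp * (1 / i + 1 / (n - i)))
                if ti > best_t:
                    best_t, best_i = ti, i
            assert split == best_i
            assert t == pytest.approx(best_t, rel=1e-10)

    def test_arc_scan_matches_exhaustive_arc_search(self, rng):
        # oracle: argmax of the arc-vs-complement t over all (i, j) pairs
        for trial in range(10):
            n = int(rng.integers(10, 50))
            v = rng.normal(size=n)
            i, j, t = _max_arc_t(v, min_side=2)
            best = (-1.0, None)
            for ii in range(0, n - 1):
                for jj in range(ii + 2, n + 1):
                    m = jj - ii
                    if m < 2 or n - m < 2:
                        continue
                    inside, outside = v[ii:jj], np.concatenate([v[:ii], v[jj:]])
                    sp = (((inside - inside.mean()) ** 2).sum()
                          + ((outside - outside.mean()) ** 2).sum()) / (n - 2)
                    tt = abs(inside.mean() - outside.mean()) / np.sqrt(
                        sp * (1 / m + 1 / (n - m))
                    )
                    if tt > best[0]:
                        best = (tt, (ii, jj))
            assert t == pytest.approx(best[0], rel=1e-10)

    def test_type_one_error_on_pure_noise(self):
        # ~1% acceptance rate at alpha=0.01: few false splits in 50 tracks
        false_splits = 0
        for rep in range(50):
            v = np.random.default_rng(1000 + rep).normal(0, 0.1, 100)
            if cnv.segment(v, alpha=0.01, n_perm=200, seed=rep):
                false_splits += 1
        assert false_splits <= 5


class TestCallSegments:
    def _segs(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample_id", "chrom", "start", "end", "n_markers",
                     "mean_log_ratio"],
        )

    def test_marker_and_ratio_gates(self):
        segs = self._segs(
            [
                ("t1", "chr1", 100, 400, 4, 0.5),    # too few markers
                ("t1", "chr1", 500, 1100, 6, 0.25),  # gain
                ("t1", "chr1", 1200, 1800, 6, -0.25),  # not below loss cut
                ("t1", "chr2", 100, 700, 6, -0.35),  # loss
            ]
        )
        out = cnv.call_segments(segs)
        assert len(out) == 2
        assert list(out["direction"]) == ["gain", "loss"]

    def test_asymmetric_cuts_respected(self):
        segs = self._segs([("t1", "chr1", 1, 600, 6, 0.21),
                           ("t1", "chr1", 700, 1300, 6, -0.29)])
        out = cnv.call_segments(segs)
        assert len(out) == 1 and out.iloc[0]["direction"] == "gain"


class TestFilterSharedAndBlacklist:
    def _seg(self, sid, chrom, start, end, direction):
        return {
            "sample_id": sid, "chrom": chrom, "start": start, "end": end,
            "n_markers": 10,
            "mean_log_ratio": 0.4 if direction == "gain" else -0.4,
            "direction": direction,
        }

    def test_segment_mirrored_in_normal_dropped(self):
        tumor = pd.DataFrame([self._seg("t1", "chr1", 100, 200, "gain")])
        normal = pd.DataFrame([self._seg("n1", "chr1", 50, 300, "gain")])
        out = cnv.filter_shared_and_blacklist(tumor, normal)
        assert out.empty

    def test_opposite_direction_overlap_kept(self):
        tumor = pd.DataFrame([self._seg("t1", "chr1", 100, 200, "loss")])
        normal = pd.DataFrame([self._seg("n1", "chr1", 50, 300, "gain")])
        out = cnv.filter_shared_and_blacklist(tumor, normal)
        assert len(out) == 1

    def test_single_bp_blacklist_overlap_drops(self):
        tumor = pd.DataFrame([self._seg("t1", "chr1", 100, 200, "gain")])
        normal = tumor.iloc[:0]
        out = cnv.filter_shared_and_blacklist(
            tumor, normal, blacklist=[("chr1", 200, 400)]
        )
        assert out.empty

    def test_partial_same_direction_overlap_below_half_kept(self):
        tumor = pd.DataFrame([self._seg("t1", "chr1", 100, 300, "gain")])
        normal = pd.DataFrame([self._seg("n1", "chr1", 280, 500, "gain")])
        out = cnv.filter_shared_and_blacklist(tumor, normal)
        assert len(out) == 1


class TestRecurrentSegments:
    def _seg(self, sid, start, end, direction="gain"):
        return {
            "sample_id": sid, "chrom": "chr1", "start": start, "end": end,
            "n_markers": 10, "mean_log_ratio": 0.4, "direction": direction,
        }

    def test_identical_gains_reported_with_support(self):
        segs = pd.DataFrame([self._seg("t1", 100, 200), self._seg("t2", 100, 200)])
        out = cnv.recurrent_segments(segs)
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 200)
        assert out.iloc[0]["support"] == 2

    def test_singleton_absent(self):
        out = cnv.recurrent_segments(pd.DataFrame([self._seg("t1", 100, 200)]))
        assert out.empty

    def test_partial_overlap_intersection(self):
        segs = pd.DataFrame([self._seg("t1", 100, 200), self._seg("t2", 150, 250)])
        out = cnv.recurrent_segments(segs)
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (150, 200)

    def test_directions_kept_separate(self):
        segs = pd.DataFrame(
            [self._seg("t1", 100, 200, "gain"), self._seg("t2", 100, 200, "loss")]
        )
        out = cnv.recurrent_segments(segs)
        assert out.empty


class TestOverlapDmrs:
    def test_inclusive_overlap_arithmetic(self):
        cnvs = pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 200, "direction": "gain",
              "support": 2}]
        )
        dmrs = pd.DataFrame(
            [{"chrom": "chr1", "start": 150, "end": 300, "value": 0.25}]
        )
        out = cnv.overlap_dmrs(cnvs, dmrs)
        assert len(out) == 1
        assert out.iloc[0]["overlap_bp"] == 51
        assert bool(out.iloc[0]["hyper_concordant"])

    def test_disjoint_intervals_no_row(self):
        cnvs = pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 200, "direction": "gain",
              "support": 2}]
        )
        dmrs = pd.DataFrame(
            [{"chrom": "chr1", "start": 300, "end": 400, "value": 0.25}]
        )
        assert cnv.overlap_dmrs(cnvs, dmrs).empty

    def test_loss_not_hyper_concordant(self):
        cnvs = pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 200, "direction": "loss",
              "support": 2}]
        )
        dmrs = pd.DataFrame(
            [{"chrom": "chr1", "start": 150, "end": 250, "value": 0.25}]
        )
        out = cnv.overlap_dmrs(cnvs, dmrs)
        assert not bool(out.iloc[0]["hyper_concordant"])


class TestEndToEndRecovery:
    def test_spiked_segments_recovered(self, small_cohort):
        from methylforge import preprocess

        signal = small_cohort["signal"]
        manifest = small_cohort["manifest"]
        sheet = small_cohort["sheet"]
        truth = small_cohort["truth"]
        filtered, _ = preprocess.filter_probes(signal, manifest)
        T = cnv.total_intensity(filtered)
        normals = sheet.index[sheet["group"] == "normal"]
        L = cnv.log_ratio(T, normals)
        L = cnv.smooth_outliers(L, manifest.loc[L.index])
        segs = cnv.segment_matrix(
            L, manifest.loc[L.index], alpha=0.01, n_perm=200, seed=5
        )
        man = manifest.loc[L.index]
        # recovery is scored on the segmentation output: boundary accuracy
        # and mean log ratio (threshold calls are tested separately)
        for chrom, start, end, sid, cn_state in truth.cnv_segments:
            hits = segs[
                (segs["sample_id"] == sid) & (segs["chrom"] == chrom)
                & (segs["start"] <= end) & (segs["end"] >= start)
                & (segs["n_markers"] >= 5)
                & (segs["mean_log_ratio"].abs() > 0.1)
            ]
            assert len(hits) >= 1, f"missed {chrom}:{start}-{end} in {sid}"
            on = man[man["chrom"] == chrom]
            truth_n = int(((on["pos"] >= start) & (on["pos"] <= end)).sum())
            got_n = int(hits["n_markers"].sum())
            assert abs(got_n - truth_n) <= 2
            mean = float(
                (hits["mean_log_ratio"] * hits["n_markers"]).sum()
                / hits["n_markers"].sum()
            )
            assert mean == pytest.approx(np.log10(cn_state / 2.0), abs=0.05)

    def test_normals_center_at_zero(self, small_cohort):
        from methylforge import preprocess

        filtered, _ = preprocess.filter_probes(
            small_cohort["signal"], small_cohort["manifest"]
        )
        T = cnv.total_intensity(filtered)
        sheet = small_cohort["sheet"]
        normals = sheet.index[sheet["group"] == "normal"]
        L = cnv.log_ratio(T, normals)
        assert abs(L[normals].to_numpy().mean()) < 0.01
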
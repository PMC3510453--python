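"""Anchored profile matrices, aggregate NDR geometry, 5' vs 3' comparison,
and hierarchical subclade extraction."""

import numpy as np
import pandas as pd
import pytest

from tetramap import profiles
from tetramap.core import Replicon, SmoothedTrack, TranscriptUnit
from tetramap.simulate import SimulationConfig, expected_refined_spans, simulate


def unit(start, end, strand="+"):
    return TranscriptUnit("chr", start, end, strand, "confirmed", ("x",))


def ramp_track(n=5000):
    rep = Replicon("chr", n, circular=True)
    return SmoothedTrack(rep, np.arange(n, dtype=float) + 1.0, "ramp")


@pytest.fixture(scope="module")
def span_units(bundle):
    spans = expected_refined_spans(bundle.truth_units)
    ids = [f"op{r.operon}" for r in spans.itertuples()]
    units = [
        TranscriptUnit("chr", r.start, r.end, r.strand, "confirmed", tuple(r.member_ids))
        for r in spans.itertuples()
    ]
    return units, ids


class TestAnchoredMatrix:
    def test_plus_strand_row_is_forward_slice(self):
        mat = profiles.anchored_matrix(ramp_track(), [unit(1000, 1500)], "tss",
                                       flank=200, normalize="none")
        np.testing.assert_array_equal(
            mat.data.iloc[0].to_numpy(), np.arange(801, 1202, dtype=float)
        )

    def test_minus_strand_row_is_reversed(self):
        mat = profiles.anchored_matrix(ramp_track(), [unit(500, 1001, "-")], "tss",
                                       flank=200, normalize="none")
        np.testing.assert_array_equal(
            mat.data.iloc[0].to_numpy(), np.arange(1201, 800, -1, dtype=float)
        )

    def test_constant_track_rows_normalize_to_one(self):
        rep = Replicon("chr", 3000, circular=True)
        track = SmoothedTrack(rep, np.full(3000, 7.0), "const")
        mat = profiles.anchored_matrix(track, [unit(1000, 1400), unit(2000, 2400, "-")], "tss")
        np.testing.assert_allclose(mat.data.to_numpy(), 1.0)

    def test_strandless_units_skipped(self):
        mat = profiles.anchored_matrix(ramp_track(), [unit(1000, 1500),
                                       TranscriptUnit("chr", 1, 100, ".", "novel", ())], "tss")
        assert len(mat.data) == 1

    def test_orientation_mirror_symmetry(self):
        """A minus-strand transcript over the mirrored signal gives the same
        profile as a plus-strand transcript over the original."""
        n = 4000
        rng = np.random.default_rng(0)
        sig = rng.random(n) + 0.5
        rep = Replicon("chr", n, circular=True)
        fwd = SmoothedTrack(rep, sig, "s")
        rev = SmoothedTrack(rep, sig[::-1].copy(), "s")
        m_fwd = profiles.anchored_matrix(fwd, [unit(1000, 1500, "+")], "tss")
        m_rev = profiles.anchored_matrix(rev, [unit(n - 1500, n - 1000 + 1 - 1, "-")], "tss")
        np.testing.assert_allclose(
            m_fwd.data.iloc[0].to_numpy(), m_rev.data.iloc[0].to_numpy()
        )


class TestAggregateAndNdr:
    def test_single_row_aggregate_equals_row(self):
        mat = profiles.anchored_matrix(ramp_track(), [unit(1000, 1500)], "tss")
        agg = profiles.aggregate_profile(mat)
        np.testing.assert_allclose(agg["mean"].to_numpy(), mat.data.iloc[0].to_numpy())

    def test_v_shape_depth(self):
        # V from flanks at 1.0 (local maxima at -150 and +50) to 0.4 at -50
        offs = np.arange(-200, 201)
        y = np.where(np.abs(offs + 50) <= 100, 0.4 + 0.6 * np.abs(offs + 50) / 100.0, 1.0)
        y = y - 0.001 * np.maximum(0, -150 - offs) - 0.001 * np.maximum(0, offs - 50)
        agg = pd.Series(y, index=offs)
        ndr = profiles.detect_ndr(agg, "tss")
        assert ndr.min_offset == -50
        assert ndr.depth == pytest.approx(0.6, abs=0.02)

    def test_flat_aggregate_is_an_error(self):
        offs = np.arange(-200, 201)
        agg = pd.Series(np.ones(401), index=offs)
        with pytest.raises(ValueError):
            profiles.detect_ndr(agg, "tss")

    def test_planted_tss_ndr_and_flanking_nucleosomes(self, smoothed, span_units):
        units, ids = span_units
        mat = profiles.anchored_matrix(smoothed, units, "tss", ids=ids)
        agg = profiles.aggregate_profile(mat, n_boot=50, seed=0)
        ndr = profiles.detect_ndr(agg, "tss")
        assert abs(ndr.min_offset - (-50)) <= 10  # planted NDR center
        assert (agg["lo"] <= agg["mean"]).all() and (agg["mean"] <= agg["hi"]).all()

    def test_five_prime_ndr_deeper_and_wider_than_three_prime(self, smoothed, span_units):
        units, ids = span_units
        m5 = profiles.anchored_matrix(smoothed, units, "tss", ids=ids)
        m3 = profiles.anchored_matrix(smoothed, units, "tts", ids=ids)
        c5 = profiles.detect_ndr(profiles.aggregate_profile(m5), "tss")
        c3 = profiles.detect_ndr(profiles.aggregate_profile(m3), "tts")
        report = profiles.compare_ndr(c5, c3, m5, m3, n_boot=60, seed=0)
        assert report["depth_diff"] > 0 and report["width_diff"] > 0
        assert report["depth_diff_ci"][0] > 0
        assert report["width_diff_ci"][0] > 0

    def test_identical_profiles_zero_difference(self):
        offs = np.arange(-200, 201)
        y = 1.0 + 0.3 * np.cos(offs / 20.0) - 0.5 * np.exp(-((offs + 50) ** 2) / 800)
        call = profiles.detect_ndr(pd.Series(y, index=offs), "tss")
        rep = profiles.compare_ndr(call, call)
        assert rep["depth_diff"] == 0 and rep["width_diff"] == 0


class TestClustering:
    def make_matrix(self, rows, ids):
        offs = np.arange(-10, 11)
        data = pd.DataFrame(rows, index=ids, columns=offs)
        return profiles.ProfileMatrix("tss", 10, data)

    def test_three_orthogonal_templates(self):
        rng = np.random.default_rng(0)
        t = np.eye(3).repeat(7, axis=1)
        rows, ids, labels = [], [], []
        for i in range(30):
            k = i % 3
            rows.append(t[k] + rng.normal(0, 0.01, 21))
            ids.append(f"r{i}")
            labels.append(k)
        res = profiles.cluster_profiles(self.make_matrix(rows, ids), k=3)
        groups = {}
        for rid, lab in res.assignment.items():
            groups.setdefault(lab, set()).add(int(rid[1:]) % 3)
        assert all(len(v) == 1 for v in groups.values())  # clusters == templates

    def test_scaling_and_shifting_invariance(self):
        rng = np.random.default_rng(1)
        rows = [rng.random(21) for _ in range(8)]
        ids = [f"r{i}" for i in range(8)]
        res_a = profiles.cluster_profiles(self.make_matrix(rows, ids), k=2)
        scaled = [3.0 * r + 5.0 for r in rows]
        res_b = profiles.cluster_profiles(self.make_matrix(scaled, ids), k=2)
        assert res_a.assignment == res_b.assignment

    def test_zero_variance_rows_dropped(self):
        rng = np.random.default_rng(2)
        rows = [rng.random(21) for _ in range(6)] + [np.full(21, 2.0)]
        ids = [f"r{i}" for i in range(7)]
        res = profiles.cluster_profiles(self.make_matrix(rows, ids), k=2)
        assert res.dropped == ["r6"]

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(3)
        rows = [rng.random(21) for _ in range(3)]
        with pytest.raises(ValueError):
            profiles.cluster_profiles(self.make_matrix(rows, ["a", "b", "c"]), k=6)

    def test_planted_density_classes_recovered(self):
        """4/5/6-nucleosome TSS profile classes separate with ARI >= 0.9."""
        from sklearn.metrics import adjusted_rand_score
        from tetramap import smoothing

        b = simulate(SimulationConfig(seed=3, profile_classes=(4, 5, 6)))
        sm = smoothing.convolve(b.mnase, smoothing.gaussian_kernel(27))
        spans = expected_refined_spans(b.truth_units)
        ids = [f"op{r.operon}" for r in spans.itertuples()]
        units = [
            TranscriptUnit("chr", r.start, r.end, r.strand, "confirmed", tuple(r.member_ids))
            for r in spans.itertuples()
        ]
        mat = profiles.anchored_matrix(sm, units, "tss", ids=ids)
        res = profiles.cluster_profiles(mat, k=3)
        res_again = profiles.cluster_profiles(mat, k=3)
        assert res.assignment == res_again.assignment  # deterministic
        tcls = b.truth_units.groupby("operon").profile_class.first().to_dict()
        kept = [i for i, lab in res.assignment.items() if lab > 0]
        truth = [tcls[int(i[2:])] for i in kept]
        pred = [res.assignment[i] for i in kept]
        assert adjusted_rand_score(truth, pred) >= 0.9


class TestExport:
    def test_leaf_order_round_trip_and_contiguity(self, tmp_path):
        rng = np.random.default_rng(4)
        offs = np.arange(-5, 6)
        base = [np.sin(offs / 2.0), np.cos(offs / 2.0)]
        rows = [base[i % 2] + rng.normal(0, 0.05, 11) for i in range(10)]
        ids = [f"r{i}" for i in range(10)]
        mat = profiles.ProfileMatrix("tss", 5, pd.DataFrame(rows, index=ids, columns=offs))
        res = profiles.cluster_profiles(mat, k=2)
        mpath, apath = tmp_path / "m.tsv", tmp_path / "a.tsv"
        profiles.export_heatmap_tables(mat, res, mpath, apath)
        assert sorted(res.leaf_order) == sorted(ids)  # a permutation of all rows
        again = pd.read_csv(mpath, sep="\t", index_col=0)
        np.testing.assert_allclose(again.to_numpy(), mat.data.loc[res.leaf_order].to_numpy())
        assign = pd.read_csv(apath, sep="\t")
        # subclades are contiguous blocks in dendrogram leaf order
        labs = assign["subclade"].tolist()
        seen = set()
        prev = None
        for lab in labs:
            if lab != prev:
                assert lab not in seen
                seen.add(lab)
            prev = lab
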
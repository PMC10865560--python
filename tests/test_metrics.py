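import numpy as np
import pytest

import perisinus as ps
from perisinus.postprocess import AGInstanceStats, RegionBoundaries


class TestOverlapMetrics:
    def test_identity_and_disjoint(self, rng):
        a = rng.random((6, 6, 6)) < 0.4
        assert ps.dsc(a, a) == 100.0
        b = np.zeros_like(a)
        b[0, 0, 0] = True
        a2 = np.zeros_like(a)
        a2[5, 5, 5] = True
        assert ps.dsc(a2, b) == 0.0

    def test_hand_counts(self):
        a = np.zeros((2, 2, 2), dtype=bool)
        b = np.zeros((2, 2, 2), dtype=bool)
        a.ravel()[:4] = True
        b.ravel()[2:4] = True
        assert ps.dsc(a, b) == pytest.approx(200 * 2 / 6)
        # TP=2, FN=2, FP=0 seen from a truth of 4 with prediction b
        assert ps.recall(b, a) == pytest.approx(50.0)
        assert ps.precision(b, a) == pytest.approx(100.0)

    def test_subset_geometry(self, rng):
        truth = rng.random((5, 5, 5)) < 0.5
        pred = truth.copy()
        pred[np.argwhere(truth)[0][0]] = False   # strict subset
        pred_sub = truth & pred
        assert ps.precision(pred_sub, truth) == 100.0
        assert ps.recall(pred_sub, truth) < 100.0

    def test_empty_conventions(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        o = ~z
        assert ps.dsc(z, z) == 100.0
        assert ps.recall(z, z) == 100.0 and ps.precision(z, z) == 100.0
        assert ps.recall(o, z) == 0.0 and ps.precision(z, o) == 0.0

    def test_brute_force_oracle_and_identities(self, rng):
        """Set-count oracle on random grids + DSC = 2PR/(P+R) + symmetry."""
        for _ in range(200):
            a = rng.random((8, 8, 8)) < rng.uniform(0.1, 0.9)
            b = rng.random((8, 8, 8)) < rng.uniform(0.1, 0.9)
            tp = int((a & b).sum())
            d = ps.dsc(a, b)
            assert d == pytest.approx(
                100.0 if a.sum() + b.sum() == 0
                else 200 * tp / (int(a.sum()) + int(b.sum())), abs=1e-9)
            assert d == pytest.approx(ps.dsc(b, a), abs=1e-12)
            assert ps.recall(a, b) == pytest.approx(ps.precision(b, a), abs=1e-12)
            p = ps.precision(a, b) / 100
            r = ps.recall(a, b) / 100
            if p + r > 0:
                assert d / 100 == pytest.approx(2 * p * r / (p + r), abs=1e-9)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            ps.dsc(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestVolumeAgreement:
    def test_identity_and_shift(self):
        v = [1.0, 2.0, 3.0, 4.0]
        rms, r, p = ps.volume_agreement(v, v)
        assert rms == 0.0 and r == pytest.approx(1.0)
        rms, r, _ = ps.volume_agreement(np.add(v, 2.0), v)
        assert rms == pytest.approx(2.0) and r == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        rms, r, _ = ps.volume_agreement([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)
        assert rms == pytest.approx(np.sqrt(8 / 3))

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning):
            _, r, p = ps.volume_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)


class TestAGAgreement:
    def _stats(self, vols):
        vols = np.asarray(vols, dtype=float)
        if vols.size == 0:
            return AGInstanceStats.empty()
        return AGInstanceStats(len(vols), vols.sum(), vols.mean(),
                               vols.max(), vols.min(),
                               [(1, v, (0, 0, 0)) for v in vols])

    def test_identity(self, rng):
        stats = [self._stats(rng.uniform(2, 40, rng.integers(1, 6)))
                 for _ in range(8)]
        table = ps.ag_metric_agreement(stats, stats)
        assert np.allclose(table["rms"], 0.0)
        assert np.allclose(table["pearson_r"], 1.0)

    def test_known_noise_rms(self):
        rng = np.random.default_rng(0)
        sigma = 3.0
        ref = [self._stats([rng.uniform(10, 60)]) for _ in range(400)]
        est = [self._stats([r.total_volume + rng.normal(0, sigma)])
               for r in ref]
        table = ps.ag_metric_agreement(est, ref)
        se = sigma / np.sqrt(2 * 400)
        assert abs(table.loc["total", "rms"] - sigma) < 3 * se * 2

    def test_count_in_occurrence_units(self):
        a = [self._stats([5.0] * 3), self._stats([5.0] * 7), self._stats([5.0])]
        b = [self._stats([5.0] * 4), self._stats([5.0] * 7), self._stats([5.0])]
        table = ps.ag_metric_agreement(a, b)
        assert table.loc["count", "unit"] == "occurrences"
        assert table.loc["count", "rms"] == pytest.approx(np.sqrt(1 / 3))

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            ps.ag_metric_agreement([AGInstanceStats.empty()], [])


class TestFolds:
    def test_sizes_disjoint_and_coverage(self):
        ids = [f"s{i:02d}" for i in range(80)]
        plan = ps.make_folds(ids, seed=3)
        assert plan.n_folds == 8
        covered = set()
        for f in plan.folds:
            assert (len(f["train"]), len(f["val"]), len(f["test"])) == (60, 10, 10)
            assert not (set(f["train"]) & set(f["val"]))
            assert not (set(f["train"]) & set(f["test"]))
            assert not (set(f["val"]) & set(f["test"]))
            covered |= set(f["test"])
        assert covered == set(ids)

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(80)]
        assert ps.make_folds(ids, seed=7).folds == ps.make_folds(ids, seed=7).folds

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            ps.make_folds(list(range(50)))


class TestEvaluateCohort:
    def _labelmaps(self, datas):
        out = {}
        for i, d in enumerate(datas):
            aff = np.diag([1.0, 1.0, 1.0, 1.0])
            aff[:3, 3] = -np.array(d.shape) / 2 + 0.5
            out[f"s{i}"] = ps.LabelMap(d.astype(np.int16), (1, 1, 1), aff,
                                       "template")
        return out

    def test_perfect_predictions_all_100(self, rng):
        datas = [rng.integers(0, 4, (8, 8, 8)) for _ in range(4)]
        labs = self._labelmaps(datas)
        table = ps.evaluate_cohort(labs, labs)
        assert np.allclose(table["dsc_mean"], 100.0)
        assert np.allclose(table["dsc_sd"], 0.0)

    def test_single_subject_zero_sd(self, rng):
        labs = self._labelmaps([rng.integers(0, 4, (6, 6, 6))])
        table = ps.evaluate_cohort(labs, labs)
        assert np.allclose(table["dsc_sd"], 0.0)

    def test_empty_region_dropped(self):
        d = np.zeros((8, 8, 8), dtype=int)
        d[:, 6:, :] = 2       # only anterior voxels
        labs = self._labelmaps([d, d, d])
        b = RegionBoundaries(0.0, -2.0)
        table = ps.evaluate_cohort(labs, labs, boundaries=b)
        psd = table[table.structure == "psd"]
        assert "occipital" not in set(psd.region)
        # AG absent everywhere -> structure dropped entirely
        assert "ag" not in set(table.structure)

    def test_missing_pairs_rejected(self, rng):
        labs = self._labelmaps([rng.integers(0, 4, (4, 4, 4))])
        with pytest.raises(ValueError):
            ps.evaluate_cohort(labs, {})

    def test_per_source_breakdown(self, rng):
        datas = [rng.integers(0, 4, (6, 6, 6)) for _ in range(4)]
        labs = self._labelmaps(datas)
        sources = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        table = ps.evaluate_cohort(labs, labs, sources=sources)
        assert {"all", "A", "B"} <= set(table.group)
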
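import numpy as np
import pytest

from asymmorph import (
    AsymmetrySpec,
    apply_asymmetry,
    drop_region,
    gpa,
    group_summary,
    make_dataset,
    pca,
    quantify,
    radii,
    region_fraction,
    specimen_sum,
)
from asymmorph.geometry import centroid_size
from asymmorph.metrics import MetricsError, radii_frame
from asymmorph.io import SchemeError
from asymmorph.synthetic import affected_landmarks


class TestRadii:
    def test_identical_inputs_zero(self):
        coords = np.random.default_rng(0).normal(size=(10, 3))
        recs = radii(coords, coords, "A")
        assert all(r.rho == 0.0 for r in recs)
        assert all(np.isnan(r.phi) for r in recs)

    def test_axis_aligned_displacement(self):
        fn = np.zeros((3, 3))
        rn = np.zeros((3, 3))
        fn[1] = [0.03, 0.0, 0.0]
        recs = radii(fn, rn, "A")
        assert recs[1].rho == pytest.approx(0.03)
        assert recs[1].phi == pytest.approx(0.0)
        assert recs[1].theta == pytest.approx(np.pi / 2)

    def test_frame_mismatch_rejected(self):
        with pytest.raises(MetricsError, match="mismatch"):
            radii(np.zeros((3, 3)), np.zeros((4, 3)), "A")

    def test_record_count_scales(self):
        ds = make_dataset(4, seed=0)
        res = quantify(ds)
        assert len(res["records"]) == 4 * 123


class TestSpecimenSum:
    def test_zero_radii(self):
        recs = radii(np.zeros((5, 3)), np.zeros((5, 3)), "A")
        assert specimen_sum(recs)["A"] == 0.0

    def test_simple_sum(self):
        fn = np.zeros((2, 3))
        fn[0, 0] = 0.1
        fn[1, 1] = 0.2
        recs = radii(fn, np.zeros((2, 3)), "A")
        assert specimen_sum(recs)["A"] == pytest.approx(0.3)

    def test_invariant_to_landmark_permutation(self, asym_dataset):
        res = quantify(asym_dataset)
        sums = specimen_sum(res["records"])
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(res["records"]))
        shuffled = [res["records"][i] for i in perm]
        assert specimen_sum(shuffled) == pytest.approx(sums)

    def test_exclude_estimated_switch(self):
        from asymmorph.metrics import RadiiRecord

        recs = [
            RadiiRecord("A", 0, 0.1, 0.0, 0.0, estimated=False),
            RadiiRecord("A", 1, 0.2, 0.0, 0.0, estimated=True),
        ]
        assert specimen_sum(recs)["A"] == pytest.approx(0.3)
        assert specimen_sum(recs, include_estimated=False)["A"] == pytest.approx(0.1)


class TestGroupSummary:
    def test_singleton_group(self, asym_dataset):
        res = quantify(asym_dataset)
        sums = res["sums"]
        ids = sorted(sums)
        groups = {sid: (f"g{i}" if i == 0 else "rest") for i, sid in enumerate(ids)}
        out = group_summary(res["records"], groups)
        assert out["mean_total"]["g0"] == pytest.approx(sums[ids[0]])

    def test_mean_per_landmark_oracle(self):
        rng = np.random.default_rng(1)
        fn = {sid: rng.normal(size=(4, 3)) * 0.01 for sid in "ABC"}
        recs = []
        for sid in "ABC":
            recs += radii(fn[sid], np.zeros((4, 3)), sid)
        groups = {"A": "g", "B": "g", "C": "g"}
        out = group_summary(recs, groups)
        for lm in range(4):
            oracle = np.mean([np.linalg.norm(fn[sid][lm]) for sid in "ABC"])
            assert out["mean_per_landmark"].loc["g", lm + 1] == pytest.approx(oracle)

    def test_ranking_descending_stable_ties(self):
        from asymmorph.metrics import RadiiRecord

        recs = [
            RadiiRecord("b", 0, 0.5, 0, 0),
            RadiiRecord("a", 0, 0.5, 0, 0),
            RadiiRecord("c", 0, 0.9, 0, 0),
        ]
        out = group_summary(recs, {"a": "g", "b": "g", "c": "g"})
        assert out["full_ranking"]["specimen_id"].tolist() == ["c", "a", "b"]

    def test_unlabelled_specimen_rejected(self):
        from asymmorph.metrics import RadiiRecord

        recs = [RadiiRecord("A", 0, 0.1, 0, 0)]
        with pytest.raises(MetricsError, match="without a group"):
            group_summary(recs, {})


class TestRegionFraction:
    def test_all_in_region(self, scheme):
        from asymmorph.metrics import RadiiRecord

        rostral = scheme.region_indices("rostrum")
        recs = [RadiiRecord("A", i, 0.1 if i in rostral else 0.0, 0, 0) for i in range(123)]
        assert region_fraction(recs, scheme, "rostrum")["A"] == pytest.approx(100.0)

    def test_uniform_rho_closed_form(self, scheme):
        from asymmorph.metrics import RadiiRecord

        recs = [RadiiRecord("A", i, 0.01, 0, 0) for i in range(123)]
        n_rostral = len(scheme.region_indices("rostrum"))
        expected = 100.0 * n_rostral / 123
        assert region_fraction(recs, scheme, "rostrum")["A"] == pytest.approx(expected)

    def test_zero_total_is_nan(self, scheme):
        from asymmorph.metrics import RadiiRecord

        recs = [RadiiRecord("A", i, 0.0, 0, 0) for i in range(123)]
        assert np.isnan(region_fraction(recs, scheme, "rostrum")["A"])

    def test_unknown_region_rejected(self, scheme):
        with pytest.raises(SchemeError, match="unknown region"):
            region_fraction([], scheme, "wings")

    def test_planted_nasal_dominates(self, asym_dataset):
        res = quantify(asym_dataset)
        nasal = region_fraction(res["records"], asym_dataset.scheme, "nasal")
        for region in ("rostrum", "maxilla", "jugal", "posterior"):
            other = region_fraction(res["records"], asym_dataset.scheme, region)
            for sid in nasal:
                assert nasal[sid] > other[sid]


class TestDropRegion:
    def test_count_conservation(self, asym_dataset):
        scheme = asym_dataset.scheme
        region = "jugal"
        idx = scheme.region_indices(region)
        p = sum(1 for i in idx if i in scheme.left_indices)
        m = sum(1 for i in idx if i in scheme.midline)
        reduced = drop_region(asym_dataset, region)
        assert reduced.scheme.n_total == scheme.n_total - 2 * p - m
        assert reduced.configurations[0].n_landmarks == reduced.scheme.n_total

    def test_structure_revalidated(self, asym_dataset):
        reduced = drop_region(asym_dataset, "rostrum")
        s = reduced.scheme
        covered = set()
        for l, r in s.pairs:
            covered |= {l, r}
        covered |= set(s.midline)
        assert covered == set(range(s.n_total))

    def test_one_sided_region_rejected(self, asym_dataset):
        ds = asym_dataset
        scheme = ds.scheme
        l, r = scheme.pairs[0]
        bad_regions = dict(scheme.regions)
        bad_regions[l] = "lopsided"
        from asymmorph import LandmarkScheme, LandmarkDataset

        bad_scheme = LandmarkScheme(scheme.n_total, scheme.pairs, scheme.midline, bad_regions)
        bad_ds = LandmarkDataset(bad_scheme, [c.copy() for c in ds.configurations])
        with pytest.raises(SchemeError, match="partner"):
            drop_region(bad_ds, "lopsided")

    def test_drop_reduces_sum(self, asym_dataset):
        res_full = quantify(asym_dataset)
        reduced = drop_region(asym_dataset, "nasal")
        res_red = quantify(reduced)
        sid = asym_dataset.configurations[0].specimen_id
        # planted asymmetry was all nasal, so the reduced sum collapses
        assert res_red["sums"][sid] < 0.05 * res_full["sums"][sid]


class TestPca:
    def test_variance_proportions_sum_to_one(self, asym_dataset):
        res = quantify(asym_dataset)
        rng = np.random.default_rng(0)
        aligned = res["aligned"]
        aligned.coords = aligned.coords + rng.normal(0, 1e-4, aligned.coords.shape)
        out = pca(aligned)
        assert out.proportion_variance.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigen_oracle(self, template):
        from asymmorph import LandmarkConfiguration

        rng = np.random.default_rng(5)
        configs = [
            LandmarkConfiguration(
                f"s{i}", template.coords + rng.normal(0, 3, template.coords.shape),
                np.zeros(template.n_landmarks, bool),
            )
            for i in range(5)
        ]
        aligned = gpa(configs)
        out = pca(aligned)
        X = aligned.coords.reshape(5, -1)
        Xc = X - X.mean(axis=0)
        w, v = np.linalg.eigh(Xc @ Xc.T)
        oracle_var = np.sort(w)[::-1]
        oracle_var = oracle_var / oracle_var.sum()
        assert np.allclose(out.proportion_variance[: len(oracle_var)], oracle_var, atol=1e-10)
        # scores match gram-matrix oracle up to sign
        for j in range(3):
            s = out.scores[:, j]
            o = v[:, np.argsort(w)[::-1][j]] * np.sqrt(np.sort(w)[::-1][j])
            assert min(np.abs(s - o).max(), np.abs(s + o).max()) < 1e-8

    def test_duplicated_specimens_keep_proportions(self, asym_dataset):
        res = quantify(asym_dataset)
        aligned = res["aligned"]
        rng = np.random.default_rng(1)
        aligned.coords = aligned.coords + rng.normal(0, 1e-4, aligned.coords.shape)
        out1 = pca(aligned)
        import copy

        doubled = copy.deepcopy(aligned)
        doubled.specimen_ids = aligned.specimen_ids + [f"{s}_b" for s in aligned.specimen_ids]
        doubled.coords = np.vstack([aligned.coords, aligned.coords])
        out2 = pca(doubled)
        k = min(4, len(out1.proportion_variance) - 1)
        assert np.allclose(
            out1.proportion_variance[:k], out2.proportion_variance[:k], atol=1e-8
        )

    def test_constant_data_handled(self, template):
        aligned = gpa([template.copy() for _ in range(3)])
        for i, c in enumerate(aligned.specimen_ids):
            aligned.specimen_ids[i] = f"s{i}"
        out = pca(aligned)
        assert np.isfinite(out.proportion_variance).all()


class TestPlantedSignalProperties:
    def test_rho_equals_delta_over_size(self, template, scheme):
        spec = AsymmetrySpec(regions=("nasal",), magnitude=2.0, side="right")
        cfg = apply_asymmetry(template.copy(), spec, scheme)
        s = centroid_size(cfg.coords)
        ds = make_dataset(3, asymmetry=spec, seed=0)
        res = quantify(ds)
        affected = set(affected_landmarks(spec, scheme))
        for r in res["records"]:
            if r.landmark_index in affected:
                assert r.rho == pytest.approx(2.0 / s, rel=0.01)

    def test_sum_monotone_in_magnitude(self):
        sums = []
        for mag in (1.0, 2.0, 4.0):
            ds = make_dataset(2, asymmetry=AsymmetrySpec(magnitude=mag), seed=4)
            res = quantify(ds)
            sums.append(next(iter(res["sums"].values())))
        assert sums[0] < sums[1] < sums[2]
        assert sums[1] / sums[0] == pytest.approx(2.0, rel=0.02)
        assert sums[2] / sums[1] == pytest.approx(2.0, rel=0.02)
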
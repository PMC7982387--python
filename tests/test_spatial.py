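"""Mantel/partial Mantel, PCoA, PCoA regression and the sliding-window resampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rhizogeo as rg
from rhizogeo.errors import StrainMismatchError
from rhizogeo.spatial import PCoAResult, decay_spearman

from conftest import euclidean_dm


def _random_dm(rng, n, level="trait"):
    pts = rng.normal(size=(n, 3))
    return euclidean_dm(pts, level)


class TestMantel:
    def test_self_correlation_r_one_p_floor(self):
        rng = np.random.default_rng(1)
        x = _random_dm(rng, 10)
        res = rg.mantel(x, x, n_perm=99, seed=2)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_r_equals_hand_computed_pearson(self):
        rng = np.random.default_rng(4)
        x, y = _random_dm(rng, 4), _random_dm(rng, 4)
        res = rg.mantel(x, y, n_perm=9, seed=0)
        il = np.tril_indices(4, -1)
        expected = np.corrcoef(x.values[il], y.values[il])[0, 1]
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_r_matches_scikit_bio(self):
        """Cross-check the statistic against an independent implementation."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        x, y = _random_dm(rng, 12), _random_dm(rng, 12)
        ours = rg.mantel(x, y, n_perm=9, seed=0)
        sk_x = skbio_distance.DistanceMatrix(x.values, list(x.labels))
        sk_y = skbio_distance.DistanceMatrix(y.values, list(y.labels))
        r_sk, _, _ = skbio_distance.mantel(sk_x, sk_y, permutations=0)
        assert ours.r == pytest.approx(float(r_sk), abs=1e-10)

    def test_label_mismatch_error(self):
        rng = np.random.default_rng(5)
        x = _random_dm(rng, 5)
        y = rg.DistanceMatrix([f"q{i}" for i in range(5)], x.values, "trait")
        with pytest.raises(StrainMismatchError):
            rg.mantel(x, y, n_perm=9)

    def test_zero_variance_error(self):
        flat = rg.DistanceMatrix(["a", "b", "c"], 1 - np.eye(3), "species")
        rng = np.random.default_rng(5)
        other = rg.DistanceMatrix(["a", "b", "c"], _random_dm(rng, 3).values, "trait")
        with pytest.raises(ValueError, match="variance"):
            rg.mantel(flat, other, n_perm=9)

    def test_invariant_under_common_relabeling(self):
        rng = np.random.default_rng(6)
        x, y = _random_dm(rng, 8), _random_dm(rng, 8)
        perm = rng.permutation(8)
        order = [x.labels[i] for i in perm]
        r1 = rg.mantel(x, y, n_perm=99, seed=3).r
        r2 = rg.mantel(x.reorder(order), y.reorder(order), n_perm=99, seed=3).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(7)
        x, y = _random_dm(rng, 9), _random_dm(rng, 9)
        p1 = rg.mantel(x, y, n_perm=199, seed=42).p
        p2 = rg.mantel(x, y, n_perm=199, seed=42).p
        assert p1 == p2


class TestPartialMantel:
    def test_reduces_to_simple_when_covariate_orthogonal(self):
        """Constructed z triangle exactly orthogonal to x and y triangles."""
        rng = np.random.default_rng(11)
        n = 6
        x, y = _random_dm(rng, n), _random_dm(rng, n)
        il = np.tril_indices(n, -1)
        xv, yv = x.values[il], y.values[il]
        basis = np.stack([np.ones_like(xv), xv - xv.mean(), yv - yv.mean()])
        v = rng.normal(size=xv.size)
        # project out constant, x and y components -> r_xz = r_yz = 0 exactly
        q, _ = np.linalg.qr(basis.T)
        v = v - q @ (q.T @ v)
        zv = 1.0 + 0.1 * v / np.abs(v).max()
        zmat = np.zeros((n, n))
        zmat[il] = zv
        zmat = zmat + zmat.T
        z = rg.DistanceMatrix(x.labels, zmat, "trait")
        simple = rg.mantel(x, y, n_perm=9, seed=0).r
        partial = rg.partial_mantel(x, y, z, n_perm=9, seed=0).r
        assert partial == pytest.approx(simple, abs=1e-10)

    def test_identical_y_and_z_gives_zero(self):
        rng = np.random.default_rng(12)
        x, y = _random_dm(rng, 7), _random_dm(rng, 7)
        res = rg.partial_mantel(x, y, y, n_perm=9, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_covariate_rejected(self):
        rng = np.random.default_rng(13)
        x, y = _random_dm(rng, 6), _random_dm(rng, 6)
        with pytest.raises(ValueError):
            rg.partial_mantel(x, y, x, n_perm=9, seed=0)  # r_xz = 1

    def test_confounder_removed(self):
        """x and y both driven by z: partial r collapses relative to simple r."""
        rng = np.random.default_rng(14)
        simple_rs, partial_rs = [], []
        for _ in range(100):
            n = 12
            z_pos = rng.uniform(0, 10, size=(n, 1))
            x = euclidean_dm(z_pos + rng.normal(scale=0.4, size=(n, 1)))
            y = euclidean_dm(z_pos + rng.normal(scale=0.4, size=(n, 1)))
            z = euclidean_dm(z_pos)
            simple_rs.append(abs(rg.mantel(x, y, n_perm=1, seed=0).r))
            partial_rs.append(abs(rg.partial_mantel(x, y, z, n_perm=1, seed=0).r))
        assert np.mean(partial_rs) < np.mean(simple_rs)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        dm = euclidean_dm(np.array([[0.0], [1.0], [2.0]]))
        res = rg.pcoa(dm)
        assert (res.eigenvalues > 1e-10).sum() == 1
        coords = res.coordinates
        recon = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        np.testing.assert_allclose(recon, dm.values, atol=1e-10)

    def test_euclidean_reconstruction_2d(self):
        rng = np.random.default_rng(20)
        pts = rng.normal(size=(10, 2))
        dm = euclidean_dm(pts)
        res = rg.pcoa(dm, n_axes=2)
        c = res.coordinates
        recon = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
        np.testing.assert_allclose(recon, dm.values, atol=1e-8)

    def test_regular_simplex_equal_eigenvalues(self):
        n = 5
        dm = rg.DistanceMatrix([f"p{i}" for i in range(n)], 1.0 - np.eye(n), "species")
        res = rg.pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert pos.size == n - 1
        np.testing.assert_allclose(pos, pos[0], atol=1e-10)

    def test_eigenvalues_sorted_and_proportions(self):
        rng = np.random.default_rng(21)
        dm = euclidean_dm(rng.normal(size=(8, 3)))
        res = rg.pcoa(dm)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_matches_scikit_bio_embedding(self, default_dataset):
        skbio_mod = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix as SkDM

        dm = rg.p_distance_matrix(default_dataset.mla.concatenated)
        ours = rg.pcoa(dm, n_axes=2)
        theirs = skbio_mod.pcoa(SkDM(dm.values, list(dm.labels)), number_of_dimensions=2)
        for k in range(2):
            a = ours.coordinates[:, k]
            b = theirs.samples[f"PC{k + 1}"].to_numpy()
            # axes defined up to sign
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_truncation_warning(self):
        dm = euclidean_dm(np.array([[0.0], [1.0], [2.0]]))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = rg.pcoa(dm, n_axes=2)
        assert res.coordinates.shape[1] == 1


class TestPCoARegression:
    def _geo(self, rng, n=20):
        return rg.pcoa(euclidean_dm(rng.uniform(0, 100, size=(n, 2))), n_axes=2)

    def test_exact_copy_axis(self):
        rng = np.random.default_rng(30)
        geo = self._geo(rng)
        genetic = PCoAResult(
            labels=geo.labels,
            coordinates=geo.coordinates[:, :1].copy(),
            eigenvalues=np.array([1.0]),
            proportion_explained=np.array([1.0]),
            negative_eigenvalues=np.array([]),
        )
        alt = {l: float(v) for l, v in zip(geo.labels, rng.normal(size=20))}
        table = rg.pcoa_regression(genetic, geo, alt, n_genetic_axes=1)
        assert table["r_squared"].iloc[0] == pytest.approx(1.0)
        alt_row = table[table["term"] == "altitude"].iloc[0]
        assert alt_row["F"] == pytest.approx(0.0, abs=1e-6)

    def test_rank_deficient_design_error(self):
        rng = np.random.default_rng(31)
        geo = self._geo(rng)
        # altitude an exact copy of geo1 -> collinear design
        alt = {l: float(v) for l, v in zip(geo.labels, geo.coordinates[:, 0])}
        genetic = self._geo(rng)
        with pytest.raises(ValueError, match="rank"):
            rg.pcoa_regression(genetic, geo, alt, n_genetic_axes=1)

    def test_matches_statsmodels_sequential_anova(self):
        """Per-term F values equal statsmodels' own anova_lm(typ=1)."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(32)
        geo = self._geo(rng)
        genetic = self._geo(rng)
        alt = {l: float(v) for l, v in zip(geo.labels, rng.normal(size=20))}
        table = rg.pcoa_regression(genetic, geo, alt, n_genetic_axes=1)
        df = pd.DataFrame(
            {
                "y": genetic.coordinates[:, 0],
                "geo1": geo.coordinates[:, 0],
                "geo2": geo.coordinates[:, 1],
                "altitude": [alt[l] for l in geo.labels],
            }
        )
        fit = smf.ols("y ~ geo1 + geo2 + altitude", data=df).fit()
        ref = anova_lm(fit, typ=1)
        for term in ("geo1", "geo2", "altitude"):
            ours = table[table["term"] == term]["F"].iloc[0]
            assert ours == pytest.approx(ref.loc[term, "F"], rel=1e-8)

    def test_altitude_signal_detected(self, default_dataset):
        """The high-elevation genospecies creates an altitude association."""
        ds = default_dataset
        order = list(ds.mla.strain_ids)
        nt = rg.p_distance_matrix(ds.mla.concatenated)
        geo = rg.geographic_distance_matrix(ds.metadata).reorder(order)
        alt = ds.metadata.set_index("strain")["elevation_m"]
        table = rg.pcoa_regression(rg.pcoa(nt), rg.pcoa(geo), alt, n_genetic_axes=2)
        assert (table[table["term"] == "altitude"]["p"] < 0.05).any()


class TestSlidingWindow:
    def _dataset_matrices(self, ds):
        order = list(ds.mla.strain_ids)
        nt = rg.p_distance_matrix(ds.mla.concatenated)
        hap = rg.allele_sharing_distance(rg.call_haplotypes(ds.mla))
        geo = rg.geographic_distance_matrix(ds.metadata).reorder(order)
        return nt, hap, geo

    def test_all_strains_one_point_single_window(self):
        labels = ["a", "b", "c"]
        geo = rg.DistanceMatrix(labels, np.zeros((3, 3)), "geographic_km")
        rng = np.random.default_rng(3)
        gen = euclidean_dm(rng.normal(size=(3, 2)))
        gen = rg.DistanceMatrix(labels, gen.values, "nucleotide")
        hap = rg.DistanceMatrix(labels, gen.values, "haplotype")
        prof = rg.sliding_window_decay(gen, hap, geo, seed=1)
        assert len(prof.windows) == 1
        assert prof.windows["n_eligible"].iloc[0] == 3
        assert len(prof.baseline) == 1

    def test_empty_windows_recorded_not_dropped(self):
        # two tight clusters 200 km apart -> middle windows empty
        lat = [0.0, 0.001, 1.8, 1.801]
        labels = [f"s{i}" for i in range(4)]
        meta = pd.DataFrame(
            {"strain": labels, "latitude": lat, "longitude": [0.0] * 4}
        )
        geo = rg.geographic_distance_matrix(meta)
        rng = np.random.default_rng(4)
        base = euclidean_dm(rng.normal(size=(4, 2)))
        gen = rg.DistanceMatrix(labels, base.values, "nucleotide")
        prof = rg.sliding_window_decay(gen, gen, geo, seed=2)
        assert prof.windows["nt_distance"].isna().any()
        assert (prof.windows["n_eligible"] == 0).any()
        sampled = prof.windows.dropna(subset=["nt_distance"])
        # each sampled pair truly lies inside its window
        for _, row in sampled.iterrows():
            d = geo[(row["strain_a"], row["strain_b"])]
            assert row["window_low"] <= d < row["window_high"]

    def test_bit_reproducible_with_seed(self, default_dataset):
        nt, hap, geo = self._dataset_matrices(default_dataset)
        p1 = rg.sliding_window_decay(nt, hap, geo, seed=99)
        p2 = rg.sliding_window_decay(nt, hap, geo, seed=99)
        pd.testing.assert_frame_equal(p1.windows, p2.windows)
        pd.testing.assert_frame_equal(p1.baseline, p2.baseline)

    def test_exhaustive_mode_uses_all_pairs(self, default_dataset):
        nt, hap, geo = self._dataset_matrices(default_dataset)
        prof = rg.sliding_window_decay(nt, hap, geo, seed=1, exhaustive=True)
        row = prof.windows.dropna(subset=["nt_distance"]).iloc[0]
        il = np.tril_indices(len(geo), -1)
        geo_v, nt_v = geo.values[il], nt.values[il]
        mask = (geo_v >= row["window_low"]) & (geo_v < row["window_high"])
        assert row["nt_distance"] == pytest.approx(nt_v[mask].mean())

    def test_profile_tsv_round_trip(self, tmp_path, default_dataset):
        nt, hap, geo = self._dataset_matrices(default_dataset)
        prof = rg.sliding_window_decay(nt, hap, geo, seed=7)
        out = tmp_path / "window.tsv"
        prof.to_tsv(out)
        back = pd.read_csv(out, sep="\t")
        assert {"window_low", "window_high", "midpoint", "nt_distance",
                "hap_distance", "baseline_nt", "baseline_hap"} <= set(back.columns)
        assert len(back) == len(prof.windows)

    def test_decay_positive_on_ibd_dataset(self, default_dataset):
        nt, hap, geo = self._dataset_matrices(default_dataset)
        prof = rg.sliding_window_decay(nt, hap, geo, seed=10, exhaustive=True)
        assert decay_spearman(prof) > 0
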
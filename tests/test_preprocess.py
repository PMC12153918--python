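import numpy as np
import pandas as pd
import pytest
from scipy import stats

import milkfa
from milkfa.preprocess import ReferenceProjection
from milkfa.reference import FA_TRAITS


def _record(fa=0.4, fat=4.0, protein=3.4, **over):
    row = {t: fa for t in FA_TRAITS}
    row.update(
        fat=fat, protein=protein, milk_yield=25.0, energy_balance=-3.0,
        nitrogen_efficiency=50.0, blood_bhb=-0.8, blood_ffa=500.0, dmi=22.0,
        unit_basis="milk_basis", herd_id="H1", date="2021-01-01",
    )
    row.update(over)
    return pd.DataFrame([row])


class TestConversion:
    def test_ratio_arithmetic(self):
        out = milkfa.convert_to_fat_basis(_record(fa=0.40, fat=4.0))
        assert out["C4"].iloc[0] == pytest.approx(10.0)
        assert out["fat"].iloc[0] == 4.0  # fat itself unchanged

    def test_zero_fa_stays_zero(self):
        out = milkfa.convert_to_fat_basis(_record(fa=0.0, fat=2.0))
        assert (out[list(FA_TRAITS)] == 0).all(axis=None)

    def test_double_conversion_rejected(self):
        out = milkfa.convert_to_fat_basis(_record())
        with pytest.raises(ValueError, match="already"):
            milkfa.convert_to_fat_basis(out)

    def test_nonpositive_fat_rejected(self):
        with pytest.raises(ValueError, match="non-positive fat"):
            milkfa.convert_to_fat_basis(_record(fat=0.0))


class TestCleaning:
    @pytest.mark.parametrize(
        "over, reason",
        [
            ({"fat": 1.4}, "fat_bound"),
            ({"fat": 9.5}, "fat_bound"),
            ({"protein": 0.5}, "protein_bound"),
            ({"C16": -0.1}, "negative_fa"),
            ({"C16": np.nan}, "missing"),
            ({"fat": np.nan}, "missing"),
        ],
    )
    def test_rejection_reasons(self, over, reason):
        kept, log = milkfa.clean_records(_record(**over))
        assert kept.empty
        assert list(log["reason"]) == [reason]

    def test_first_failing_rule_precedence(self):
        kept, log = milkfa.clean_records(_record(fat=1.0, C16=-0.2))
        assert list(log["reason"]) == ["fat_bound"]

    def test_clean_input_passes_untouched(self, small_population):
        records, _ = small_population
        kept, log = milkfa.clean_records(records)
        pd.testing.assert_frame_equal(kept, records)
        assert log.empty

    def test_kept_plus_rejected_conserves_rows(self, small_population):
        """The cleaning ledger matches the generator's perturbation log."""
        records, _ = small_population
        rates = {"out_of_range": 0.04, "negative_fa": 0.03, "missing": 0.03}
        dirty, plog = milkfa.inject_artifacts(records, rates, seed=8)
        kept, rej = milkfa.clean_records(dirty)
        assert len(kept) + len(rej) == len(records)
        touched = set(plog["row"])
        assert set(rej.index) == touched
        assert set(kept.index) == set(records.index) - touched


class TestReferenceProjection:
    def test_constructed_rank_two_gives_two_components(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 400))
        # 31 traits, each a mix of the two signals plus tiny noise
        w = rng.normal(size=(2, len(FA_TRAITS)))
        X = np.outer(a, w[0]) + np.outer(b, w[1]) + rng.normal(0, 1e-3, (400, len(FA_TRAITS)))
        proj = ReferenceProjection().fit(pd.DataFrame(X, columns=FA_TRAITS))
        assert proj.n_pc_ == 2

    def test_projection_reproduces_fitting_scores(self, fat_basis_population):
        records, _ = fat_basis_population
        proj = ReferenceProjection().fit(records)
        scores = milkfa.project(records, proj)
        z = (records[list(FA_TRAITS)].to_numpy() - proj.center_) / proj.scale_
        assert np.allclose(scores.to_numpy(), z @ proj.loadings_, atol=1e-10)
        assert np.allclose(proj.score_mean_, 0, atol=1e-8)

    def test_center_record_scores_to_zero(self, fat_basis_population):
        records, _ = fat_basis_population
        proj = ReferenceProjection().fit(records)
        center = pd.DataFrame([proj.center_], columns=FA_TRAITS)
        assert np.allclose(proj.transform(center), 0, atol=1e-10)

    def test_loadings_orthonormal(self, fat_basis_population):
        records, _ = fat_basis_population
        proj = ReferenceProjection().fit(records)
        gram = proj.loadings_.T @ proj.loadings_
        assert np.allclose(gram, np.eye(proj.n_pc_), atol=1e-8)

    def test_constant_trait_rejected(self):
        X = pd.DataFrame(np.ones((10, len(FA_TRAITS))), columns=FA_TRAITS)
        with pytest.raises(ValueError, match="constant"):
            ReferenceProjection().fit(X)

    def test_default_population_first_two_pcs_dominate(self, fat_basis_population):
        """Cluster structure concentrates variance: the first two
        components of the 7-state population explain a majority."""
        records, _ = fat_basis_population
        proj = ReferenceProjection().fit(records)
        assert proj.explained_ratio_[:2].sum() > 0.5

    def test_serialization_round_trip_exact(self, fat_basis_population, tmp_path):
        records, _ = fat_basis_population
        proj = ReferenceProjection().fit(records)
        path = tmp_path / "proj.json"
        proj.save(path)
        back = ReferenceProjection.load(path)
        assert np.array_equal(back.loadings_, proj.loadings_)
        assert np.array_equal(back.score_cov_, proj.score_cov_)
        assert back.n_pc_ == proj.n_pc_
        assert np.allclose(back.gh(records), proj.gh(records))

    def test_second_population_projects_into_reference_cloud(self, state_models):
        """A second draw from the same states lands inside the (slightly
        expanded) span of the reference score cloud for nearly all points."""
        cfg_a = milkfa.SimConfig(n_herds=20, horizon_days=120, seed=31)
        cfg_b = milkfa.SimConfig(n_herds=20, horizon_days=120, seed=32)
        rec_a, _ = milkfa.simulate_population(state_models, cfg_a)
        rec_b, _ = milkfa.simulate_population(state_models, cfg_b)
        fa_a = milkfa.convert_to_fat_basis(rec_a)
        fa_b = milkfa.convert_to_fat_basis(rec_b)
        proj = ReferenceProjection().fit(fa_a)
        ref = milkfa.project(fa_a, proj).to_numpy()
        ext = milkfa.project(fa_b, proj).to_numpy()
        lo = ref.min(axis=0)
        hi = ref.max(axis=0)
        margin = 0.1 * (hi - lo)
        inside = ((ext >= lo - margin) & (ext <= hi + margin)).all(axis=1)
        assert inside.mean() >= 0.95


class TestGH:
    def test_zero_at_the_mean(self, fat_basis_population):
        records, _ = fat_basis_population
        proj = ReferenceProjection().fit(records)
        at_mean = np.asarray([proj.score_mean_])
        assert proj.gh_from_scores(at_mean)[0] == pytest.approx(0.0, abs=1e-12)

    def test_unit_deviation_identity_covariance(self):
        proj = ReferenceProjection()
        proj.n_pc_ = 6
        proj.score_mean_ = np.zeros(6)
        proj.score_cov_inv_ = np.eye(6)
        gh = proj.gh_from_scores(np.ones((1, 6)))
        assert gh[0] == pytest.approx(1.0)

    def test_gaussian_reference_mean_near_one(self):
        """nPC * GH ~ chi2(nPC) on the fitting population, so mean GH = 1."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(50_000, len(FA_TRAITS))), columns=FA_TRAITS)
        proj = ReferenceProjection(variance_threshold=0.95).fit(X)
        gh = proj.gh(X)
        assert gh.mean() == pytest.approx(1.0, abs=0.02)
        assert (gh >= 0).all()
        # extreme tail essentially follows the chi2 bound
        p5 = stats.chi2(proj.n_pc_).sf(5 * proj.n_pc_)
        assert (gh > 5).mean() <= max(5 * p5, 2e-4)

    def test_rotation_invariance(self):
        """GH is unchanged by a consistent orthonormal rotation of scores,
        mean and covariance."""
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(200, 4))
        mean = scores.mean(axis=0)
        cov = np.cov(scores, rowvar=False)
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))

        def gh_of(s, m, c):
            d = s - m
            return np.einsum("ij,jk,ik->i", d, np.linalg.inv(c), d) / 4

        base = gh_of(scores, mean, cov)
        rot = gh_of(scores @ q, mean @ q, q.T @ cov @ q)
        assert np.allclose(base, rot, atol=1e-9)
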
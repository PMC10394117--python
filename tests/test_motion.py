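"""PCA motion model, augmentation counts/ranges, and test scenarios."""

import numpy as np
import pytest

from livertrack.grid import BoundaryDVF
from livertrack.motion import (SCALING_RANGES_TRAIN, TEST_PHASES,
                               TRAIN_PHASES, TYPE1_RANGES, VALIDATION_PHASES,
                               augment_training_set, fit_pca,
                               make_test_scenarios, sample_rigid_translation,
                               scenario_field, synthesize_dvf)


def _random_fields(rng, n_phases=10, n_nodes=40):
    return [rng.normal(size=(n_nodes, 3)) for _ in range(n_phases)]


class TestFitPCA:
    def test_requires_four_phases(self, rng):
        with pytest.raises(ValueError):
            fit_pca(_random_fields(rng, 3))

    def test_mean_is_elementwise_mean(self, rng):
        fields = _random_fields(rng)
        model = fit_pca(fields)
        assert np.allclose(model.mean, np.mean([f.ravel() for f in fields], 0))

    def test_components_orthogonal_against_full_eigendecomposition(self, rng):
        fields = _random_fields(rng)
        model = fit_pca(fields)
        C = model.components
        G = C @ C.T
        assert np.allclose(G, np.eye(3), atol=1e-8)
        # cross-check subspace against a full eigendecomposition of the
        # sample covariance (independent route)
        X = np.stack([f.ravel() for f in fields])
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        top = evecs[:, np.argsort(evals)[::-1][:3]]
        # same span: projector difference vanishes
        P1 = C.T @ C
        P2 = top @ top.T
        assert np.allclose(P1, P2, atol=1e-8)

    def test_rank2_inputs_reconstruct_exactly(self, rng):
        base1 = rng.normal(size=120)
        base2 = rng.normal(size=120)
        fields = [(2.0 * np.cos(t) * base1 + np.sin(t) * base2).reshape(40, 3)
                  for t in np.linspace(0, 2 * np.pi, 8, endpoint=False)]
        model = fit_pca(fields, [f"{10*i}%" for i in range(8)])
        for i, lab in enumerate(model.coefficients):
            rec = synthesize_dvf(model, model.coefficients[lab])
            denom = max(np.linalg.norm(fields[i]), 1e-12)
            assert np.linalg.norm(rec - fields[i]) / denom < 1e-6

    def test_synthesize_matches_bruteforce_combination(self, rng):
        model = fit_pca(_random_fields(rng))
        w = rng.normal(size=4)
        expected = (w[0] * model.mean + w[1] * model.components[0]
                    + w[2] * model.components[1] + w[3] * model.components[2])
        assert np.allclose(synthesize_dvf(model, w).ravel(), expected,
                           rtol=0, atol=1e-12)
        assert np.allclose(synthesize_dvf(model, [1, 0, 0, 0]).ravel(),
                           model.mean)


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(0)
    return fit_pca(_random_fields(rng))


class TestAugmentation:
    def test_training_phase_count_768(self, model):
        cases = augment_training_set(model, TRAIN_PHASES, seed=5)
        assert len(cases) == 768

    def test_validation_phase_count_384(self, model):
        cases = augment_training_set(model, VALIDATION_PHASES, seed=5)
        assert len(cases) == 384

    def test_scaling_ranges_respected(self, model):
        cases = augment_training_set(model, TRAIN_PHASES, seed=5)
        s = np.array([c.scalings for c in cases])
        for k, (lo, hi) in enumerate(SCALING_RANGES_TRAIN):
            assert s[:, k].min() >= lo and s[:, k].max() <= hi

    def test_phase_outside_designated_set_rejected(self, model):
        with pytest.raises(ValueError):
            augment_training_set(model, ["50%"], seed=0)


class TestRigidTranslation:
    def test_range_and_zero(self, rng):
        draws = np.stack([sample_rigid_translation(6.0, rng)
                          for _ in range(10_000)])
        assert draws.min() >= -6.0 and draws.max() <= 6.0
        assert np.all(sample_rigid_translation(0.0, rng) == 0.0)

    def test_component_mean_near_zero(self, rng):
        n = 100_000
        draws = rng.uniform(-6.0, 6.0, size=(n, 3))  # CLT reference
        sigma = 6.0 / np.sqrt(3.0) / np.sqrt(n)
        sample = np.stack([sample_rigid_translation(6.0, rng)
                           for _ in range(20_000)])
        assert np.all(np.abs(sample.mean(axis=0)) <
                      3 * 6.0 / np.sqrt(3.0) / np.sqrt(len(sample)))
        assert np.all(np.abs(draws.mean(axis=0)) < 3 * sigma)


class TestScenarios:
    def test_translation_types_yield_33_cases(self, model):
        for t in (2, 3, 4):
            specs = make_test_scenarios(model, t, seed=1)
            assert len(specs) == 33
            axis = t - 2
            shifts = sorted({s.translation[axis] for s in specs})
            assert np.allclose(shifts, np.arange(-10, 11, 2))
            for s in specs:
                assert s.scalings == (1.0, 1.0, 1.0, 1.0)

    def test_type2_contains_zero_translation_per_phase(self, model):
        specs = make_test_scenarios(model, 2, seed=1)
        for phase in TEST_PHASES:
            zero = [s for s in specs if s.phase == phase
                    and s.translation == (0.0, 0.0, 0.0)]
            assert len(zero) == 1

    def test_type1_ranges_and_counts(self, model):
        specs = make_test_scenarios(model, 1, seed=1, n_type1_per_phase=25)
        assert len(specs) == 75
        s = np.array([sp.scalings for sp in specs])
        assert s[:, 1].min() >= 0.0 and s[:, 1].max() <= 5.0
        assert s[:, 2].min() >= 0.0 and s[:, 2].max() <= 5.0
        assert s[:, 3].min() >= 0.0 and s[:, 3].max() <= 2.5
        assert all(sp.translation == (0.0, 0.0, 0.0) for sp in specs)

    def test_invalid_type_rejected(self, model):
        with pytest.raises(ValueError):
            make_test_scenarios(model, 5, seed=0)

    def test_test_ranges_strictly_contain_training_ranges(self):
        for (lo_t, hi_t), (lo, hi) in zip(TYPE1_RANGES[1:],
                                          SCALING_RANGES_TRAIN[1:]):
            assert hi_t > hi  # robustness design: test beyond training
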
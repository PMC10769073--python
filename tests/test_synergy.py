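"""HSA / Bliss / ZIP scoring: arithmetic, oracles, nulls and time courses."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

import perturbscreen as ps
from perturbscreen.errors import ValidationError
from perturbscreen.layout import combination_grids
from perturbscreen.synergy import synergy_over_time, zip_score

from conftest import two_drug_null_spec, two_drug_synergy_spec


def bliss_inclusion_exclusion(effects):
    """Brute-force inclusion-exclusion expansion of the Bliss expectation."""
    n = len(effects)
    total = 0.0
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            prod = 1.0
            for i in subset:
                prod *= effects[i]
            total += (-1) ** (size + 1) * prod
    return total


class TestCapEffects:
    def test_negative_inhibition_floored(self):
        assert ps.cap_effects(np.array([-0.10]))[0] == 0.0

    def test_in_range_unchanged(self):
        assert ps.cap_effects(np.array([0.55]))[0] == 0.55

    def test_overshoot_ceiled(self):
        assert ps.cap_effects(np.array([1.02]))[0] == 1.0


class TestHSABIArithmetic:
    def test_two_drug_hsa(self):
        assert ps.hsa_score([0.3, 0.5], 0.7) == pytest.approx(0.2)

    def test_hsa_additivity_boundary(self):
        assert ps.hsa_score([0.3, 0.5], 0.5) == 0.0

    def test_three_drug_hsa_antagonistic(self):
        assert ps.hsa_score([0.1, 0.6, 0.2], 0.5) == pytest.approx(-0.1)

    def test_bi_independence_product(self):
        assert ps.bi_predicted([0.5, 0.5]) == pytest.approx(0.75)

    def test_bi_absorbing_full_effect(self):
        assert ps.bi_predicted([1.0, 0.3, 0.7]) == 1.0

    def test_bi_three_drug_value(self):
        assert ps.bi_predicted([0.1, 0.2, 0.3]) == pytest.approx(0.496)
        assert bliss_inclusion_exclusion([0.1, 0.2, 0.3]) == pytest.approx(0.496)

    def test_bi_score_difference(self):
        assert ps.bi_score([0.5, 0.5], 0.9) == pytest.approx(0.15)

    def test_null_fixed_points(self):
        singles = [0.2, 0.4, 0.35]
        assert ps.bi_score(singles, ps.bi_predicted(singles)) == pytest.approx(0.0)
        assert ps.hsa_score(singles, max(singles)) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_product_form_equals_inclusion_exclusion_exhaustively(self, n):
        levels = [0.0, 0.5, 1.0] if n >= 4 else [0.0, 0.25, 0.5, 0.75, 1.0]
        for effects in itertools.product(levels, repeat=n):
            assert ps.bi_predicted(effects) == pytest.approx(
                bliss_inclusion_exclusion(effects), abs=1e-12
            )

    @settings(max_examples=2000, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=5),
        st.floats(0, 1, allow_nan=False),
    )
    def test_hsa_value_never_exceeds_bliss_value(self, singles, observed):
        """max(Di) <= H(F) on [0,1]^N, hence hsa_score >= bi_score."""
        assert max(singles) <= ps.bi_predicted(singles) + 1e-12
        assert ps.hsa_score(singles, observed) >= ps.bi_score(singles, observed) - 1e-12

    def test_scores_invariant_to_agent_ordering(self, rng):
        for _ in range(50):
            singles = rng.uniform(0, 1, rng.integers(2, 6))
            o = rng.uniform(0, 1)
            perm = rng.permutation(singles)
            assert ps.hsa_score(singles, o) == pytest.approx(ps.hsa_score(perm, o))
            assert ps.bi_score(singles, o) == pytest.approx(ps.bi_score(perm, o))


def reference_zip_two_drug(doses_a, doses_b, mono_a, mono_b, combo):
    """Independently coded two-drug ZIP delta (classical formulation)."""

    def hill(x, emax, m, lam):
        u = (np.asarray(x, dtype=float) / m) ** lam
        return emax * u / (1.0 + u)

    pa, _ = curve_fit(hill, doses_a, mono_a, p0=[0.8, np.median(doses_a), 1.0], maxfev=20000)
    pb, _ = curve_fit(hill, doses_b, mono_b, p0=[0.8, np.median(doses_b), 1.0], maxfev=20000)
    fa, fb = hill(doses_a, *pa), hill(doses_b, *pb)
    delta = np.full(combo.shape, np.nan)
    for i in range(len(doses_a)):
        for j in range(len(doses_b)):
            expected = fa[i] + fb[j] - fa[i] * fb[j]
            fits = []
            # condition on drug A at dose i, fit along B's axis
            def cond_b(x, emax, m, lam, base=fa[i]):
                u = (np.asarray(x, dtype=float) / m) ** lam
                return base + (emax - base) * u / (1.0 + u)

            pc, _ = curve_fit(cond_b, doses_b, combo[i, :], p0=[0.9, np.median(doses_b), 1.0], maxfev=20000)
            fits.append(cond_b(doses_b[j], *pc))

            def cond_a(x, emax, m, lam, base=fb[j]):
                u = (np.asarray(x, dtype=float) / m) ** lam
                return base + (emax - base) * u / (1.0 + u)

            pc, _ = curve_fit(cond_a, doses_a, combo[:, j], p0=[0.9, np.median(doses_a), 1.0], maxfev=20000)
            fits.append(cond_a(doses_a[i], *pc))
            delta[i, j] = np.mean(fits) - expected
    return delta


class TestZIP:
    doses = np.geomspace(10.0, 3000.0, 7)

    def _mono(self, emax, m, lam):
        u = (self.doses / m) ** lam
        return emax * u / (1.0 + u)

    def test_bliss_constructed_combo_gives_zero_delta(self):
        ma = self._mono(0.8, 300, 1.4)
        mb = self._mono(0.6, 500, 1.1)
        combo = 1 - (1 - ma[:, None]) * (1 - mb[None, :])
        delta, predicted = zip_score([self.doses, self.doses], [ma, mb], combo)
        np.testing.assert_allclose(delta, 0.0, atol=1e-8)
        np.testing.assert_allclose(predicted, combo, atol=1e-8)

    def test_matches_independent_reference_implementation(self):
        ma = self._mono(0.85, 200, 1.6)
        mb = self._mono(0.65, 800, 1.2)
        combo = 1 - (1 - ma[:, None]) * (1 - mb[None, :])
        delta, _ = zip_score([self.doses, self.doses], [ma, mb], combo)
        ref = reference_zip_two_drug(self.doses, self.doses, ma, mb, combo)
        np.testing.assert_allclose(delta, ref, atol=1e-6)

    def test_three_agent_bliss_null(self):
        d = np.geomspace(10, 1000, 4)
        monos = [self._mono_on(d, 0.7, 100, 1.3), self._mono_on(d, 0.5, 300, 1.0),
                 self._mono_on(d, 0.6, 200, 1.5)]
        surv = np.ones((4, 4, 4))
        for i, m in enumerate(monos):
            shape = [1, 1, 1]
            shape[i] = -1
            surv = surv * (1 - m.reshape(shape))
        delta, _ = zip_score([d, d, d], monos, 1 - surv)
        np.testing.assert_allclose(delta, 0.0, atol=1e-6)

    @staticmethod
    def _mono_on(d, emax, m, lam):
        u = (d / m) ** lam
        return emax * u / (1.0 + u)

    def test_needs_two_doses_per_agent(self):
        with pytest.raises(ValidationError):
            zip_score([np.array([1.0]), self.doses], [np.array([0.1]), self._mono(0.5, 100, 1)],
                      np.zeros((1, 7)))


class TestSynergyOverTime:
    def _analysis(self, spec, method="BI"):
        from perturbscreen.synthgen import simulate_screen

        screen, truth, _ = simulate_screen(spec)
        lay = ps.build_layout(screen.descriptors, confirmed=True)
        ctrl = screen.measurements[:, lay.control_indices[0]]
        eff = ps.normalize_to_control(screen.measurements, ctrl).effect
        grid = combination_grids(lay.branches[0])[0]
        return screen, synergy_over_time(eff, screen.elapsed, grid, method)

    def test_endpoint_screen_single_column(self):
        screen, res = self._analysis(two_drug_null_spec(0, times=(72.0,)))
        assert res.scores.shape == (1, 49)

    def test_onset_detected_at_injected_time(self):
        spec = two_drug_synergy_spec(3)
        screen, res = self._analysis(spec)
        cell = res.coords.index((0, 0))
        assert res.onset_time(cell) == pytest.approx(20.0, abs=4.0)
        before = res.scores[screen.elapsed < 18.0, cell]
        assert np.nanmax(np.abs(before)) < 0.1

    def test_zip_rejected_for_genetic_chemical(self, fixtures):
        path, _ = fixtures["genetic_chemical"]
        screen = ps.read_export(path)
        lay = ps.build_layout(screen.descriptors, confirmed=True)
        ctrl = screen.measurements[:, lay.control_indices[0]]
        eff = ps.normalize_to_control(screen.measurements, ctrl).effect
        branch = next(b for b in lay.branches if b.has_combination)
        grid = combination_grids(branch, lay.branches)[0]
        with pytest.raises(ValidationError, match="HSA or BI"):
            synergy_over_time(
                eff, screen.elapsed, grid, "ZIP", experiment_type="genetic_chemical"
            )

    def test_bliss_null_screen_scores_near_zero(self):
        means = []
        for seed in range(5):
            _, res = self._analysis(two_drug_null_spec(seed))
            means.append(np.nanmean(res.scores))
        assert abs(np.mean(means)) < 0.02

    def test_injected_epsilon_recovered_in_bi_score(self):
        spec = two_drug_synergy_spec(11, epsilon=0.2, onset=20.0)
        screen, res = self._analysis(spec)
        cell = res.coords.index((0, 0))
        after = res.scores[screen.elapsed >= 24.0, cell]
        # survival-model truth: score = eps * (1 - H), H small at the low-dose cell
        assert np.nanmean(after) == pytest.approx(0.2, abs=0.05)
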
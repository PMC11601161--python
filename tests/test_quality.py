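import numpy as np
import pytest

import factalign as fa
from factalign.align import AlignmentResult
from factalign.quality import (CalibrationError, EvalueCalibration,
                               QualityParams)


def identity_alignment(n):
    return AlignmentResult(columns=[(i, i) for i in range(n)], score=1.0)


class TestLddtMu:
    def test_self_alignment_scores_one(self, helix30):
        a = identity_alignment(len(helix30))
        assert fa.lddt_mu(a, helix30, helix30) == pytest.approx(1.0)

    def test_no_reference_pairs_in_radius_scores_zero(self):
        # aligned residues 20 A apart: no pair within the 15 A radius
        n = 5
        coords = np.column_stack([20.0 * np.arange(n), np.zeros(n),
                                  np.zeros(n)])
        s = fa.ChainStructure(id="sparse", aa="A" * n, coords=coords)
        assert fa.lddt_mu(identity_alignment(n), s, s) == 0.0

    def test_empty_alignment_scores_zero(self, helix30):
        a = AlignmentResult(columns=[], score=0.0)
        assert fa.lddt_mu(a, helix30, helix30) == 0.0

    def test_monotone_degradation_with_noise(self, helix30):
        scores = {0.1: [], 2.0: []}
        for sigma in scores:
            for rep in range(20):
                hom, cols = fa.derive_homolog(
                    helix30, fa.SimParams(seed=300 + rep, noise_sigma=sigma,
                                          indel_rate=0.0))
                a = AlignmentResult(columns=cols, score=1.0)
                scores[sigma].append(fa.lddt_mu(a, helix30, hom))
        assert np.mean(scores[0.1]) > np.mean(scores[2.0])

    def test_rigid_transform_invariance(self, helix30):
        rng = np.random.default_rng(11)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = fa.ChainStructure(id="m", aa=helix30.aa,
                                  coords=helix30.coords @ q.T + 100.0)
        a = identity_alignment(len(helix30))
        assert fa.lddt_mu(a, helix30, moved) == pytest.approx(
            fa.lddt_mu(a, helix30, helix30), abs=1e-9)

    def test_out_of_range_column_rejected(self, helix30):
        a = AlignmentResult(columns=[(0, 0), (40, 40)], score=0.0)
        with pytest.raises(IndexError):
            fa.lddt_mu(a, helix30, helix30)


class TestAqStatistic:
    def test_closed_form_two_thirds(self):
        # choose t so a + b t = 0
        p = QualityParams()
        t_star = p.a / -p.b
        # invert: delta_lddt contribution only (s = s_rev = 0)
        r = fa.aq_statistic(t_star / p.delta, 0.0, 0.0, 50, 50, p)
        assert r.aq == pytest.approx(2 / 3)

    def test_limits_zero_and_one(self):
        p = QualityParams()
        hi = fa.aq_statistic(0.0, 1e9, 0.0, 50, 50, p)
        lo = fa.aq_statistic(0.0, 0.0, 1e9, 50, 50, p)
        assert hi.aq == pytest.approx(1.0, abs=1e-12)
        assert lo.aq == pytest.approx(0.0, abs=1e-12)
        assert 0 < hi.aq <= 1 and 0 <= lo.aq < 1

    def test_symmetric_in_lengths(self):
        a = fa.aq_statistic(0.5, 30.0, 5.0, 40, 90)
        b = fa.aq_statistic(0.5, 30.0, 5.0, 90, 40)
        assert a.aq == b.aq

    def test_monotone_in_components(self):
        p = QualityParams()
        base = fa.aq_statistic(0.5, 50.0, 10.0, 50, 50, p).aq
        assert fa.aq_statistic(0.6, 50.0, 10.0, 50, 50, p).aq > base
        assert fa.aq_statistic(0.5, 60.0, 10.0, 50, 50, p).aq > base
        assert fa.aq_statistic(0.5, 50.0, 20.0, 50, 50, p).aq < base

    def test_lambda_damps_short_queries(self):
        p = QualityParams()
        short = fa.aq_statistic(0.0, 20.0, 0.0, 5, 5, p)
        # without lambda the normalised score would be 20*alpha/5; with it
        # the statistic is bounded by alpha*s/(L+lambda)
        assert short.t == pytest.approx(p.alpha * 20.0 / (5 + p.lam))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            QualityParams(b=0.5)
        with pytest.raises(ValueError):
            fa.aq_statistic(0.5, 1.0, 1.0, 0, 10)


class TestEvalueCalibration:
    @staticmethod
    def _decoys(n=2000, seed=0):
        rng = np.random.default_rng(seed)
        # smooth unimodal null in (0, 1)
        return rng.beta(2.0, 8.0, size=n)

    def test_slope_negative(self):
        cal = fa.fit_evalue(self._decoys(), 100)
        assert cal.slope < 0

    def test_doubling_database_doubles_evalue(self):
        cal = fa.fit_evalue(self._decoys(), 100)
        aq = 0.6
        assert fa.evalue_of(aq, cal, 200) == pytest.approx(
            2 * fa.evalue_of(aq, cal, 100))

    def test_below_median_evalue_at_least_half_db(self):
        cal = fa.fit_evalue(self._decoys(), 100)
        aq = np.quantile(self._decoys(), 0.2)
        assert fa.evalue_of(aq, cal, 100) >= 50.0

    def test_evalue_monotone_nonincreasing(self):
        cal = fa.fit_evalue(self._decoys(), 100)
        es = [fa.evalue_of(q, cal, 100) for q in np.linspace(0, 1, 50)]
        assert all(a >= b - 1e-12 for a, b in zip(es, es[1:]))

    def test_too_few_decoys_rejected(self):
        with pytest.raises(CalibrationError):
            fa.fit_evalue(self._decoys(50), 10)

    def test_self_consistency_of_fitted_tail(self):
        """Decoys drawn from the fitted null itself measure FPEPQ within a
        factor of 2 of the E-value threshold."""
        cal = fa.fit_evalue(self._decoys(4000, seed=1), 100)
        n_queries = 500
        per_query = 100
        rng = np.random.default_rng(2)
        # inverse-transform sampling from the fitted exceedance model:
        # u = P_null(AQ >= aq) is uniform
        u = rng.uniform(size=(n_queries, per_query))
        aq = (np.log10(u) - cal.intercept) / cal.slope
        evs = per_query * np.minimum(
            10.0 ** (cal.intercept + cal.slope * aq), 1.0)
        for e_thr in (0.1, 1.0, 10.0):
            fpepq = np.sum(evs < e_thr) / n_queries
            assert e_thr / 2 <= fpepq <= 2 * e_thr, (e_thr, fpepq)


class TestTuner:
    def test_tuner_picks_separating_params(self):
        rng = np.random.default_rng(3)
        n = 400
        is_h = np.zeros(n, dtype=bool)
        is_h[:100] = True
        comp = np.zeros((n, 4))
        comp[:, 3] = 50.0  # L
        comp[is_h, 0] = rng.normal(0.6, 0.05, 100)   # lddt
        comp[~is_h, 0] = rng.normal(0.2, 0.1, 300)
        comp[is_h, 1] = rng.normal(200, 30, 100)     # s
        comp[~is_h, 1] = rng.normal(40, 10, 300)
        comp[:, 2] = rng.normal(60, 20, n)           # s_rev
        p = fa.tune_quality_params(comp, is_h)
        t_h = p.delta * comp[is_h, 0] + (
            p.alpha * comp[is_h, 1] - p.beta * comp[is_h, 2]) / (50 + p.lam)
        t_d = p.delta * comp[~is_h, 0] + (
            p.alpha * comp[~is_h, 1] - p.beta * comp[~is_h, 2]) / (50 + p.lam)
        assert np.percentile(t_h, 1) > np.percentile(t_d, 99)
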
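import json

import numpy as np
import pytest

from spade_stp.fca import Concept, STPattern
from spade_stp.mining import MiningConfig
from spade_stp.significance import (PSRConfig, PValueSpectrum, SignificanceMap,
                                    SpadeConfig, estimate_spectrum, psf, psr,
                                    spade_run)
from spade_stp.synth import (InjectionSpec, RateModel, generate_background,
                             inject_stp)


def spectrum_from(pairs, n_surrogates, mode="exact"):
    """Build a spectrum whose (z, c) counts are given directly."""
    sp = PValueSpectrum(n_surrogates=n_surrogates, counting_mode=mode)
    if mode == "exact":
        sp._counts = dict(pairs)
    else:
        sp._max_c = {z: np.sort(np.asarray(v)) for z, v in pairs.items()}
    return sp


class TestSpectrum:
    def test_fraction_definition(self):
        sp = spectrum_from({(3, 4): 30}, 1000)
        assert sp.p_value(3, 4) == 0.03

    def test_unobserved_signature_is_zero(self):
        sp = spectrum_from({}, 1000)
        assert sp.p_value(5, 5) == 0.0

    def test_cumulative_monotone_in_c(self):
        sp = spectrum_from({3: [3, 5, 8]}, 10, mode="cumulative")
        ps = [sp.p_value(3, c) for c in range(3, 10)]
        assert ps == sorted(ps, reverse=True)
        assert sp.p_value(3, 3) == 0.3 and sp.p_value(3, 6) == 0.1

    def test_too_few_surrogates_rejected(self):
        tr = generate_background(RateModel(rate=10.0), 3, 100.0,
                                 np.random.default_rng(0))
        with pytest.raises(ValueError, match=">= 100"):
            estimate_spectrum(tr, MiningConfig(), n_surrogates=10)

    def test_estimated_spectrum_monotone_and_serializable(self):
        rng = np.random.default_rng(1)
        tr = generate_background(RateModel(rate=30.0), 10, 500.0, rng)
        sp = estimate_spectrum(tr, MiningConfig(), n_surrogates=100, rng=rng,
                               K=20)
        for z, arr in sp._max_c.items():
            ps = [sp.p_value(z, c) for c in range(3, int(arr.max()) + 2)]
            assert ps == sorted(ps, reverse=True)
        back = PValueSpectrum.from_json(json.loads(json.dumps(sp.to_json())))
        assert back.p_value(3, 3) == sp.p_value(3, 3)


def concept(z, c):
    return Concept(intent=tuple(range(z)), extent=tuple(range(c)))


class TestPSF:
    def test_all_zero_pvalues_keep_everything(self):
        sp = spectrum_from({}, 1000)
        cs = [concept(3, 3), concept(4, 5)]
        kept, sigs, _ = psf(cs, sp, alpha=0.01)
        assert kept == cs and sigs == {(3, 3), (4, 5)}

    def test_single_signature_reduces_to_plain_alpha(self):
        sp = spectrum_from({(3, 3): 20}, 1000)  # p = 0.02
        kept, sigs, _ = psf([concept(3, 3)], sp, alpha=0.01)
        assert kept == [] and sigs == set()

    def test_bh_step_up_hand_computed(self):
        # p-values {0.002, 0.006, 0.04} at alpha 0.01: BH keeps two smallest
        sp = spectrum_from({(3, 3): 2, (4, 4): 6, (5, 5): 40}, 1000)
        cs = [concept(3, 3), concept(4, 4), concept(5, 5)]
        kept, sigs, _ = psf(cs, sp, alpha=0.01)
        assert sigs == {(3, 3), (4, 4)}
        assert [c.signature for c in kept] == [(3, 3), (4, 4)]


def pat(spikes, occs):
    return STPattern(spikes=tuple(sorted(spikes)), occurrences=tuple(occs))


class TestPSR:
    def sig_map(self, significant):
        sp = spectrum_from({}, 1000)
        m = SignificanceMap(p_crit=0.5, spectrum=sp, z_min=3, c_min=3)
        m.is_significant = lambda z, c: (z, c) in significant  # type: ignore
        return m

    def test_disjoint_patterns_untouched(self):
        a = pat([(0, 0), (1, 5), (2, 10)], range(5))
        b = pat([(5, 0), (6, 5), (7, 10)], range(4))
        out = psr([a, b], self.sig_map(set()), PSRConfig(), K=50)
        assert out == [a, b]

    def test_subset_conditioning_arithmetic(self):
        # A (z=5, c=4) contains B (z=3, c=10): A tested at (5-3+0, 4),
        # B at (3, 10-4+2). Making only A's conditioned signature
        # significant keeps A alone.
        a = pat([(i, 5 * i) for i in range(5)], range(4))
        b = pat([(i, 5 * i) for i in range(3)], range(10))
        out = psr([a, b], self.sig_map({(2, 4)}), PSRConfig(h=0, k=2), K=50)
        assert out == [a]
        out = psr([a, b], self.sig_map({(3, 8)}), PSRConfig(h=0, k=2), K=50)
        assert out == [b]
        out = psr([a, b], self.sig_map({(2, 4), (3, 8)}), PSRConfig(), K=50)
        assert out == [a, b]

    def test_neither_significant_keeps_larger_zc(self):
        a = pat([(i, 5 * i) for i in range(5)], range(3))   # z*c = 15
        b = pat([(i, 5 * i) for i in range(3)], range(4))   # z*c = 12
        out = psr([a, b], self.sig_map(set()), PSRConfig(), K=50)
        assert out == [a]

    def test_shifted_subset_detected(self):
        # B equals A's tail shifted to lag 0: still a sub-pattern, and with
        # neither conditioned signature significant the larger z*c wins
        a = pat([(0, 0), (1, 5), (2, 10)], range(3))
        b = pat([(1, 0), (2, 5)], range(4))
        out = psr([a, b], self.sig_map(set()), PSRConfig(), K=50)
        assert out == [a]

    def test_never_increases_count(self):
        rng = np.random.default_rng(0)
        pats = [pat([(int(n), int(l)) for n, l in
                     zip(rng.integers(0, 10, 3), [0, 5, 10])], range(3))
                for _ in range(6)]
        out = psr(pats, self.sig_map(set()), PSRConfig(), K=50)
        assert len(out) <= len(pats)


class TestSpadeRun:
    @pytest.fixture(scope="class")
    def injected_data(self):
        rng = np.random.default_rng(9)
        bg = generate_background(RateModel(rate=25.0), 30, 1000.0, rng)
        return inject_stp(bg, InjectionSpec(z=8, c=10, lag=5.0), rng)

    def test_significance_branch_finds_injection(self, injected_data):
        data, gt = injected_data
        cfg = SpadeConfig(method="psf-psr", n_surrogates=100)
        rep = spade_run(data, cfg, np.random.default_rng(1))
        assert rep["stages"]["mined"] >= rep["stages"]["filtered"]
        assert rep["stages"]["psf_kept"] >= rep["stages"]["final"] >= 1
        keys = {tuple(sorted(zip(p["neurons"], [int(l) for l in p["lags_ms"]])))
                for p in rep["patterns"]}
        assert gt.key(1.0) in keys

    def test_same_seed_identical_report(self, injected_data):
        data, _ = injected_data
        cfg = SpadeConfig(method="stab-comb")
        a = spade_run(data, cfg, np.random.default_rng(7))
        b = spade_run(data, cfg, np.random.default_rng(7))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_stability_branch_report_fields(self, injected_data):
        data, _ = injected_data
        rep = spade_run(data, SpadeConfig(method="stab-ext"),
                        np.random.default_rng(2))
        assert rep["thresholds"]["theta_ext"] is not None
        for p in rep["patterns"]:
            assert "sigma_ext" in p

    def test_unknown_method_rejected(self, injected_data):
        data, _ = injected_data
        with pytest.raises(ValueError):
            spade_run(data, SpadeConfig(method="nope"), np.random.default_rng(0))
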
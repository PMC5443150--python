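import numpy as np
import pytest

from spade_stp.fca import Concept, build_context
from spade_stp.mining import (MiningConfig, apply_pattern_filter,
                              brute_force_closed, mine_closed_arrays,
                              mine_closed_frequent)
from spade_stp.spikes import bin_spikes

from conftest import attr_ids, make_context, random_context


def as_set(concepts):
    return {(c.intent, c.extent) for c in concepts}


ALL = MiningConfig(min_support=1, min_size=1, z_min=1, c_min=1)


class TestBruteForce:
    def test_hand_enumerated_toy(self, toy_context):
        got = as_set(brute_force_closed(toy_context))
        assert got == {((0,), (0, 1, 2)), ((0, 1), (0, 1)), ((0, 2), (2,))}

    def test_single_object_context(self):
        ctx = make_context([[1, 3]], 5)
        got = as_set(brute_force_closed(ctx))
        assert got == {((1, 3), (0,))}

    def test_empty_incidence_min_support_two(self):
        ctx = make_context([[], [], []], 4)
        assert brute_force_closed(ctx, min_support=2) == []

    def test_large_context_refused(self):
        ctx = make_context([[0]] * 21, 1)
        with pytest.raises(ValueError, match="<= 20"):
            brute_force_closed(ctx)


class TestMiner:
    def test_unique_pair_concept(self):
        # {a,b} occurs in exactly windows 0 and 1
        ctx = make_context([[0, 1], [0, 1, 2], [2, 3], [3]], 4)
        got = mine_closed_frequent(ctx, MiningConfig(min_support=2, min_size=2,
                                                     z_min=1, c_min=1))
        assert ((0, 1), (0, 1)) in as_set(got)

    def test_worked_example_concepts(self, worked_example):
        w = worked_example
        ctx = build_context(bin_spikes(w["trains"], 1.0), w["K"])
        mined = as_set(mine_closed_frequent(
            ctx, MiningConfig(min_support=2, min_size=2, z_min=1, c_min=1)))
        U = (attr_ids(w["H"], w["K"]), (w["t_A"], w["t_B"]))
        Q = (attr_ids(w["Q"], w["K"]), (4, 19))
        assert U in mined and Q in mined
        # the single-window concept V is reachable at min_support 1
        mined1 = as_set(mine_closed_frequent(ctx, ALL))
        V = (attr_ids(w["F"], w["K"]), (w["t_A"],))
        assert V in mined1

    @pytest.mark.parametrize("min_support", [1, 2, 3])
    def test_oracle_equivalence_random(self, min_support):
        rng = np.random.default_rng(10 + min_support)
        for _ in range(30):
            ctx = random_context(rng, n_obj=8, n_attr=12, density=0.3)
            cfg = MiningConfig(min_support=min_support, min_size=1,
                               z_min=1, c_min=1)
            assert as_set(mine_closed_frequent(ctx, cfg)) == \
                as_set(brute_force_closed(ctx, min_support))

    def test_canonical_fast_path_equals_full_mine(self):
        rng = np.random.default_rng(3)
        from spade_stp.synth import RateModel, generate_background
        tr = generate_background(RateModel(kind="stationary", rate=30.0),
                                 10, 500.0, rng)
        ctx = build_context(bin_spikes(tr, 1.0), 20)
        full = mine_closed_arrays(ctx, 2, 2)
        keep = full.canonical_filter(2, 2, drop_truncated=False)
        a = {(tuple(full.intent(i)), tuple(full.extent(i))) for i in keep}
        fast = mine_closed_arrays(ctx, 2, 2, canonical_only=True)
        keep_f = fast.canonical_filter(2, 2, drop_truncated=False)
        b = {(tuple(fast.intent(i)), tuple(fast.extent(i))) for i in keep_f}
        assert a == b

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(4)
        ctx = random_context(rng, n_obj=8, n_attr=10, density=0.4)
        prev = None
        for ms in (1, 2, 3, 4):
            cur = as_set(mine_closed_frequent(
                ctx, MiningConfig(min_support=ms, min_size=1, z_min=1, c_min=1)))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_closure_invariant(self, worked_example):
        from spade_stp.fca import derive_extent, derive_intent
        w = worked_example
        ctx = build_context(bin_spikes(w["trains"], 1.0), w["K"])
        for cc in mine_closed_frequent(ctx, MiningConfig(min_support=2, min_size=1,
                                                         z_min=1, c_min=1)):
            assert tuple(derive_intent(ctx, cc.extent)) == cc.intent
            assert tuple(derive_extent(ctx, cc.intent)) == cc.extent

    def test_single_stage_equals_two_stage(self):
        # mining at support 3 and filtering 3/3 equals mining at support 2
        # then filtering: closedness does not depend on the threshold
        rng = np.random.default_rng(5)
        from spade_stp.synth import RateModel, generate_background
        tr = generate_background(RateModel(kind="stationary", rate=40.0),
                                 15, 800.0, rng)
        ctx = build_context(bin_spikes(tr, 1.0), 25)
        two = mine_closed_arrays(ctx, 2, 2)
        one = mine_closed_arrays(ctx, 3, 3)
        ka = two.canonical_filter(3, 3)
        kb = one.canonical_filter(3, 3)
        a = {(tuple(two.intent(i)), tuple(two.extent(i))) for i in ka}
        b = {(tuple(one.intent(i)), tuple(one.extent(i))) for i in kb}
        assert a == b


class TestPatternFilter:
    def test_small_z_rejected_default(self, toy_context):
        cc = Concept(intent=(0, 1), extent=tuple(range(10)))
        assert apply_pattern_filter(toy_context, [cc]) == []

    def test_boundary_signature_kept(self):
        ctx = make_context([[0, 3, 6]] * 3 + [[1]], 9, K=3, n_neurons=3)
        cc = Concept(intent=(0, 3, 6), extent=(0, 1, 2))
        kept = apply_pattern_filter(ctx, [cc])
        assert kept == [cc]

    def test_shifted_copies_removed(self, worked_example):
        w = worked_example
        ctx = build_context(bin_spikes(w["trains"], 1.0), w["K"])
        U = Concept(intent=attr_ids(w["H"], w["K"]), extent=(w["t_A"], w["t_B"]))
        Q = Concept(intent=attr_ids(w["Q"], w["K"]), extent=(4, 19))
        kept = apply_pattern_filter(ctx, [U, Q], z_min=3, c_min=2)
        assert kept == [U]

    def test_truncated_duplicates_dropped_in_pipeline_filter(self):
        # inject a 4-spike sequence often enough that its windowed suffixes
        # appear as closed canonical concepts; the pipeline filter drops them
        from spade_stp.synth import InjectionSpec, RateModel, generate_background, inject_stp
        rng = np.random.default_rng(11)
        bg = generate_background(RateModel(kind="stationary", rate=5.0), 8, 1000.0, rng)
        data, gt = inject_stp(bg, InjectionSpec(z=4, c=8, lag=5.0), rng)
        ctx = build_context(bin_spikes(data, 1.0), 20)
        mr = mine_closed_arrays(ctx, 3, 3, canonical_only=True)
        with_trunc = mr.canonical_filter(3, 3, drop_truncated=False)
        without = mr.canonical_filter(3, 3, drop_truncated=True)
        kept_templates = {tuple(sorted((int(a) // 20, int(a) % 20)
                                       for a in mr.intent(i))) for i in without}
        suffix = tuple(sorted((n, int(l) - 5) for n, l in
                              zip(gt.neurons[1:], gt.lags[1:])))
        dropped = {tuple(sorted((int(a) // 20, int(a) % 20) for a in mr.intent(i)))
                   for i in set(with_trunc) - set(without)}
        assert suffix in dropped
        assert suffix not in kept_templates
        assert gt.key(1.0) in kept_templates
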
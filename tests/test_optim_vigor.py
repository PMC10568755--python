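"""Adam update correctness and germination-vigor statistics."""
import numpy as np
import pytest

from peapod.nn import Parameter
from peapod.optim import Adam, adam_step
from peapod.synth import PlateSpec, generate_plate_series, series_counts_from_events
from peapod.vigor import (GerminationSeries, compare_conditions,
                          germination_index, germination_rate,
                          series_from_detections)


def reference_adam(params, grad_seq, lr, b1, b2, eps):
    """Hand-rolled oracle: the moment/bias-correction/update sequence."""
    params = [np.array(p, dtype=np.float64) for p in params]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    for t, grads in enumerate(grad_seq, start=1):
        for i, g in enumerate(grads):
            g = np.asarray(g, dtype=np.float64)
            m[i] = b1 * m[i] + (1 - b1) * g
            v[i] = b2 * v[i] + (1 - b2) * g * g
            mhat = m[i] / (1 - b1**t)
            vhat = v[i] / (1 - b2**t)
            params[i] = params[i] - lr * mhat / (np.sqrt(vhat) + eps)
    return params


class TestAdam:
    def test_first_step_bias_correction_exact(self):
        # at t=1 the corrected first moment equals the raw gradient, so the
        # update direction is g / (|g| + eps)
        p = Parameter(np.array([1.0, -2.0]))
        p.grad = np.array([0.5, -0.25], dtype=np.float32)
        opt = Adam([p], lr=0.1, eps=1e-12)
        opt.step()
        assert np.allclose(p.data, [1.0 - 0.1, -2.0 + 0.1], atol=1e-6)

    def test_three_steps_match_reference_oracle(self):
        grads = [[np.array([1.0, -2.0])]] * 3
        want = reference_adam([[0.3, 0.7]], grads, 0.1, 0.937, 0.999, 1e-8)[0]
        # class-based path
        p = Parameter(np.array([0.3, 0.7]))
        opt = Adam([p], lr=0.1)
        for g in grads:
            p.grad = g[0].astype(np.float32)
            opt.step()
        assert np.allclose(p.data, want, atol=1e-6)
        # functional path (float64) agrees to 1e-12
        params, state = [np.array([0.3, 0.7])], None
        for g in grads:
            params, state = adam_step(params, g, state, lr=0.1)
        assert np.max(np.abs(params[0] - want)) < 1e-12

    def test_constant_gradient_approaches_sign_step(self):
        params, state = [np.array([0.0])], None
        for _ in range(300):
            params, state = adam_step(params, [np.array([3.7])], state,
                                      lr=0.01, eps=1e-12)
        # per-step displacement tends to -lr * sign(g)
        before = params[0].copy()
        params, state = adam_step(params, [np.array([3.7])], state,
                                  lr=0.01, eps=1e-12)
        assert np.allclose(params[0] - before, -0.01, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adam_step([np.zeros(3)], [np.zeros(2)])


class TestVigorStats:
    def test_rate_examples(self):
        assert germination_rate(0, 36) == 0.0
        assert germination_rate(36, 36) == 100.0
        assert germination_rate(9, 36) == 25.0
        with pytest.raises(ValueError):
            germination_rate(1, 0)

    def test_index_examples(self):
        assert germination_index([0, 0, 0]) == 0.0
        assert germination_index([0, 3, 4, 2, 0]) == pytest.approx(
            3 / 2 + 4 / 3 + 2 / 4)
        with pytest.raises(ValueError):
            germination_index([1.0], days=[0])

    def test_later_germination_strictly_lowers_index(self):
        g = [0, 3, 4, 2, 0, 0]
        shifted = [0, 0, 3, 4, 2, 0]
        assert germination_index(shifted) < germination_index(g)

    def test_index_bounds(self):
        s = GerminationSeries("p", "g", "CK", 36, nt=[0, 10, 20, 25, 30])
        gi = s.index()
        assert gi <= 36
        assert gi >= s.nt[-1] / len(s.nt)

    def test_series_invariants_enforced(self):
        with pytest.raises(ValueError):
            GerminationSeries("p", "g", "CK", 10, nt=[5, 3])
        with pytest.raises(ValueError):
            GerminationSeries("p", "g", "CK", 10, nt=[5, 12])


def perfect_detections(truth, conf=0.9):
    """Turn ground-truth labels into noiseless detector output."""
    per_day = []
    for labels in truth.labels_by_day:
        per_day.append(np.array([[b.x1, b.y1, b.x2, b.y2, conf, b.cls]
                                 for b in labels]).reshape(-1, 6))
    return per_day


class TestSeriesFromDetections:
    def test_recovers_generator_events_exactly(self):
        spec = PlateSpec(grid=(3, 3), image_size=(180, 150), seed=9)
        _, truth = generate_plate_series(spec, 5)
        series = series_from_detections(perfect_detections(truth),
                                        truth.centers)
        nt, gt = series_counts_from_events(truth.events, 5)
        assert series.nt == nt and series.gt == gt

    def test_zero_detections(self):
        series = series_from_detections([np.zeros((0, 6))] * 4,
                                        [(10, 10), (30, 30)])
        assert series.nt == [0, 0, 0, 0]

    def test_monotone_despite_flip_flop(self):
        layout = [(10.0, 10.0)]
        day = lambda cls: np.array([[5, 5, 15, 15, 0.9, cls]])
        series = series_from_detections([day(1), day(0), day(1)], layout)
        assert series.nt == [1, 1, 1]

    def test_double_claim_resolved_by_confidence(self):
        layout = [(10.0, 10.0), (100.0, 10.0)]
        dets = np.array([[5, 5, 15, 15, 0.6, 0], [6, 5, 16, 15, 0.9, 1]])
        series = series_from_detections([dets], layout)
        assert series.nt == [1]


class TestCompareConditions:
    def mk(self, genotype, condition, nt, n=36, plate="p"):
        return GerminationSeries(plate, genotype, condition, n, nt=list(nt))

    def test_identical_conditions_zero_decrease(self):
        s = [self.mk("A", "CK", [0, 10, 20]), self.mk("A", "S1", [0, 10, 20])]
        df = compare_conditions(s)
        row = df[df.genotype == "A"].iloc[0]
        assert row.rate_decrease_pct == 0.0 and row.gi_decrease_pct == 0.0

    def test_halved_rate_is_fifty_percent_decrease(self):
        s = [self.mk("A", "CK", [0, 14, 29]), self.mk("A", "S1", [0, 7, 14])]
        # rates: 29/36 -> 80.6%,  14/36 -> ~40.3% (half)
        df = compare_conditions(s)
        assert df[df.genotype == "A"].iloc[0].rate_decrease_pct == \
            pytest.approx(100 * (29 - 14) / 29)

    def test_pooled_matches_hand_computation(self):
        s = [self.mk("A", "CK", [10, 20]), self.mk("A", "S1", [5, 10]),
             self.mk("B", "CK", [12, 30]), self.mk("B", "S1", [6, 18])]
        df = compare_conditions(s)
        pooled = df[df.genotype == "pooled"].iloc[0]
        rate_ck = (100 * 20 / 36 + 100 * 30 / 36) / 2
        rate_s = (100 * 10 / 36 + 100 * 18 / 36) / 2
        assert pooled.rate_decrease_pct == pytest.approx(
            100 * (rate_ck - rate_s) / rate_ck)

    def test_replicate_order_invariance(self):
        reps = [self.mk("A", "CK", [5, 15], plate="r1"),
                self.mk("A", "CK", [8, 22], plate="r2"),
                self.mk("A", "S1", [2, 9], plate="r3")]
        a = compare_conditions(reps)
        b = compare_conditions(list(reversed(reps)))
        assert np.allclose(a.drop(columns="genotype").values,
                           b.drop(columns="genotype").values)

    def test_missing_pair_skipped(self):
        df = compare_conditions([self.mk("A", "CK", [3, 6])])
        assert len(df) == 0
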
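"""Kernel unit tests: frozen hand-traced examples, exhaustive brute-force
oracle agreement, and the conservation/range/purity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwmecg.codec import (
    CodecConfig,
    CodecState,
    compress_sample,
    compress_stream,
    operation_budget,
    trace_kernel_ops,
)


def oracle_kernel(x: int, acc: int, step: int, max_code: int):
    """Independent brute-force reference for one kernel step.

    Deliberately written from the behavioural description, not the
    production code path: enumerate the candidate output levels and pick
    the one the error-feedback rule selects.
    """
    base_level = x - (x % step)  # largest grid multiple <= x
    error = x - base_level
    acc = acc + error
    level = base_level
    if acc > step:
        level = base_level + step
        acc = acc - step
    code = level // step
    if code > max_code:
        code = max_code
        acc = acc + step
        if acc > 2 * step:
            acc = 2 * step
    return code, acc


class TestCompressSample:
    @pytest.mark.parametrize(
        "x, acc0, r, b, code, acc1",
        [
            (5, 0, 4, 2, 1, 1),   # plain truncation, error accumulates
            (5, 4, 4, 2, 2, 1),   # accumulator exceeds the step: injection
            (0, 0, 4, 2, 0, 0),   # zero in, zero out
            (8, 0, 4, 2, 2, 0),   # exact grid multiple: no error
        ],
    )
    def test_hand_traced_examples(self, x, acc0, r, b, code, acc1):
        cfg = CodecConfig(input_bits=r, output_bits=b)
        got_code, state = compress_sample(x, CodecState(acc=acc0), cfg)
        assert (got_code, state.acc) == (code, acc1)

    def test_out_of_range_sample_rejected(self):
        cfg = CodecConfig(input_bits=4, output_bits=2)
        with pytest.raises(ValueError):
            compress_sample(16, CodecState(), cfg)
        with pytest.raises(ValueError):
            compress_sample(-1, CodecState(), cfg)

    def test_invalid_state_rejected(self):
        cfg = CodecConfig(input_bits=4, output_bits=2)
        with pytest.raises(ValueError):
            compress_sample(3, CodecState(acc=9), cfg)  # > 2*step

    @pytest.mark.parametrize("b", [1, 2, 3])
    def test_exhaustive_oracle_agreement(self, b):
        """Every reachable (x, acc) state matches the brute-force reference."""
        cfg = CodecConfig(input_bits=4, output_bits=b)
        for x in range(16):
            for acc in range(2 * cfg.step + 1):
                got = compress_sample(x, CodecState(acc=acc), cfg)
                want = oracle_kernel(x, acc, cfg.step, cfg.max_code)
                assert (got[0], got[1].acc) == want, (x, acc, b)

    def test_top_code_clamp_saturates(self):
        cfg = CodecConfig(input_bits=4, output_bits=2)  # step=4, max_code=3
        code, state = compress_sample(15, CodecState(acc=4), cfg)
        assert code == cfg.max_code
        assert state.acc <= 2 * cfg.step


class TestCodecConfig:
    @pytest.mark.parametrize("r, b", [(4, 4), (4, 0), (3, 4), (17, 4)])
    def test_invalid_configs_rejected(self, r, b):
        with pytest.raises(ValueError):
            CodecConfig(input_bits=r, output_bits=b)

    def test_step_identity(self):
        for r in range(2, 17):
            for b in range(1, r):
                cfg = CodecConfig(r, b)
                assert cfg.step * (1 << b) == 1 << r
                assert cfg.step >= 2


class TestCompressStream:
    def test_hand_traced_stream(self):
        cfg = CodecConfig(4, 2)
        s = compress_stream([5, 5, 5, 5, 5], cfg)
        assert s.codes.tolist() == [1, 1, 1, 1, 2]
        assert s.final_acc == 1
        # conservation closes the books: sum(x) - step*sum(codes) = final acc
        assert 25 - cfg.step * int(s.codes.sum()) == s.final_acc

    def test_exact_multiple_constant(self):
        s = compress_stream([8, 8, 8], CodecConfig(4, 2))
        assert s.codes.tolist() == [2, 2, 2]
        assert s.final_acc == 0

    def test_empty_stream_valid(self):
        s = compress_stream([], CodecConfig(4, 2))
        assert s.n_samples == 0 and s.codes.size == 0

    def test_matches_sample_by_sample(self):
        cfg = CodecConfig(11, 4)
        rng = np.random.default_rng(7)
        xs = rng.integers(0, 2048, size=300)
        stream = compress_stream(xs, cfg)
        state = CodecState()
        for i, x in enumerate(xs):
            code, state = compress_sample(int(x), state, cfg)
            assert code == stream.codes[i]
        assert state.acc == stream.final_acc

    @settings(deadline=None, max_examples=60)
    @given(
        data=st.data(),
        b=st.integers(min_value=1, max_value=3),
    )
    def test_prefix_conservation_property(self, data, b):
        """On clamp-free streams every prefix satisfies
        sum(x) - step*sum(codes) = acc_n - acc_0, hence stays within one step."""
        cfg = CodecConfig(input_bits=4, output_bits=b)
        # keep x below the top quantization level so the clamp never fires
        xs = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=cfg.max_code * cfg.step - 1),
                min_size=1,
                max_size=50,
            )
        )
        state = CodecState()
        csum_x, csum_code = 0, 0
        for x in xs:
            code, state = compress_sample(x, state, cfg)
            csum_x += x
            csum_code += code
            assert csum_x - cfg.step * csum_code == state.acc
            assert 0 <= state.acc <= cfg.step

    def test_purity(self):
        cfg = CodecConfig(11, 4)
        xs = np.random.default_rng(3).integers(0, 2048, size=500)
        a = compress_stream(xs, cfg)
        b = compress_stream(xs, cfg)
        np.testing.assert_array_equal(a.codes, b.codes)
        assert a.final_acc == b.final_acc

    def test_code_range_always_respected(self):
        cfg = CodecConfig(11, 2)
        xs = np.random.default_rng(5).integers(0, 2048, size=2000)
        s = compress_stream(xs, cfg)
        assert int(s.codes.max()) <= cfg.max_code
        assert int(s.codes.min()) >= 0


class TestOperationBudget:
    def test_worst_case_is_three_scaling_six_basic(self):
        assert operation_budget() == (3, 6)

    def test_budget_independent_of_config(self):
        for r, b in [(4, 1), (8, 4), (11, 4), (16, 8)]:
            assert operation_budget(CodecConfig(r, b)) == (3, 6)

    def test_trace_matches_kernel_output(self):
        cfg = CodecConfig(4, 2)
        for x in range(16):
            for acc in range(2 * cfg.step + 1):
                code_t, acc_t, _ = trace_kernel_ops(x, acc, cfg)
                code_k, state = compress_sample(x, CodecState(acc=acc), cfg)
                assert (code_t, acc_t) == (code_k, state.acc)
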
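import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apml._bits import bits_to_str
from apml.complexity import (
    ConditionalCtmTable,
    CropSpec,
    CtmTable,
    PairingPlan,
    PartitionSpec,
    bdm,
    block_entropy,
    brute_force_strong_bdm,
    build_base_ctm_by_tm_enumeration,
    build_conditional_ctm,
    coarse_conditional_bdm,
    ctm_lookup,
    rank_by_complexity,
    strong_conditional_bdm,
)


# ---------------------------------------------------------------------------
# conditional CTM tables


class TestConditionalCtm:
    def test_single_pair_is_zero_bits(self):
        table = build_conditional_ctm([("01", "10")])
        assert table.lookup("10", "01") == 0.0

    def test_four_pair_relation_values_and_fallback(self):
        # (s,a) twice -> 1 bit; singletons -> 2 bits; fallback floor(log2 4)+1 = 3
        pairs = [("0", "00"), ("0", "00"), ("0", "01"), ("1", "11")]
        table = build_conditional_ctm(pairs)
        assert table.pair_count == 4
        assert table.lookup("00", "0") == 1.0
        assert table.lookup("01", "0") == 2.0
        assert table.lookup("11", "1") == 2.0
        assert table.fallback_bits == 3
        assert table.lookup("10", "1") == 3.0

    def test_empty_relation_rejected(self):
        with pytest.raises(ValueError, match="empty relation"):
            build_conditional_ctm([])

    def test_crop_larger_than_object_rejected(self):
        with pytest.raises(ValueError):
            build_conditional_ctm([("01", "10")], crop=CropSpec((3, 5), None))

    def test_crop_applied_before_keying(self):
        # conditions differing only in cropped-away bits collapse
        pairs = [("000100", "110110"), ("110111", "110100")]
        table = build_conditional_ctm(pairs, crop=CropSpec((1, 5), (1, 5)))
        assert table.lookup("1011", "0010") == 1.0     # key-shape query
        assert table.lookup("010100", "110111") == 1.0  # full-shape query, cropped

    @pytest.mark.parametrize("pair_count,expected", [
        (528_384, 20),   # the printed initial-condition fallback
        (331_776, 19),   # the printed NK-space fallback
        (4, 3),
    ])
    def test_fallback_penalty(self, pair_count, expected):
        table = ConditionalCtmTable({("0", "0"): 1.0}, pair_count)
        assert table.fallback_bits == expected

    def test_normalization_and_fallback_dominance(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 30))
            pairs = [(bits_to_str(rng.integers(0, 2, 3)), bits_to_str(rng.integers(0, 2, 4)))
                     for _ in range(n)]
            table = build_conditional_ctm(pairs)
            assert table.normalization() == pytest.approx(1.0, abs=1e-9)
            assert table.fallback_bits > table.max_value()

    def test_eca_table_invariants(self, eca_table):
        assert eca_table.pair_count == 524_288
        assert eca_table.fallback_bits == 20
        assert eca_table.normalization() == pytest.approx(1.0, abs=1e-9)
        assert eca_table.fallback_bits > eca_table.max_value()

    def test_lookup_shape_mismatch(self, eca_table):
        with pytest.raises(ValueError, match="bits"):
            ctm_lookup(eca_table, np.zeros((4, 6), dtype=np.uint8), "0101")


# ---------------------------------------------------------------------------
# BDM family


def _base(entries):
    return CtmTable(dict(entries))


class TestBdm:
    part = PartitionSpec((2,))

    def test_single_block(self):
        assert bdm("01", self.part, _base({"01": 5.0})) == 5.0

    def test_multiplicity_term(self):
        # one block repeated 4x: 5 + log2 4
        assert bdm("01010101", self.part, _base({"01": 5.0})) == 7.0

    def test_two_distinct_blocks(self):
        assert bdm("0111", self.part, _base({"01": 3.0, "11": 5.0})) == 8.0

    def test_missing_entry_is_error_naming_block(self):
        with pytest.raises(KeyError, match="11"):
            bdm("0111", self.part, _base({"01": 3.0}))

    def test_entropy_surrogate_flag(self):
        v = bdm("0111", self.part, _base({"01": 3.0}), surrogate=True)
        assert v == pytest.approx(3.0)  # H("11") = 0, so only log terms vanish

    def test_remainder_policies(self):
        spec_pad = PartitionSpec((2,), remainder="pad")
        assert bdm("011", PartitionSpec((2,)), _base({"01": 1.0, "10": 9.0})) == 1.0
        assert bdm("011", spec_pad, _base({"01": 1.0, "10": 9.0})) == 10.0


class TestCoarseConditionalBdm:
    part = PartitionSpec((2,))

    def test_self_conditioning_zero(self, rng):
        base = _base({bits_to_str([a, b]): 1.0 for a in (0, 1) for b in (0, 1)})
        for _ in range(10):
            x = rng.integers(0, 2, 8, dtype=np.uint8)
            assert coarse_conditional_bdm(x, x, self.part, base) == 0.0

    def test_disjoint_blocks_reduce_to_bdm(self):
        base = _base({"00": 2.0, "11": 3.0})
        assert coarse_conditional_bdm("0011", "0101", self.part, base, surrogate=True) \
            == bdm("0011", self.part, base)

    def test_multiplicity_example(self):
        # X = {A x2, B x1}, Y = {A x1}, CTM(B) = 3 -> 3 + log2 2 = 4
        base = _base({"01": 9.0, "11": 3.0})
        assert coarse_conditional_bdm("010111", "01", self.part, base) == 4.0

    def test_conditioning_never_hurts(self, rng):
        base = _base({bits_to_str([a, b]): float(rng.integers(1, 9))
                      for a in (0, 1) for b in (0, 1)})
        for _ in range(50):
            x = rng.integers(0, 2, 10, dtype=np.uint8)
            y = rng.integers(0, 2, 10, dtype=np.uint8)
            assert coarse_conditional_bdm(x, y, self.part, base) \
                <= bdm(x, self.part, base) + 1e-12


def _toy_cond(rng, zero_diagonal=True, bits=2):
    keys = [format(i, f"0{bits}b") for i in range(1 << bits)]
    entries = {}
    for s in keys:
        for x in keys:
            entries[(s, x)] = 0.0 if (zero_diagonal and s == x) \
                else float(np.round(rng.uniform(0.0, 6.0), 3))
    return ConditionalCtmTable(entries, pair_count=200)


class TestStrongConditionalBdm:
    part = PartitionSpec((2,))

    def test_self_conditioning_zero(self, rng):
        cond = _toy_cond(rng)
        for _ in range(10):
            x = rng.integers(0, 2, 8, dtype=np.uint8)
            assert strong_conditional_bdm(x, x, self.part, cond) == 0.0

    def test_matches_brute_force_over_partial_pairings(self, rng):
        # every <= 8-X-block instance: pairing objective separates per
        # block, so the fast path must equal full enumeration
        for cost_model in ("zero", "mapping-bits"):
            plan = PairingPlan(cost_model=cost_model, strategy="exhaustive")
            for _ in range(25):
                cond = _toy_cond(rng, zero_diagonal=False)
                x = rng.integers(0, 2, 8, dtype=np.uint8)
                y = rng.integers(0, 2, 6, dtype=np.uint8)
                assert strong_conditional_bdm(x, y, self.part, cond, plan) \
                    == pytest.approx(brute_force_strong_bdm(x, y, self.part, cond, plan))

    def test_greedy_equals_exhaustive(self, rng):
        for _ in range(25):
            cond = _toy_cond(rng, zero_diagonal=False)
            x = rng.integers(0, 2, 12, dtype=np.uint8)
            y = rng.integers(0, 2, 8, dtype=np.uint8)
            a = strong_conditional_bdm(x, y, self.part, cond, PairingPlan(strategy="greedy"))
            b = strong_conditional_bdm(x, y, self.part, cond, PairingPlan(strategy="exhaustive"))
            assert a == pytest.approx(b)

    def test_strong_below_coarse_when_conditionals_cheaper(self, rng):
        # CTM(r|r') <= CTM(r) for all pairs (and zero self-pairs) implies
        # the strong estimate cannot exceed the coarse one
        base_vals = {format(i, "02b"): 6.0 for i in range(4)}
        base = _base(base_vals)
        for _ in range(25):
            entries = {(s, x): 0.0 if s == x else float(np.round(rng.uniform(0, 5.9), 3))
                       for s in base_vals for x in base_vals}
            cond = ConditionalCtmTable(entries, pair_count=200)
            x = rng.integers(0, 2, 10, dtype=np.uint8)
            y = rng.integers(0, 2, 10, dtype=np.uint8)
            assert strong_conditional_bdm(x, y, self.part, cond) \
                <= coarse_conditional_bdm(x, y, self.part, base) + 1e-12

    def test_crafted_inequality_instance(self):
        # CTM(A|B) = 1 < CTM(A) = 6 makes strong strictly better
        cond = ConditionalCtmTable({("11", "01"): 1.0}, pair_count=200)
        base = _base({"01": 6.0, "11": 6.0})
        x, y = "01", "11"   # X-block "01" conditioned on Y-block "11"
        strong = strong_conditional_bdm(x, y, self.part, cond)
        coarse = coarse_conditional_bdm(x, y, self.part, base)
        assert strong == 1.0 < coarse == 6.0

    def test_positional_pairs_colocated_blocks(self, eca_table):
        x = np.zeros((4, 12), dtype=np.uint8)
        y = np.zeros(12, dtype=np.uint8)
        d = strong_conditional_bdm(
            x, y, PartitionSpec((4, 6)), eca_table,
            PairingPlan(strategy="positional"), partition_y=PartitionSpec((6,)))
        expected = 2 * eca_table.lookup(x[:, :6], y[:6])
        assert d == pytest.approx(expected)


# ---------------------------------------------------------------------------
# entropy and ordering


class TestBlockEntropy:
    part = PartitionSpec((2,))

    def test_uniform_blocks_zero(self):
        assert block_entropy("010101", self.part) == 0.0

    def test_two_equally_frequent_blocks(self):
        assert block_entropy("00110011", self.part) == 1.0

    def test_all_distinct_blocks(self):
        assert block_entropy("00011011", self.part) == 2.0

    def test_worst_case_bdm_degenerates_to_entropy(self, rng):
        # equal-CTM base: BDM ordering tracks the block-entropy ordering
        base = _base({format(i, "02b"): 1.0 for i in range(4)})
        xs = [rng.integers(0, 2, 16, dtype=np.uint8) for _ in range(40)]
        b = [bdm(x, self.part, base) for x in xs]
        h = [block_entropy(x, self.part) for x in xs]
        from scipy.stats import spearmanr
        assert spearmanr(b, h).statistic > 0.85


class TestRankByComplexity:
    def test_equal_scores_fall_back_to_lex(self):
        objs = ["10", "01", "11", "00"]
        assert rank_by_complexity(objs, lambda s: 0.0) == ["00", "01", "10", "11"]

    def test_score_then_lex(self):
        scores = {"11": 2.0, "00": 1.0, "01": 3.0}
        assert rank_by_complexity(list(scores), scores.get) == ["00", "11", "01"]

    def test_matches_brute_force_sort(self, rng):
        table = {format(i, "08b"): float(rng.uniform(0, 9)) for i in range(256)}
        objs = list(table)
        expected = sorted(objs, key=lambda s: (table[s], s))
        assert rank_by_complexity(objs, table.get) == expected

    def test_scorer_failure_names_object(self):
        with pytest.raises(RuntimeError, match="'01'"):
            rank_by_complexity(["00", "01"], {"00": 1.0}.__getitem__)


# ---------------------------------------------------------------------------
# small-TM enumeration


def _independent_tm_run(table, max_steps):
    """Minimal reference simulator used as an oracle."""
    tape, pos, lo, hi, state = {}, 0, 0, 0, 0
    for _ in range(max_steps):
        write, move, nxt = table[(state, tape.get(pos, 0))]
        tape[pos] = write
        if nxt is None:
            return "".join(str(tape.get(i, 0)) for i in range(lo, hi + 1))
        pos += move
        lo, hi = min(lo, pos), max(hi, pos)
        state = nxt
    return None


class TestTmEnumeration:
    def test_one_state_table_normalizes(self):
        table = build_base_ctm_by_tm_enumeration(1, 50)
        assert all(math.isfinite(v) and v >= 0 for v in table.entries.values())
        total = sum(2.0 ** -v for v in table.entries.values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_two_state_space_size(self, tm_base):
        assert tm_base.metadata["machines"] == 10_000

    def test_frequencies_match_independent_simulation(self):
        from itertools import product
        max_steps = 30
        table = build_base_ctm_by_tm_enumeration(2, max_steps)
        actions = [(w, m, n) for w in (0, 1) for m in (-1, 1) for n in (0, 1)]
        actions += [(0, 0, None), (1, 0, None)]
        counts, halting = {}, 0
        for combo in product(range(10), repeat=4):
            # entry order mirrors the builder: least-significant first
            t = {}
            for e, a in enumerate(combo):
                t[(e // 2, e % 2)] = actions[a]
            out = _independent_tm_run(t, max_steps)
            if out is not None:
                halting += 1
                counts[out] = counts.get(out, 0) + 1
        assert halting == table.metadata["halting"]
        for x, m in counts.items():
            assert table.entries[x] == pytest.approx(-math.log2(m / halting))

    def test_monotonicity_in_max_steps(self):
        short = build_base_ctm_by_tm_enumeration(2, 10)
        longer = build_base_ctm_by_tm_enumeration(2, 60)
        assert set(short.entries) <= set(longer.entries)

    def test_space_too_large(self):
        with pytest.raises(ValueError, match="space too large"):
            build_base_ctm_by_tm_enumeration(4, 10)


@given(st.integers(min_value=1, max_value=10_000))
def test_fallback_exceeds_max_tabulated_value(pair_count):
    table = ConditionalCtmTable({("0", "0"): math.log2(pair_count)}, pair_count)
    assert table.fallback_bits > table.max_value()
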
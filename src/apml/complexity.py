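"""Computable approximations to (conditional) algorithmic complexity.

The Coding Theorem Method (CTM) turns output frequencies of an
exhaustively enumerated generative space into complexity estimates via
the coding theorem, K(x) ~ -log2 AP(x).  A *conditional* CTM table does
the same for (condition, outcome) pairs drawn from a finite relation
P = X x Y: a pair seen m times out of |P| is assigned
-log2(m / |P|) bits, and a pair never seen is assigned the fallback
penalty floor(log2 |P|) + 1, strictly above every tabulated value.

The Block Decomposition Method (BDM) extends CTM estimates to larger
tensors by partitioning them into base blocks with known CTM values and
summing CTM(block) + log2(multiplicity) over distinct blocks.  Two
conditional extensions are provided:

* coarse conditional BDM — charges only the blocks of X absent from Y
  (plus a multiplicity correction on shared blocks);
* strong conditional BDM — pairs X-blocks with Y-blocks and sums the
  pairwise conditional CTM values, minimized over admissible pairings.

All logarithms are base 2; every quantity is denominated in bits.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from ._bits import as_bits, bits_to_str

__all__ = [
    "CropSpec",
    "CtmTable",
    "ConditionalCtmTable",
    "PartitionSpec",
    "PairingPlan",
    "build_conditional_ctm",
    "ctm_lookup",
    "partition_blocks",
    "block_multiset",
    "bdm",
    "coarse_conditional_bdm",
    "strong_conditional_bdm",
    "block_entropy",
    "rank_by_complexity",
    "build_base_ctm_by_tm_enumeration",
    "entropy_surrogate",
]


# ---------------------------------------------------------------------------
# tables


@dataclass(frozen=True)
class CropSpec:
    """Window applied (along the last axis) before keying a pair.

    ``condition``/``outcome`` are (start, stop) column slices, or None to
    keep the object whole.  Rows of 2-D outcomes are always kept: the
    crop exists to discard boundary columns of finite-width evolutions.
    """

    condition: Optional[tuple] = None
    outcome: Optional[tuple] = None

    def crop_condition(self, arr: np.ndarray) -> np.ndarray:
        if self.condition is None:
            return arr
        lo, hi = self.condition
        return arr[..., lo:hi]

    def crop_outcome(self, arr: np.ndarray) -> np.ndarray:
        if self.outcome is None:
            return arr
        lo, hi = self.outcome
        return arr[..., lo:hi]

    def describe(self) -> str:
        fmt = lambda w: "-" if w is None else f"{w[0]}:{w[1]}"
        return f"cond={fmt(self.condition)};out={fmt(self.outcome)}"


def _fallback_bits(pair_count: int) -> int:
    return int(math.floor(math.log2(pair_count))) + 1


@dataclass
class CtmTable:
    """Finite map object-key -> bits for base (unconditional) CTM values."""

    entries: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.entries.items():
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"CTM value for {k!r} must be finite and >= 0")

    def lookup(self, obj) -> float:
        key = obj if isinstance(obj, str) else bits_to_str(obj)
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"no base CTM entry for block {key!r}") from None

    def __contains__(self, obj) -> bool:
        key = obj if isinstance(obj, str) else bits_to_str(obj)
        return key in self.entries

    @classmethod
    def uniform(cls, block_bits: int) -> "CtmTable":
        """Maximal-entropy base: every block of n bits costs n bits.

        The -log2(1/2^n) value of the uniform distribution over n-bit
        blocks; useful when no enumerated generative space is available
        and the estimator should act as a pure reproduction test.
        """
        keys = (format(i, f"0{block_bits}b") for i in range(1 << block_bits))
        return cls(
            entries={k: float(block_bits) for k in keys},
            metadata={"source": f"uniform-{block_bits}bit"},
        )


class ConditionalCtmTable:
    """Finite map (condition, outcome) -> bits; the computable stand-in
    for K(x|y) over an enumerated relation.

    Invariants: tabulated value of a pair seen m times is -log2(m/|P|);
    the 2^(-value) masses of distinct pairs sum to 1; the fallback
    penalty floor(log2 |P|) + 1 exceeds every tabulated value.
    """

    def __init__(self, entries: Mapping, pair_count: int, crop: Optional[CropSpec] = None,
                 metadata: Optional[dict] = None):
        if pair_count <= 0:
            raise ValueError("pair_count must be positive")
        self.entries = dict(entries)
        self.pair_count = int(pair_count)
        self.fallback_bits = _fallback_bits(self.pair_count)
        self.crop = crop
        self.metadata = dict(metadata or {})

    # -- construction ------------------------------------------------------

    @classmethod
    def from_counts(cls, counts: Mapping, pair_count: Optional[int] = None,
                    crop: Optional[CropSpec] = None, metadata: Optional[dict] = None
                    ) -> "ConditionalCtmTable":
        """Build from a {(condition_key, outcome_key): multiplicity} map."""
        if not counts:
            raise ValueError("empty relation")
        total = pair_count if pair_count is not None else sum(counts.values())
        entries = {pair: -math.log2(m / total) for pair, m in counts.items()}
        return cls(entries, total, crop=crop, metadata=metadata)

    # -- queries -----------------------------------------------------------

    def _key(self, obj, window, kind: str) -> str:
        arr = as_bits(obj)
        cropped_len = self.metadata.get(f"{kind}_key_bits")
        if window is not None:
            pre_len = self.metadata.get(f"{kind}_full_bits")
            if pre_len is not None and arr.shape[-1] == pre_len:
                arr = window(arr)
            elif cropped_len is not None and arr.size == cropped_len:
                pass  # query already at key shape
            else:
                arr = window(arr)
        if cropped_len is not None and arr.size != cropped_len:
            raise ValueError(
                f"{kind} query has {arr.size} bits after cropping, "
                f"table keys have {cropped_len}")
        return bits_to_str(arr)

    def lookup(self, x, s) -> float:
        """CTM(x|s): tabulated -log2 frequency, or the fallback penalty."""
        crop = self.crop or CropSpec()
        key = (self._key(s, crop.crop_condition, "condition"),
               self._key(x, crop.crop_outcome, "outcome"))
        return self.entries.get(key, float(self.fallback_bits))

    def __contains__(self, pair) -> bool:
        s, x = pair
        crop = self.crop or CropSpec()
        key = (self._key(s, crop.crop_condition, "condition"),
               self._key(x, crop.crop_outcome, "outcome"))
        return key in self.entries

    def normalization(self) -> float:
        """Sum of 2^(-value) over tabulated pairs (should be 1)."""
        vals = np.fromiter(self.entries.values(), dtype=float, count=len(self.entries))
        return float(np.exp2(-vals).sum())

    def max_value(self) -> float:
        return max(self.entries.values())


def build_conditional_ctm(pairs: Iterable, crop: Optional[CropSpec] = None,
                          metadata: Optional[dict] = None) -> ConditionalCtmTable:
    """Tabulate a conditional CTM function from a multiset of
    (condition, outcome) pairs.

    |P| counts pair occurrences *with* repeats (after cropping); the
    tabulated value of a pair seen m times is -log2(m/|P|).
    """
    crop = crop or CropSpec()
    counts: Counter = Counter()
    meta = dict(metadata or {})
    n = 0
    for s, x in pairs:
        s_arr, x_arr = as_bits(s), as_bits(x)
        cs, cx = crop.crop_condition(s_arr), crop.crop_outcome(x_arr)
        if cs.size == 0 or cx.size == 0:
            raise ValueError("crop larger than object")
        meta.setdefault("condition_full_bits", s_arr.shape[-1])
        meta.setdefault("outcome_full_bits", x_arr.shape[-1])
        meta.setdefault("condition_key_bits", cs.size)
        meta.setdefault("outcome_key_bits", cx.size)
        counts[(bits_to_str(cs), bits_to_str(cx))] += 1
        n += 1
    if n == 0:
        raise ValueError("empty relation")
    meta["crop"] = crop.describe()
    return ConditionalCtmTable.from_counts(counts, pair_count=n, crop=crop, metadata=meta)


def ctm_lookup(table: ConditionalCtmTable, x, s) -> float:
    """CTM(x|s) against a built table (fallback penalty when absent)."""
    return table.lookup(x, s)


# ---------------------------------------------------------------------------
# partitions


@dataclass(frozen=True)
class PartitionSpec:
    """Non-overlapping row-major block decomposition.

    ``block_shape`` is (rows, cols) for matrices or (length,) for
    strings.  Blocks that do not fill the block shape are discarded by
    default; ``remainder="pad"`` zero-pads them instead.
    """

    block_shape: tuple
    remainder: str = "discard"

    def __post_init__(self):
        if self.remainder not in ("discard", "pad"):
            raise ValueError("remainder must be 'discard' or 'pad'")


def partition_blocks(X, spec: PartitionSpec) -> list:
    """Blocks of X in row-major traversal order (each has the block shape)."""
    arr = as_bits(X)
    shape = spec.block_shape
    if arr.ndim == 1 and len(shape) == 1:
        (b,) = shape
        blocks = []
        for i in range(0, arr.shape[0], b):
            chunk = arr[i:i + b]
            if chunk.shape[0] < b:
                if spec.remainder == "discard":
                    continue
                chunk = np.pad(chunk, (0, b - chunk.shape[0]))
            blocks.append(chunk)
        return blocks
    if arr.ndim == 2 and len(shape) == 2:
        br, bc = shape
        blocks = []
        for i in range(0, arr.shape[0], br):
            for j in range(0, arr.shape[1], bc):
                chunk = arr[i:i + br, j:j + bc]
                if chunk.shape != (br, bc):
                    if spec.remainder == "discard":
                        continue
                    chunk = np.pad(chunk, ((0, br - chunk.shape[0]),
                                           (0, bc - chunk.shape[1])))
                blocks.append(chunk)
        return blocks
    raise ValueError(f"partition shape {shape} does not match tensor ndim {arr.ndim}")


def block_multiset(X, spec: PartitionSpec) -> list:
    """Adj(X): list of (block_key, block, multiplicity), first-seen order."""
    blocks = partition_blocks(X, spec)
    seen: dict = {}
    for b in blocks:
        key = bits_to_str(b)
        if key in seen:
            seen[key][1] += 1
        else:
            seen[key] = [b, 1]
    return [(k, b, n) for k, (b, n) in seen.items()]


# ---------------------------------------------------------------------------
# BDM family


def _base_value(key: str, block: np.ndarray, base: CtmTable, surrogate: bool) -> float:
    if key in base.entries:
        return base.entries[key]
    if surrogate:
        return entropy_surrogate(block)
    raise KeyError(f"no base CTM entry for block {key!r} (surrogate disabled)")


def entropy_surrogate(block) -> float:
    """Entropy-calibrated stand-in for a missing base CTM entry: the
    block's empirical bit entropy times its length (exploratory use)."""
    arr = as_bits(block).ravel()
    p = arr.mean() if arr.size else 0.0
    if p in (0.0, 1.0):
        return 0.0
    h = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
    return float(arr.size * h)


def bdm(X, partition: PartitionSpec, base: CtmTable, surrogate: bool = False) -> float:
    """BDM(X) = sum over distinct blocks of CTM(block) + log2(multiplicity)."""
    total = 0.0
    for key, block, n in block_multiset(X, partition):
        total += _base_value(key, block, base, surrogate) + math.log2(n)
    return total


def _multiplicity_term(nx: int, ny: int) -> float:
    """f(n_x, n_y): 0 when multiplicities agree, else log2(n_x)."""
    return 0.0 if nx == ny else math.log2(nx)


def coarse_conditional_bdm(X, Y, partition: PartitionSpec, base: CtmTable,
                           surrogate: bool = False) -> float:
    """BDM(X|Y): blocks of X absent from Y are charged in full; shared
    blocks only pay the multiplicity correction f(n_x, n_y)."""
    adj_y = {key: n for key, _, n in block_multiset(Y, partition)}
    total = 0.0
    for key, block, nx in block_multiset(X, partition):
        if key in adj_y:
            total += _multiplicity_term(nx, adj_y[key])
        else:
            total += _base_value(key, block, base, surrogate) + math.log2(nx)
    return total


@dataclass(frozen=True)
class PairingPlan:
    """How strong conditional BDM maps X-blocks onto Y-blocks.

    cost model: "zero" (constant offsets cancel in argmin classification)
    or "mapping-bits" = (#mapped X-blocks) * log2(1 + #distinct Y-blocks),
    a computable stand-in for the |P| program-length term.

    strategy: "exhaustive" / "greedy" both return the exact minimum (the
    objective separates per X-block because the pairing is a functional
    relation, not a matching); "positional" pairs co-located blocks, the
    right prior for tensors generated by local dynamics.
    """

    cost_model: str = "zero"
    strategy: str = "exhaustive"

    def __post_init__(self):
        if self.cost_model not in ("zero", "mapping-bits"):
            raise ValueError(f"unknown cost model {self.cost_model!r}")
        if self.strategy not in ("exhaustive", "greedy", "positional"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def strong_conditional_bdm(X, Y, partition: PartitionSpec,
                           cond: ConditionalCtmTable,
                           plan: PairingPlan = PairingPlan(),
                           partition_y: Optional[PartitionSpec] = None) -> float:
    """Def-6 style conditional BDM: min over pairings of
    sum(CTM(r_x | r_y) + f(n_x, n_y)) + pairing cost.

    ``partition_y`` lets condition and outcome live at different shapes
    (e.g. 6x4 evolution blocks conditioned on 6-bit strings); defaults
    to the X partition.  An unmapped X-block is charged the table's
    fallback penalty plus log2 of its multiplicity.
    """
    part_y = partition_y or partition
    if plan.strategy == "positional":
        xblocks = partition_blocks(X, partition)
        yblocks = partition_blocks(Y, part_y)
        total = 0.0
        mapped = 0
        for i, xb in enumerate(xblocks):
            if i < len(yblocks):
                total += cond.lookup(xb, yblocks[i])
                mapped += 1
            else:
                total += float(cond.fallback_bits)
        if plan.cost_model == "mapping-bits" and mapped:
            total += mapped * math.log2(1 + len({bits_to_str(b) for b in yblocks}))
        return total

    adj_x = block_multiset(X, partition)
    adj_y = block_multiset(Y, part_y)
    map_cost = math.log2(1 + len(adj_y)) if plan.cost_model == "mapping-bits" else 0.0
    total = 0.0
    for key, xb, nx in adj_x:
        unmapped = float(cond.fallback_bits) + math.log2(nx)
        best = unmapped
        for _, yb, ny in adj_y:
            c = cond.lookup(xb, yb) + _multiplicity_term(nx, ny) + map_cost
            if c < best:
                best = c
        total += best
    return total


def brute_force_strong_bdm(X, Y, partition: PartitionSpec,
                           cond: ConditionalCtmTable,
                           plan: PairingPlan = PairingPlan(),
                           partition_y: Optional[PartitionSpec] = None) -> float:
    """Explicit enumeration over every partial pairing (test oracle)."""
    part_y = partition_y or partition
    adj_x = block_multiset(X, partition)
    adj_y = block_multiset(Y, part_y)
    map_cost = math.log2(1 + len(adj_y)) if plan.cost_model == "mapping-bits" else 0.0
    best_total = math.inf
    # each X-block maps to one of the Y-blocks or stays unmapped
    for assignment in itertools.product(range(len(adj_y) + 1), repeat=len(adj_x)):
        total = 0.0
        for (key, xb, nx), choice in zip(adj_x, assignment):
            if choice == len(adj_y):
                total += float(cond.fallback_bits) + math.log2(nx)
            else:
                _, yb, ny = adj_y[choice]
                total += cond.lookup(xb, yb) + _multiplicity_term(nx, ny) + map_cost
        best_total = min(best_total, total)
    return best_total


def block_entropy(X, partition: PartitionSpec) -> float:
    """Shannon entropy (bits) of the block-frequency distribution of X."""
    multiset = block_multiset(X, partition)
    counts = np.array([n for _, _, n in multiset], dtype=float)
    if counts.size == 0:
        raise ValueError("empty tensor")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# ordering


def rank_by_complexity(objects: Sequence, scorer: Callable) -> list:
    """Ascending algorithmic order: sort by score, ties broken
    lexicographically on the bit sequence (stable, seed-free)."""
    decorated = []
    for obj in objects:
        key = obj if isinstance(obj, str) else bits_to_str(obj)
        try:
            score = scorer(obj)
        except Exception as exc:
            raise RuntimeError(f"scorer failed on object {key!r}: {exc}") from exc
        decorated.append((score, key, obj))
    decorated.sort(key=lambda t: (t[0], t[1]))
    return [obj for _, _, obj in decorated]


# ---------------------------------------------------------------------------
# small-Turing-machine CTM base tables


_MAX_TM_STATES = 3


def _tm_transitions(states: int):
    """Action alphabet of a (state, read-symbol) entry: 4n move actions
    plus 2 halting writes -- (4n+2) choices, hence (4n+2)^(2n) machines."""
    actions = []
    for write in (0, 1):
        for move in (-1, 1):
            for nxt in range(states):
                actions.append((write, move, nxt))
    actions.append((0, 0, -1))  # write 0, halt
    actions.append((1, 0, -1))  # write 1, halt
    return actions


def build_base_ctm_by_tm_enumeration(states: int, max_steps: int,
                                     symbols: int = 2) -> CtmTable:
    """CTM(x) = -log2(fraction of halting machines outputting x), from an
    exhaustive run of every (4n+2)^(2n) two-symbol Turing machine on a
    blank tape.  The output of a halting machine is the visited tape
    segment read left to right.  Deterministic for fixed (n, max_steps).
    """
    if symbols != 2:
        raise ValueError("only 2-symbol machines are enumerated")
    if states > _MAX_TM_STATES:
        raise ValueError("space too large; supply external table")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    actions = _tm_transitions(states)
    n_actions = len(actions)
    n_entries = 2 * states
    counts: Counter = Counter()
    halting = 0
    for code in range(n_actions ** n_entries):
        # decode the transition table: entry (state, symbol) -> action
        table = []
        c = code
        for _ in range(n_entries):
            table.append(actions[c % n_actions])
            c //= n_actions
        tape: dict = {}
        pos = 0
        lo = hi = 0
        state = 0
        for _ in range(max_steps):
            sym = tape.get(pos, 0)
            write, move, nxt = table[2 * state + sym]
            tape[pos] = write
            if nxt == -1:
                halting += 1
                out = "".join(str(tape.get(i, 0)) for i in range(lo, hi + 1))
                counts[out] += 1
                break
            pos += move
            lo, hi = min(lo, pos), max(hi, pos)
            state = nxt
    if halting == 0:
        raise RuntimeError("no machine halted within max_steps")
    entries = {x: -math.log2(m / halting) for x, m in counts.items()}
    return CtmTable(entries, metadata={
        "source": f"tm-enumeration(states={states},max_steps={max_steps})",
        "machines": n_actions ** n_entries,
        "halting": halting,
    })
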
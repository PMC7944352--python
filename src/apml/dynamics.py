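"""Elementary cellular automata and NK/Kauffman Boolean networks.

Simulators, exhaustive enumerators of small generative spaces, and the
labeled-dataset generators that produce every experimental corpus used
by the classifiers: ECA rule identification, ECA initial-condition
identification (12-bit and 24-bit variants), NK rule-list and topology
classification (n=4, k=2), and Kauffman connectivity (k = 1, 2, 3)
classification at n=24.

Conventions: cyclic boundary for ECA (preserves shift symmetry); NK
nodes take an unordered set of k distinct input nodes (self allowed)
and a k-ary Boolean function, updated synchronously; evolutions are
(rows = time, row 0 = initial state) uint8 matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from ._bits import as_bits, bits_to_str, ints_to_bits, pack_rows
from ._rng import substream

__all__ = [
    "EcaRule",
    "eca_step",
    "eca_evolve",
    "NKNetwork",
    "nk_evolve",
    "enumerate_nk_space",
    "enumerate_nk_evolutions",
    "random_nk",
    "BOOLEAN_POOL",
    "LabeledDataset",
    "gen_eca_rule_dataset",
    "gen_initcond_dataset",
    "gen_nk_class_datasets",
    "gen_kauffman_k_dataset",
    "eca_relation_counts",
    "INITCOND_CLASS_INTEGERS",
    "ECA_RULE_CLASSES",
]


# ---------------------------------------------------------------------------
# elementary cellular automata


@dataclass(frozen=True)
class EcaRule:
    """Wolfram-numbered ECA rule: the output bit for neighborhood
    (left, center, right) is bit 4*left + 2*center + right of the number."""

    number: int

    def __post_init__(self):
        if not 0 <= self.number <= 255:
            raise ValueError("rule number must be in 0..255")

    @property
    def table(self) -> np.ndarray:
        return ((self.number >> np.arange(8)) & 1).astype(np.uint8)


def _rule_table(rule) -> np.ndarray:
    if isinstance(rule, EcaRule):
        return rule.table
    return EcaRule(int(rule)).table


def eca_step(state, rule) -> np.ndarray:
    """One synchronous update with cyclic boundary."""
    s = as_bits(state)
    if s.ndim != 1 or s.shape[0] < 3:
        raise ValueError("state must be a 1-D string of length >= 3")
    table = _rule_table(rule)
    idx = (np.roll(s, 1) << 2) | (s << 1) | np.roll(s, -1)
    return table[idx]


def eca_evolve(init, rule, steps: int, include_init: bool = True,
               boundary: str = "cyclic") -> np.ndarray:
    """Evolution matrix: steps+1 rows when the initial row is kept,
    steps rows otherwise; width is preserved.

    boundary: "cyclic" wraps the row into a ring; "background" evolves
    the row on an infinite all-zero background and keeps the original
    window (the frontier columns then interact with the background,
    which itself evolves under the rule -- exactly the finite-frontier
    behavior the initial-condition task's table cropping addresses).
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    s = as_bits(init)
    if s.ndim != 1:
        raise ValueError("initial state must be 1-D")
    evo = _eca_evolve_batch(s[None, :], rule, steps, boundary=boundary)[0]
    return evo if include_init else evo[1:]


def _eca_evolve_batch(states: np.ndarray, rule, steps: int,
                      boundary: str = "cyclic") -> np.ndarray:
    """Vectorized evolution of many initial states: (n, steps+1, width)."""
    if boundary not in ("cyclic", "background"):
        raise ValueError(f"unknown boundary {boundary!r}")
    width = states.shape[1]
    if boundary == "background":
        # pad by `steps` zeros per side: the pad absorbs all boundary
        # effects within the light cone, making the kept window exact
        # for an infinite zero background
        pad = np.zeros((states.shape[0], steps), dtype=np.uint8)
        states = np.concatenate([pad, states, pad], axis=1)
    table = _rule_table(rule)
    out = np.empty((states.shape[0], steps + 1, states.shape[1]), dtype=np.uint8)
    s = states
    out[:, 0] = s
    for t in range(steps):
        idx = (np.roll(s, 1, axis=1) << 2) | (s << 1) | np.roll(s, -1, axis=1)
        s = table[idx]
        out[:, t + 1] = s
    if boundary == "background":
        out = out[:, :, steps:steps + width]
    return out


def eca_relation_counts(width: int = 12, steps: int = 4,
                        rules: Iterable = range(128),
                        crop: int = 3, boundary: str = "background") -> dict:
    """Multiplicity map of the cropped (string, evolution) relation over
    ALL ``width``-bit strings and the given rules: the raw material of
    the domain-specific conditional CTM table of the initial-condition
    task.  Condition key = inner bits of the string, outcome key =
    row-major inner submatrix of the init-removed evolution.
    """
    inits = ints_to_bits(np.arange(1 << width), width)
    lo, hi = crop, width - crop
    counts: dict = {}
    for rule in rules:
        evo = _eca_evolve_batch(inits, rule, steps, boundary=boundary)
        conds = inits[:, lo:hi]
        outs = evo[:, 1:, lo:hi].reshape(inits.shape[0], -1)
        cond_codes = pack_rows(conds)
        out_codes = pack_rows(outs)
        combined = (cond_codes << np.uint64(outs.shape[1])) | out_codes
        codes, mult = np.unique(combined, return_counts=True)
        for code, m in zip(codes.tolist(), mult.tolist()):
            counts[code] = counts.get(code, 0) + m
    cond_bits, out_bits = hi - lo, (hi - lo) * steps
    decoded = {}
    for code, m in counts.items():
        out_code = code & ((1 << out_bits) - 1)
        cond_code = code >> out_bits
        decoded[(format(cond_code, f"0{cond_bits}b"),
                 format(out_code, f"0{out_bits}b"))] = m
    return decoded


# ---------------------------------------------------------------------------
# NK / Kauffman networks


def _named_pool():
    # truth tables indexed by (a << 1) | b
    return {
        "And": (0, 0, 0, 1),
        "Or": (0, 1, 1, 1),
        "Nand": (1, 1, 1, 0),
        "XOr": (0, 1, 1, 0),
    }


BOOLEAN_POOL = ("And", "Or", "Nand", "XOr")
_POOL_TABLES = _named_pool()


@dataclass(frozen=True)
class BooleanFunction:
    """k-ary Boolean function as a truth table indexed by the input
    bits read MSB-first (arity-2 named functions cover the classic
    And/Or/Nand/XOr pool)."""

    name: str
    table: tuple

    @classmethod
    def named(cls, name: str) -> "BooleanFunction":
        return cls(name, _POOL_TABLES[name])

    @property
    def arity(self) -> int:
        return int(math.log2(len(self.table)))

    def __call__(self, *inputs) -> int:
        idx = 0
        for b in inputs:
            idx = (idx << 1) | int(b)
        return self.table[idx]


def _coerce_function(fn) -> BooleanFunction:
    return BooleanFunction.named(fn) if isinstance(fn, str) else fn


@dataclass
class NKNetwork:
    """n-node Boolean network: per node an input tuple of k distinct
    node indices and a k-ary Boolean function."""

    inputs: tuple      # per node: sorted tuple of k source-node indices
    functions: tuple   # per node: BooleanFunction

    def __post_init__(self):
        self.inputs = tuple(tuple(sorted(ix)) for ix in self.inputs)
        self.functions = tuple(_coerce_function(f) for f in self.functions)
        for ix, f in zip(self.inputs, self.functions):
            if len(set(ix)) != len(ix):
                raise ValueError("input nodes must be distinct")
            if f.arity != len(ix):
                raise ValueError(
                    f"function arity {f.arity} != input count {len(ix)}")

    @property
    def n(self) -> int:
        return len(self.inputs)

    def adjacency(self) -> np.ndarray:
        """A[i, j] = 1 iff node i feeds node j (column sums equal k)."""
        adj = np.zeros((self.n, self.n), dtype=np.uint8)
        for j, ix in enumerate(self.inputs):
            for i in ix:
                adj[i, j] = 1
        return adj

    def function_names(self) -> tuple:
        return tuple(f.name for f in self.functions)

    def step(self, state: np.ndarray) -> np.ndarray:
        nxt = np.empty_like(state)
        for j, (ix, f) in enumerate(zip(self.inputs, self.functions)):
            nxt[j] = f(*(state[i] for i in ix))
        return nxt


def nk_evolve(net: NKNetwork, init, recorded_rows: int) -> np.ndarray:
    """Synchronous evolution; row 0 is the initial state, so
    ``recorded_rows`` rows means recorded_rows - 1 updates (n=4 with 10
    rows flattens to the 40-bit vectors of the rule/topology tasks)."""
    s = as_bits(init)
    if s.shape[0] != net.n:
        raise ValueError(f"initial state has {s.shape[0]} bits, network has {net.n} nodes")
    rows = [s]
    for _ in range(recorded_rows - 1):
        s = net.step(s)
        rows.append(s)
    return np.stack(rows)


def enumerate_nk_space(n: int, k: int, function_pool: Sequence = BOOLEAN_POOL
                       ) -> Iterator[NKNetwork]:
    """Every network: each node independently takes one of C(n, k) input
    sets times |pool| functions (input-set index major, function index
    minor, node-by-node odometer).  (C(n,k) * |pool|)^n networks total.
    """
    if k > n:
        raise ValueError("k must not exceed n")
    if not function_pool:
        raise ValueError("function pool must be non-empty")
    pool = [_coerce_function(f) for f in function_pool]
    input_sets = list(combinations(range(n), k))
    node_choices = [(ix, f) for ix in input_sets for f in pool]
    for combo in product(node_choices, repeat=n):
        yield NKNetwork(tuple(c[0] for c in combo), tuple(c[1] for c in combo))


def enumerate_nk_evolutions(n: int = 4, k: int = 2,
                            function_pool: Sequence = BOOLEAN_POOL,
                            rows: int = 10):
    """Vectorized sweep of the full network space from the zero initial
    state.  Returns (rule_keys, topo_keys, evolutions) aligned arrays:
    rule_keys[i] / topo_keys[i] are bit-string encodings of network i's
    function list and adjacency, evolutions[i] the flattened n*rows
    evolution vector.  Enumeration order matches enumerate_nk_space.
    """
    pool = [_coerce_function(f) for f in function_pool]
    input_sets = list(combinations(range(n), k))
    n_cfg = len(input_sets) * len(pool)
    total = n_cfg ** n
    # node-by-node odometer (node 0 most significant, matching product())
    cfg = np.empty((total, n), dtype=np.int64)
    ids = np.arange(total)
    for node in range(n - 1, -1, -1):
        cfg[:, node] = ids % n_cfg
        ids //= n_cfg
    set_idx, fn_idx = cfg // len(pool), cfg % len(pool)
    in_arr = np.array(input_sets, dtype=np.int64)[set_idx]      # (total, n, k)
    fn_tables = np.array([f.table for f in pool], dtype=np.uint8)
    state = np.zeros((total, n), dtype=np.uint8)
    rows_out = np.empty((total, rows, n), dtype=np.uint8)
    rows_out[:, 0] = state
    gather = np.arange(total)[:, None]
    for t in range(1, rows):
        idx = np.zeros((total, n), dtype=np.int64)
        for pos in range(k):
            idx = (idx << 1) | state[gather, in_arr[:, :, pos]]
        state = fn_tables[fn_idx, idx]
        rows_out[:, t] = state
    evolutions = rows_out.reshape(total, rows * n)
    # function-list key: 2 bits per node in pool order
    fn_bits = max(1, math.ceil(math.log2(len(pool))))
    rule_keys = _codes_to_strs(pack_rows(
        ints_to_bits(fn_idx.astype(np.uint64), fn_bits).reshape(total, -1)),
        n * fn_bits)
    # topology key: row-major n x n adjacency bits
    adj = np.zeros((total, n, n), dtype=np.uint8)
    for j in range(n):
        for pos in range(k):
            adj[np.arange(total), in_arr[:, j, pos], j] = 1
    topo_keys = _codes_to_strs(pack_rows(adj.reshape(total, n * n)), n * n)
    return rule_keys, topo_keys, evolutions


def _codes_to_strs(codes: np.ndarray, width: int) -> list:
    return [format(int(c), f"0{width}b") for c in codes]


def random_nk(n: int, k: int, function_pool: Sequence = BOOLEAN_POOL,
              required_function: Optional[str] = None,
              rng: Optional[np.random.Generator] = None) -> NKNetwork:
    """Uniform draw over admissible networks; when ``required_function``
    is given, redraw function lists until it appears at least once."""
    rng = rng if rng is not None else np.random.default_rng()
    pool = [_coerce_function(f) for f in function_pool]
    names = [f.name for f in pool]
    if required_function is not None and required_function not in names:
        raise ValueError(f"required function {required_function!r} not in pool")
    input_sets = list(combinations(range(n), k))
    inputs = tuple(input_sets[i] for i in rng.integers(len(input_sets), size=n))
    while True:
        fidx = rng.integers(len(pool), size=n)
        fns = tuple(pool[i] for i in fidx)
        if required_function is None or required_function in {f.name for f in fns}:
            return NKNetwork(inputs, fns)


def _random_function_list(rng, pool=BOOLEAN_POOL, required="Nand", n=4) -> tuple:
    while True:
        names = tuple(pool[i] for i in rng.integers(len(pool), size=n))
        if required is None or required in names:
            return names


def _random_topology(rng, n=4, k=2) -> tuple:
    sets = list(combinations(range(n), k))
    return tuple(sets[i] for i in rng.integers(len(sets), size=n))


# ---------------------------------------------------------------------------
# labeled datasets


@dataclass
class LabeledDataset:
    """Samples with class labels, a split tag, and a provenance manifest
    (generator name, parameters, seed) sufficient to regenerate the data
    bit-for-bit."""

    samples: list
    labels: list
    split: str
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.samples) != len(self.labels):
            raise ValueError("samples and labels must have equal length")

    def __len__(self) -> int:
        return len(self.samples)

    def class_counts(self) -> dict:
        out: dict = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


ECA_RULE_CLASSES = (167, 11, 129, 215, 88, 32, 237, 156, 173, 236, 110)

INITCOND_CLASS_INTEGERS = (704, 3572, 3067, 3184, 1939, 2386, 2896, 205, 828, 3935)


def _split_sizes(per_class: dict) -> dict:
    return per_class


def gen_eca_rule_dataset(seed, rules: Sequence = ECA_RULE_CLASSES,
                         width: int = 32) -> dict:
    """ECA generative-rule corpus: 32x32 evolutions (initial row kept) of
    uniform random 32-bit strings, labeled by the generating rule.
    Train/validation 25 per class, test 125 per class."""
    seed, streams = _streams(seed, "eca-rules")
    sizes = {"train": 25, "validation": 25, "test": 125}
    out = {}
    for split, per_class in sizes.items():
        rng = streams[split]
        samples, labels = [], []
        for rule in rules:
            inits = rng.integers(0, 2, size=(per_class, width), dtype=np.uint8)
            for init in inits:
                samples.append(eca_evolve(init, rule, width - 1, include_init=True))
                labels.append(rule)
        out[split] = LabeledDataset(samples, labels, split, manifest={
            "generator": "eca-rules", "seed": seed, "classes": list(rules),
            "width": width, "per_class": per_class})
    return out


def _class_strings_12bit(integers=INITCOND_CLASS_INTEGERS, width=12) -> list:
    return [format(i, f"0{width}b") for i in integers]


def gen_initcond_dataset(seed, class_strings: Optional[Sequence] = None,
                         width: int = 12, steps: int = 4,
                         rules: Sequence = range(128),
                         per_class: int = 20,
                         boundary: str = "background") -> dict:
    """Initial-condition corpus: each sample is the ``steps`` x ``width``
    evolution (initialization row removed) of one of the class strings
    under a uniformly drawn rule.  Default classes are the 12-bit binary
    expansions of the ten reference integers; pass 20 random 24-bit
    strings for the transfer variant."""
    if class_strings is None:
        class_strings = _class_strings_12bit(width=width)
    class_strings = [s if isinstance(s, str) else bits_to_str(s) for s in class_strings]
    if len(set(class_strings)) != len(class_strings):
        raise ValueError("duplicate class strings")
    if any(len(s) != width for s in class_strings):
        raise ValueError("class strings must match the configured width")
    seed, streams = _streams(seed, "init-cond")
    rules = list(rules)
    out = {}
    for split in ("train", "validation", "test"):
        rng = streams[split]
        samples, labels = [], []
        for cls in class_strings:
            init = as_bits(cls)
            rule_draw = rng.integers(0, len(rules), size=per_class)
            for ridx in rule_draw:
                evo = eca_evolve(init, rules[ridx], steps, include_init=False,
                                 boundary=boundary)
                samples.append(evo)
                labels.append(cls)
        out[split] = LabeledDataset(samples, labels, split, manifest={
            "generator": "init-cond", "seed": seed, "classes": class_strings,
            "width": width, "steps": steps, "rules": [int(r) for r in rules],
            "per_class": per_class, "boundary": boundary})
    return out


def random_class_strings(rng, count: int, width: int) -> list:
    """Distinct uniform random class bit strings."""
    seen: list = []
    while len(seen) < count:
        s = bits_to_str(rng.integers(0, 2, size=width, dtype=np.uint8))
        if s not in seen:
            seen.append(s)
    return seen


def _encode_function_list(names: Sequence, pool: Sequence = BOOLEAN_POOL) -> str:
    bits_per = max(1, math.ceil(math.log2(len(pool))))
    return "".join(format(pool.index(nm), f"0{bits_per}b") for nm in names)


def _encode_topology(input_sets: Sequence, n: int) -> str:
    adj = np.zeros((n, n), dtype=np.uint8)
    for j, ix in enumerate(input_sets):
        for i in ix:
            adj[i, j] = 1
    return bits_to_str(adj)


def gen_nk_class_datasets(seed, mode: str = "rules", n: int = 4, k: int = 2,
                          rows: int = 10, n_classes: int = 10,
                          per_class_train: int = 20, test_size: int = 2000,
                          required_function: str = "Nand") -> dict:
    """NK classification corpora at n=4, k=2 from the zero initial state.

    rules mode: classes are ordered 4-function lists (each containing the
    required function), topology random per sample.  topology mode:
    classes are random k=2 adjacency structures, function list random
    (required-function-containing) per sample.  Labels are the bit-string
    encodings of the class objects, matching conditional-CTM table keys.
    """
    if mode not in ("rules", "topology"):
        raise ValueError("mode must be 'rules' or 'topology'")
    seed, streams = _streams(seed, f"nk-{mode}")
    cls_rng = streams["classes"]
    classes = []
    while len(classes) < n_classes:
        if mode == "rules":
            obj = _random_function_list(cls_rng, required=required_function, n=n)
        else:
            obj = _random_topology(cls_rng, n=n, k=k)
        if obj not in classes:
            classes.append(obj)
    class_keys = ([_encode_function_list(c) for c in classes] if mode == "rules"
                  else [_encode_topology(c, n) for c in classes])
    zero = np.zeros(n, dtype=np.uint8)
    sizes = {"train": per_class_train * n_classes,
             "validation": per_class_train * n_classes,
             "test": test_size}
    out = {}
    for split, size in sizes.items():
        rng = streams[split]
        per_class = size // n_classes
        samples, labels = [], []
        for cls_obj, key in zip(classes, class_keys):
            for _ in range(per_class):
                if mode == "rules":
                    net = NKNetwork(_random_topology(rng, n=n, k=k), cls_obj)
                else:
                    net = NKNetwork(cls_obj,
                                    _random_function_list(rng, required=required_function, n=n))
                samples.append(nk_evolve(net, zero, rows).ravel())
                labels.append(key)
        out[split] = LabeledDataset(samples, labels, split, manifest={
            "generator": f"nk-{mode}", "seed": seed, "classes": class_keys,
            "class_objects": [list(map(list, c)) if mode == "topology" else list(c)
                              for c in classes],
            "n": n, "k": k, "rows": rows, "required_function": required_function})
    return out


def _random_k_function(rng, k: int) -> BooleanFunction:
    table = tuple(int(b) for b in rng.integers(0, 2, size=1 << k))
    return BooleanFunction(f"tt{table}", table)


def gen_kauffman_k_dataset(seed, n: int = 24, ks: Sequence = (1, 2, 3),
                           rows: int = 10, per_class: int = 100) -> dict:
    """Connectivity-regime corpus: 240-bit evolution vectors of n=24
    networks with k = 1 (frozen), 2 (critical), 3 (chaotic); functions
    uniform over all 2^(2^k) k-ary Boolean functions, initial state
    uniform random per sample."""
    seed, streams = _streams(seed, "kauffman-k")
    out = {}
    for split in ("train", "validation", "test"):
        rng = streams[split]
        samples, labels = [], []
        for k in ks:
            sets = list(combinations(range(n), k))
            for _ in range(per_class):
                inputs = tuple(sets[i] for i in rng.integers(len(sets), size=n))
                fns = tuple(_random_k_function(rng, k) for _ in range(n))
                net = NKNetwork(inputs, fns)
                init = rng.integers(0, 2, size=n, dtype=np.uint8)
                samples.append(nk_evolve(net, init, rows).ravel())
                labels.append(k)
        out[split] = LabeledDataset(samples, labels, split, manifest={
            "generator": "kauffman-k", "seed": seed, "classes": list(ks),
            "n": n, "rows": rows, "per_class": per_class})
    return out


# ---------------------------------------------------------------------------


def _streams(rng_or_seed, name: str):
    """Accept a seed (records it in manifests) and derive per-split streams."""
    if isinstance(rng_or_seed, (int, np.integer)):
        seed = int(rng_or_seed)
    else:
        raise TypeError(
            "dataset generators take an integer seed so the manifest can "
            "record it; use substream() for ad-hoc generators")
    streams = {part: substream(seed, f"{name}/{part}")
               for part in ("train", "validation", "test", "classes")}
    return seed, streams
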
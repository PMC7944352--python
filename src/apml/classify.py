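"""Algorithmic-probability centroid classification.

A model is an ordered set of class centroids; an object is assigned to
the class whose centroid minimizes the (approximated) conditional
algorithmic complexity K(x | centroid).  Centroids are binary tensors —
or, at a higher abstraction level, structured keys such as encoded
Boolean-function lists or adjacency matrices looked up directly in a
conditional CTM table.

Training is greedy block optimization: starting from all-zero
centroids, successive index windows of each centroid are optimized
against the aggregate class cost, exhaustively for small windows and by
coordinate descent for large ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._bits import as_bits, bits_to_str
from .complexity import (
    ConditionalCtmTable,
    CtmTable,
    PairingPlan,
    PartitionSpec,
    bdm,
    block_entropy,
    coarse_conditional_bdm,
    strong_conditional_bdm,
)
from .dynamics import LabeledDataset, eca_evolve

__all__ = [
    "DistanceSpec",
    "CentroidModel",
    "predict",
    "greedy_block_train",
    "scalar_center_train",
    "scalar_center_predict",
    "exhaustive_search_classify",
    "build_evolution_index",
    "evaluate",
    "EvaluationReport",
    "one_pixel_attack_scan",
    "AttackReport",
    "training_cost",
]


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceSpec:
    """Pluggable conditional-complexity distance between a sample x and
    a centroid c.

    kinds: "conditional-ctm" (direct table lookup CTM(x|c)),
    "strong-bdm" (block-paired conditional CTM),
    "coarse-bdm" (block-set difference against an unconditional base).
    ``partition`` decomposes samples; ``centroid_partition`` (strong
    only) decomposes centroids when they live at a different shape.
    """

    kind: str
    partition: Optional[PartitionSpec] = None
    centroid_partition: Optional[PartitionSpec] = None
    cond_table: Optional[ConditionalCtmTable] = None
    base_table: Optional[CtmTable] = None
    plan: PairingPlan = field(default_factory=lambda: PairingPlan(strategy="positional"))
    surrogate: bool = False

    def __post_init__(self):
        needs = {"conditional-ctm": ("cond_table",),
                 "strong-bdm": ("cond_table", "partition"),
                 "coarse-bdm": ("base_table", "partition")}
        if self.kind not in needs:
            raise ValueError(f"unknown distance kind {self.kind!r}")
        for attr in needs[self.kind]:
            if getattr(self, attr) is None:
                raise ValueError(f"distance {self.kind!r} requires {attr}")

    def __call__(self, x, centroid) -> float:
        if self.kind == "conditional-ctm":
            return self.cond_table.lookup(x, centroid)
        if self.kind == "strong-bdm":
            return strong_conditional_bdm(
                x, centroid, self.partition, self.cond_table, self.plan,
                partition_y=self.centroid_partition)
        return coarse_conditional_bdm(
            x, centroid, self.partition, self.base_table, surrogate=self.surrogate)

    def describe(self) -> dict:
        return {"kind": self.kind,
                "partition": getattr(self.partition, "block_shape", None),
                "centroid_partition": getattr(self.centroid_partition, "block_shape", None),
                "plan": (self.plan.strategy, self.plan.cost_model)}


@dataclass
class CentroidModel:
    """Ordered class -> centroid map; prediction is argmin distance with
    ties broken by the earliest class in declared order."""

    classes: list            # class labels, order fixes tie-breaking
    centroids: list          # str keys or binary tensors, one per class
    distance: DistanceSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.classes) != len(self.centroids):
            raise ValueError("one centroid per class required")

    def items(self):
        return zip(self.classes, self.centroids)


def predict(model: CentroidModel, x):
    """argmin_c distance(x | centroid_c); first class wins ties."""
    best_label, best_cost = None, math.inf
    for label, centroid in model.items():
        try:
            d = model.distance(x, centroid)
        except Exception as exc:
            raise RuntimeError(f"distance failed at centroid {label!r}: {exc}") from exc
        if d < best_cost:
            best_label, best_cost = label, d
    return best_label


def training_cost(model: CentroidModel, dataset: LabeledDataset) -> float:
    """Aggregate training cost: sum over samples of distance to their own
    class centroid."""
    by_label = dict(model.items())
    return sum(model.distance(x, by_label[lab])
               for x, lab in zip(dataset.samples, dataset.labels))


# ---------------------------------------------------------------------------
# greedy block training


_EXHAUSTIVE_BLOCK_BITS = 16


def greedy_block_train(init_model: CentroidModel, train: LabeledDataset,
                       blocks: Sequence[Sequence[int]],
                       max_passes: int = 8) -> CentroidModel:
    """Optimize each class centroid block-by-block against the summed
    class cost.

    ``blocks`` is a schedule of flat centroid-coordinate windows (e.g.
    two 6-bit halves, or four 8x8 quadrants of a 16x16 centroid).
    Windows of <= 16 bits are searched exhaustively over all 2^b
    candidates (first strict improvement in ascending candidate order);
    wider windows fall back to repeated single-bit coordinate-descent
    passes.  The aggregate cost is non-increasing across accepted
    updates.
    """
    groups: dict = {}
    for x, lab in zip(train.samples, train.labels):
        groups.setdefault(lab, []).append(x)
    new_centroids = []
    for label, centroid in init_model.items():
        if label not in groups:
            raise ValueError(f"class {label!r} has no training samples")
        samples = groups[label]
        cent = as_bits(centroid).copy()
        shape = cent.shape
        flat = cent.ravel()
        dist = init_model.distance
        cost = lambda: sum(dist(x, flat.reshape(shape)) for x in samples)
        current = cost()
        for window in blocks:
            window = list(window)
            if len(window) <= _EXHAUSTIVE_BLOCK_BITS:
                best_bits, best_cost = flat[window].copy(), current
                for cand in range(1 << len(window)):
                    flat[window] = [(cand >> (len(window) - 1 - i)) & 1
                                    for i in range(len(window))]
                    c = cost()
                    if c < best_cost:
                        best_bits, best_cost = flat[window].copy(), c
                flat[window] = best_bits
                current = best_cost
            else:
                for _ in range(max_passes):
                    improved = False
                    for i in window:
                        flat[i] ^= 1
                        c = cost()
                        if c < current:
                            current = c
                            improved = True
                        else:
                            flat[i] ^= 1
                    if not improved:
                        break
        new_centroids.append(flat.reshape(shape))
    return CentroidModel(list(init_model.classes), new_centroids,
                         init_model.distance,
                         provenance={**init_model.provenance,
                                     "trained": "greedy-block",
                                     "blocks": [list(b) for b in blocks]})


def two_half_schedule(width: int) -> list:
    """The two-block schedule of the initial-condition task, generalized:
    consecutive 6-bit windows covering a width-``width`` centroid."""
    return [list(range(i, min(i + 6, width))) for i in range(0, width, 6)]


# ---------------------------------------------------------------------------
# scalar (single-number) classifiers


def scalar_center_train(train: LabeledDataset, scorer: Callable) -> dict:
    """Class center = mean complexity score of the class's samples."""
    sums: dict = {}
    counts: dict = {}
    for x, lab in zip(train.samples, train.labels):
        sums[lab] = sums.get(lab, 0.0) + scorer(x)
        counts[lab] = counts.get(lab, 0) + 1
    if not sums:
        raise ValueError("empty training set")
    return {lab: sums[lab] / counts[lab] for lab in sums}


def scalar_center_predict(centers: dict, x, scorer: Callable):
    """argmin |score(x) - center|; ties go to the smaller class key."""
    if not centers:
        raise ValueError("no class centers")
    score = scorer(x)
    return min(sorted(centers), key=lambda lab: abs(score - centers[lab]))


def bdm_scorer(partition: PartitionSpec, base: CtmTable, surrogate: bool = True):
    return lambda x: bdm(x, partition, base, surrogate=surrogate)


def entropy_scorer(partition: PartitionSpec):
    return lambda x: block_entropy(x, partition)


# ---------------------------------------------------------------------------
# exhaustive-search baseline


def build_evolution_index(class_strings: Sequence[str], rule_range,
                          steps: int, boundary: str = "background") -> dict:
    """Map evolution-bytes -> class label for every (rule, class string)
    pair, keeping the first match in ascending (rule, class-index)
    order; gives answers identical to the explicit scan."""
    index: dict = {}
    for rule in rule_range:
        for cls in class_strings:
            evo = eca_evolve(as_bits(cls), rule, steps, include_init=False,
                             boundary=boundary)
            key = evo.tobytes()
            if key not in index:
                index[key] = cls
    return index


def exhaustive_search_classify(x, class_strings: Sequence[str], rule_range,
                               steps: int, fallback: Optional[CentroidModel] = None,
                               index: Optional[dict] = None,
                               boundary: str = "background"):
    """Scan (rule, class string) pairs for an exact reproduction of the
    init-removed evolution; unmatched images fall back to the centroid
    model (or None)."""
    arr = as_bits(x)
    if index is not None:
        label = index.get(arr.tobytes())
        if label is not None:
            return label
    else:
        for rule in rule_range:
            for cls in class_strings:
                evo = eca_evolve(as_bits(cls), rule, steps, include_init=False,
                                 boundary=boundary)
                if evo.shape == arr.shape and np.array_equal(evo, arr):
                    return cls
    return predict(fallback, x) if fallback is not None else None


# ---------------------------------------------------------------------------
# evaluation and robustness


@dataclass
class EvaluationReport:
    accuracy: float
    classes: list
    confusion: np.ndarray    # true x predicted counts
    per_class: dict

    def __str__(self):
        lines = [f"accuracy: {self.accuracy:.4f}"]
        for lab in self.classes:
            lines.append(f"  {lab}: {self.per_class[lab]:.4f}")
        return "\n".join(lines)


def evaluate(predictor, dataset: LabeledDataset) -> EvaluationReport:
    """Accuracy, confusion matrix and per-class accuracy of a model (a
    CentroidModel or any callable sample -> label)."""
    fn = (lambda x: predict(predictor, x)) if isinstance(predictor, CentroidModel) else predictor
    classes = list(dict.fromkeys(dataset.labels))
    idx = {lab: i for i, lab in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for x, lab in zip(dataset.samples, dataset.labels):
        pred = fn(x)
        if pred not in idx:   # prediction outside the dataset's label set
            idx[pred] = len(idx)
            grown = np.zeros((len(idx), len(idx)), dtype=np.int64)
            grown[:confusion.shape[0], :confusion.shape[1]] = confusion
            confusion = grown
            classes.append(pred)
        confusion[idx[lab], idx[pred]] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion)) / total
    per_class = {}
    for lab in dict.fromkeys(dataset.labels):
        row = confusion[idx[lab]]
        per_class[lab] = float(row[idx[lab]]) / row.sum() if row.sum() else 0.0
    return EvaluationReport(accuracy, classes, confusion, per_class)


@dataclass
class AttackReport:
    total: int
    per_sample_mean: float
    percentage: float        # of (sample, pixel) flips that change the label
    per_sample: list

    def __str__(self):
        return (f"vulnerabilities: {self.total} total, "
                f"{self.per_sample_mean:.2f} per sample, "
                f"{self.percentage:.2f}% of pixels")


def one_pixel_attack_scan(model, dataset: LabeledDataset) -> AttackReport:
    """Exhaustive one-pixel robustness scan: flip each pixel of each
    sample independently, re-predict, and count label changes."""
    fn = (lambda x: predict(model, x)) if isinstance(model, CentroidModel) else model
    per_sample = []
    pixels = None
    for x in dataset.samples:
        arr = as_bits(x).copy()
        base_label = fn(arr)
        flips = 0
        flat = arr.ravel()
        pixels = flat.size
        for i in range(flat.size):
            flat[i] ^= 1
            if fn(arr) != base_label:
                flips += 1
            flat[i] ^= 1
        per_sample.append(flips)
    total = int(sum(per_sample))
    n = len(per_sample)
    return AttackReport(
        total=total,
        per_sample_mean=total / n if n else 0.0,
        percentage=100.0 * total / (n * pixels) if n and pixels else 0.0,
        per_sample=per_sample,
    )
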
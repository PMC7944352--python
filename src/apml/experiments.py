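"""Reference end-to-end experiment pipelines.

Each function runs one seed of a complete study — dataset generation,
table-driven training where the task has any, and test-split evaluation
— and returns the test accuracy.  They are the single source of truth
for the reproduction protocol used by ``scripts/acceptance.py`` and the
acceptance test suite.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._rng import substream
from .classify import (
    CentroidModel,
    DistanceSpec,
    build_evolution_index,
    evaluate,
    exhaustive_search_classify,
    greedy_block_train,
    two_half_schedule,
)
from .complexity import ConditionalCtmTable, PairingPlan, PartitionSpec
from .dynamics import gen_initcond_dataset, gen_nk_class_datasets, random_class_strings

__all__ = [
    "initcond_distance_spec",
    "initcond_strong_bdm_accuracy",
    "exhaustive_search_accuracy",
    "transfer_24bit_accuracy",
    "nk_conditional_ctm_accuracy",
]


def initcond_distance_spec(table: ConditionalCtmTable) -> DistanceSpec:
    """Strong conditional BDM over positional (6-bit half, 6x4 half)
    block pairs — the distance of the initial-condition classifiers."""
    return DistanceSpec(
        kind="strong-bdm",
        partition=PartitionSpec((4, 6)),
        centroid_partition=PartitionSpec((6,)),
        cond_table=table,
        plan=PairingPlan(strategy="positional"),
    )


def _train_initcond_model(splits, classes, table):
    width = len(classes[0])
    spec = initcond_distance_spec(table)
    init = CentroidModel(
        list(classes), [np.zeros(width, dtype=np.uint8) for _ in classes], spec,
        provenance={"seed": splits["train"].manifest["seed"]})
    return greedy_block_train(init, splits["train"], two_half_schedule(width))


def initcond_strong_bdm_accuracy(seed: int, table: ConditionalCtmTable) -> float:
    """10-class initial-condition task: train 12-bit centroids by
    two-half greedy optimization, evaluate on the fresh test split."""
    splits = gen_initcond_dataset(seed)
    classes = splits["train"].manifest["classes"]
    model = _train_initcond_model(splits, classes, table)
    return evaluate(model, splits["test"]).accuracy


def exhaustive_search_accuracy(seed: int) -> float:
    """Exact-reproduction baseline on the same datasets: scan (rule,
    class string) pairs for the image's generating evolution."""
    splits = gen_initcond_dataset(seed)
    classes = splits["train"].manifest["classes"]
    rules = splits["train"].manifest["rules"]
    index = build_evolution_index(classes, rules, splits["train"].manifest["steps"])
    test = splits["test"]
    hits = sum(
        exhaustive_search_classify(x, classes, rules, 4, index=index) == lab
        for x, lab in zip(test.samples, test.labels))
    return hits / len(test)


def transfer_24bit_accuracy(seed: int, table: ConditionalCtmTable) -> float:
    """Transfer of the same scheme to 20 random 24-bit classes and
    24x4 images, reusing the 6-bit-crop table unchanged."""
    classes = random_class_strings(substream(seed, "init-cond-24/classes"), 20, 24)
    splits = gen_initcond_dataset(seed, class_strings=classes, width=24)
    model = _train_initcond_model(splits, classes, table)
    return evaluate(model, splits["test"]).accuracy


def nk_conditional_ctm_accuracy(seed: int, mode: str,
                                table: ConditionalCtmTable) -> float:
    """NK rule-list or topology classification of 40-bit evolutions by
    direct conditional-CTM lookup against the 10 class objects."""
    splits = gen_nk_class_datasets(seed, mode=mode)
    classes = splits["train"].manifest["classes"]
    model = CentroidModel(classes, list(classes),
                          DistanceSpec(kind="conditional-ctm", cond_table=table))
    return evaluate(model, splits["test"]).accuracy
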
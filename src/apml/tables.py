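"""Domain-specific conditional CTM tables from enumerated spaces.

These wrap the vectorized enumerators in :mod:`apml.dynamics` into the
:class:`~apml.complexity.ConditionalCtmTable` objects the classifiers
consume.  Each table is deterministic (no randomness is involved: the
generative spaces are enumerated exhaustively), so it is built once and
reused across seeds.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .complexity import ConditionalCtmTable, CropSpec
from .dynamics import BOOLEAN_POOL, eca_relation_counts, enumerate_nk_evolutions

__all__ = ["eca_initcond_table", "nk_conditional_tables"]


def eca_initcond_table(width: int = 12, steps: int = 4,
                       rules: Iterable = range(128),
                       crop: int = 3,
                       boundary: str = "background") -> ConditionalCtmTable:
    """Conditional CTM table of the initial-condition task: all
    ``width``-bit strings evolved ``steps`` steps under every rule, with
    inner-bit cropping of both condition and evolution to discard the
    frontier columns.  For width 12 and rules 0-127 this is the
    |P| = 524,288 relation whose fallback penalty is 20 bits."""
    rules = list(rules)
    counts = eca_relation_counts(width=width, steps=steps, rules=rules, crop=crop,
                                 boundary=boundary)
    spec = CropSpec(condition=(crop, width - crop), outcome=(crop, width - crop))
    inner = width - 2 * crop
    return ConditionalCtmTable.from_counts(counts, crop=spec, metadata={
        "source": f"eca(width={width},steps={steps},rules={rules[0]}..{rules[-1]},"
                  f"boundary={boundary})",
        "crop": spec.describe(),
        "condition_full_bits": width, "condition_key_bits": inner,
        "outcome_full_bits": width, "outcome_key_bits": inner * steps,
    })


def nk_conditional_tables(n: int = 4, k: int = 2,
                          function_pool: Sequence = BOOLEAN_POOL,
                          rows: int = 10) -> tuple:
    """(rules_table, topology_table) compiled from the complete
    enumeration of the n, k network space evolved from the zero state.

    Conditions are bit-string encodings: 2 bits per node function for
    the rule-list table, the row-major n x n adjacency for the topology
    table; outcomes are the flattened n*rows evolution vectors.  For
    n=4, k=2 and the four-function pool, |P| = 331,776 and the fallback
    penalty is 19 bits."""
    rule_keys, topo_keys, evolutions = enumerate_nk_evolutions(
        n=n, k=k, function_pool=function_pool, rows=rows)
    evo_strs = ["".join(map(str, row)) for row in evolutions.tolist()]
    out_bits = n * rows
    tables = []
    for cond_keys, cond_bits, source in (
            (rule_keys, 2 * n, "rule-list"),
            (topo_keys, n * n, "topology")):
        counts = Counter(zip(cond_keys, evo_strs))
        tables.append(ConditionalCtmTable.from_counts(counts, metadata={
            "source": f"nk-{source}(n={n},k={k},rows={rows})",
            "condition_full_bits": cond_bits, "condition_key_bits": cond_bits,
            "outcome_full_bits": out_bits, "outcome_key_bits": out_bits,
        }))
    return tables[0], tables[1]
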
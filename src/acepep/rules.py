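"""Frequent-itemset and association-rule mining (FP-growth).

Support of a rule X -> Y is the fraction of transactions containing X u Y;
confidence is support(X u Y) / support(X).  Mining runs over
property-encoded peptide transactions to surface residue-property patterns
(e.g. "aromatic at the C-terminus") shared by strong binders.

FP-growth builds a prefix tree of transactions ordered by item frequency and
mines it recursively through conditional pattern bases; output is exactly
the itemsets whose support meets the threshold, identical to exhaustive
subset enumeration.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import pandas as pd

Item = Hashable
Itemset = frozenset


@dataclass
class AssociationRule:
    antecedent: Itemset
    consequent: Itemset
    support: float
    confidence: float

    def __post_init__(self):
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")


class _Node:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}


def _build_tree(transactions: Sequence[tuple[Sequence[Item], int]],
                min_count: float):
    """Build an FP-tree from (items, multiplicity) pairs; return (root, header)."""
    counts: Counter = Counter()
    for items, mult in transactions:
        for item in items:
            counts[item] += mult
    frequent = {i for i, c in counts.items() if c >= min_count}
    # order: decreasing support, deterministic tie-break on repr
    order = {item: (-counts[item], str(item)) for item in frequent}
    root = _Node(None, None)
    header: dict[Item, list[_Node]] = defaultdict(list)
    for items, mult in transactions:
        path = sorted((i for i in items if i in frequent), key=order.__getitem__)
        node = root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = _Node(item, node)
                node.children[item] = child
                header[item].append(child)
            child.count += mult
            node = child
    return root, header, counts


def _mine(transactions, min_count, suffix: Itemset, out: dict[Itemset, int]):
    _, header, counts = _build_tree(transactions, min_count)
    # least-frequent first so conditional trees shrink
    for item in sorted(header, key=lambda i: (counts[i], str(i))):
        support = sum(node.count for node in header[item])
        new_set = suffix | {item}
        out[new_set] = support
        # conditional pattern base for this item
        conditional: list[tuple[list, int]] = []
        for node in header[item]:
            path = []
            parent = node.parent
            while parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                conditional.append((path, node.count))
        if conditional:
            _mine(conditional, min_count, new_set, out)


def mine_frequent_itemsets(
    transactions: Sequence[Iterable[Item]], min_support: float
) -> dict[Itemset, float]:
    """All itemsets with support >= ``min_support`` and their supports.

    Support is occurrence count / number of transactions.
    """
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    db = [frozenset(t) for t in transactions]
    if not db:
        raise ValueError("transaction database is empty")
    n = len(db)
    # subtract an epsilon so support == min_support is kept despite rounding
    min_count = min_support * n - 1e-9
    counts: dict[Itemset, int] = {}
    _mine([(list(t), 1) for t in db], min_count, frozenset(), counts)
    return {itemset: c / n for itemset, c in counts.items()}


def generate_rules(
    itemsets: dict[Itemset, float],
    min_confidence: float,
    single_consequent: bool = True,
) -> list[AssociationRule]:
    """Rules X -> Y from frequent itemsets, confidence >= ``min_confidence``.

    Antecedent supports come from the same mining pass (every subset of a
    frequent itemset is frequent, so they are always present).  By default
    consequents are single items; ``single_consequent=False`` emits every
    proper split.  Output sorted by (confidence, support) descending with a
    deterministic lexicographic tie-break.
    """
    if not 0 < min_confidence <= 1:
        raise ValueError(f"min_confidence must be in (0, 1], got {min_confidence}")
    rules: list[AssociationRule] = []
    for itemset, support in itemsets.items():
        if len(itemset) < 2:
            continue
        if single_consequent:
            splits = [(itemset - {y}, frozenset({y})) for y in itemset]
        else:
            splits = []
            for r in range(1, len(itemset)):
                for antecedent in itertools.combinations(sorted(itemset, key=str), r):
                    x = frozenset(antecedent)
                    splits.append((x, itemset - x))
        for x, y in splits:
            confidence = support / itemsets[x]
            if confidence >= min_confidence - 1e-12:
                rules.append(AssociationRule(x, y, support, min(confidence, 1.0)))
    rules.sort(
        key=lambda r: (
            -r.confidence,
            -r.support,
            sorted(map(str, r.antecedent)),
            sorted(map(str, r.consequent)),
        )
    )
    return rules


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Rules as a DataFrame with comma-joined itemset columns."""
    return pd.DataFrame(
        {
            "antecedent": [",".join(sorted(map(str, r.antecedent))) for r in rules],
            "consequent": [",".join(sorted(map(str, r.consequent))) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
        }
    )


def read_transactions(path) -> list[frozenset]:
    """Read a transaction CSV: one row per peptide, comma-separated items."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(frozenset(line.split(",")))
    return out
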
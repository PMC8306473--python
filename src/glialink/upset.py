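"""Exclusive-intersection (UpSet) decomposition of DE gene sets.

Given the up- (or down-) regulated gene sets of the four pairwise
comparisons, every gene is assigned to exactly one membership pattern: the
set of comparisons it belongs to and no others.  Five patterns carry the
study's colour labels:

  blue   - DE in KO-NS vs WT-NS only
  pink   - DE in KO-St vs WT-St only
  orange - DE in KO-St vs KO-NS only
  gray   - DE in WT-St vs WT-NS only
  red    - DE in exactly {WT-St vs WT-NS, KO-St vs KO-NS, KO-St vs WT-St}
           (the stimulation-shared, TNFR2-sensitive set)

The default "red" reading is the exclusive triple intersection (standard
UpSet semantics); an inclusive mode (genes in all three regardless of the
fourth set) is available.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import COMPARISONS

CATEGORY_PATTERNS: dict[str, frozenset[str]] = {
    "blue": frozenset({"KO-NS vs WT-NS"}),
    "pink": frozenset({"KO-St vs WT-St"}),
    "orange": frozenset({"KO-St vs KO-NS"}),
    "gray": frozenset({"WT-St vs WT-NS"}),
    "red": frozenset({"WT-St vs WT-NS", "KO-St vs KO-NS", "KO-St vs WT-St"}),
}


@dataclass
class OverlapDecomposition:
    """Named input sets plus their exclusive-intersection classes."""

    sets: dict[str, set[str]]
    classes: dict[frozenset[str], set[str]]
    categories: dict[str, frozenset[str]] = field(default_factory=dict)
    category_genes: dict[str, set[str]] = field(default_factory=dict)

    def class_sizes(self) -> dict[frozenset[str], int]:
        return {p: len(g) for p, g in self.classes.items()}

    def category_sizes(self) -> dict[str, int]:
        return {label: len(g) for label, g in self.category_genes.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(pattern)), len(genes), ";".join(sorted(genes)))
            for pattern, genes in sorted(
                self.classes.items(), key=lambda kv: (-len(kv[1]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["pattern", "size", "genes"])


def upset_decompose(sets) -> OverlapDecomposition:
    """Partition the union of the input sets into exclusive classes.

    ``sets`` is a mapping name -> gene ids, or an iterable of (name, ids)
    pairs (duplicate names rejected).  Empty classes are omitted; the
    emitted classes are pairwise disjoint and their sizes sum to the size
    of the union.
    """
    if not isinstance(sets, Mapping):
        pairs = list(sets)
        names = [name for name, _ in pairs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate set names")
        sets = dict(pairs)
    if len(sets) == 0:
        raise ValueError("need at least one input set")
    sets = {name: set(members) for name, members in sets.items()}

    membership: dict[str, set[str]] = {}
    for name, members in sets.items():
        for gene in members:
            membership.setdefault(gene, set()).add(name)

    classes: dict[frozenset[str], set[str]] = {}
    for gene, names in membership.items():
        classes.setdefault(frozenset(names), set()).add(gene)
    return OverlapDecomposition(sets=sets, classes=classes)


def label_categories(
    dec: OverlapDecomposition, inclusive: bool = False
) -> OverlapDecomposition:
    """Bind the five colour labels to their membership patterns.

    Requires all four comparison names among the decomposition's sets.
    In exclusive mode (default) a label counts the genes of exactly its
    pattern; in inclusive mode it counts genes present in every set of the
    pattern, regardless of other memberships.
    """
    missing = [name for name in COMPARISONS if name not in dec.sets]
    if missing:
        raise ValueError(
            f"missing comparison set(s): {missing}; expected {list(COMPARISONS)}"
        )

    category_genes: dict[str, set[str]] = {}
    for label, pattern in CATEGORY_PATTERNS.items():
        if inclusive:
            genes = set.intersection(*(dec.sets[name] for name in pattern))
        else:
            genes = set(dec.classes.get(pattern, set()))
        category_genes[label] = genes

    return OverlapDecomposition(
        sets=dec.sets,
        classes=dec.classes,
        categories=dict(CATEGORY_PATTERNS),
        category_genes=category_genes,
    )
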
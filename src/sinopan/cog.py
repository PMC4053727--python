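"""COG-category composition of core vs accessory gene families.

Gene-level COG assignments (one-letter categories from COGnitor-style
annotation, consumed as input) are lifted to family level by majority vote,
and category proportions are computed per partition (core vs accessory,
optionally per species group) over assigned families only.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .cluster import ClusterTable

__all__ = ["normalize_category", "family_cog_label", "cog_proportions"]

COG_CATEGORIES = tuple("JAKLBDYVTMNZWUOCGEFHIPQRS")


def normalize_category(category: str | None) -> str | None:
    """Reduce a raw COG annotation to a single category letter.

    Multi-category annotations (e.g. "KT") keep the first letter; empty or
    missing annotations mean unassigned (None).
    """
    if category is None:
        return None
    category = category.strip().upper()
    if not category or category == "NA":
        return None
    return category[0]


def family_cog_label(
    table: ClusterTable, cog: dict[str, str | None]
) -> dict[int, str | None]:
    """Family -> COG category by majority vote over assigned members.

    Ties break alphabetically; a family with no assigned member is
    unassigned (None). Genes absent from ``cog`` count as unassigned.
    """
    labels: dict[int, str | None] = {}
    for fam, _rep, members in table.clusters:
        votes = Counter()
        for gene in members:
            cat = normalize_category(cog.get(gene))
            if cat is not None:
                votes[cat] += 1
        if not votes:
            labels[fam] = None
        else:
            top = max(votes.values())
            labels[fam] = min(c for c, n in votes.items() if n == top)
    return labels


def cog_proportions(
    labels: dict[int, str | None], partition: dict[str, set[int]]
) -> pd.DataFrame:
    """Per-category percentages of assigned families within each partition.

    ``partition`` maps a group name (e.g. "core", "accessory") to a family
    set. For each group, percent = 100 * (assigned families in category) /
    (assigned families in group); unassigned families never enter any
    denominator. Percentages within a group sum to 100. Raises ``ValueError``
    for a group with zero assigned families.
    """
    rows = {}
    categories: set[str] = set()
    for group, fams in partition.items():
        counts = Counter()
        for fam in fams:
            cat = labels.get(fam)
            if cat is not None:
                counts[cat] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"partition {group!r} contains no COG-assigned families")
        rows[group] = {c: 100.0 * n / total for c, n in counts.items()}
        categories |= set(counts)
    order = [c for c in COG_CATEGORIES if c in categories]
    order += sorted(categories - set(order))
    df = pd.DataFrame(rows).reindex(order).fillna(0.0)
    df.index.name = "category"
    return df
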
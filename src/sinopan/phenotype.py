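"""Symbiotic-phenotype clustering and gene-presence association tables.

Raw replicate measurements (strain x host genotype x trait x replicate) are
averaged over replicates, min-max normalized to [0, 1] within each (host
genotype, trait), averaged over genotypes into one profile row per strain,
and clustered hierarchically (Euclidean distance, complete linkage — the
defaults of R's heatmap.2) into phenotype clusters. With k=2 the cluster
with the higher grand-mean profile is PC I (the compatible group), the other
PC II. Per-cluster gene-presence proportion tables then link phenotype
clusters to gene-cluster content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io import SpeciesMap

__all__ = [
    "PhenotypeClusterAssignment",
    "average_replicates",
    "minmax_normalize",
    "strain_profiles",
    "cluster_strains",
    "presence_proportion_table",
    "round_half_away",
]

logger = logging.getLogger(__name__)

_KEY = ["strain", "host_genotype", "trait"]


def _check_columns(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table is missing columns {missing}")


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean value over replicates per (strain, host_genotype, trait).

    Missing replicates are tolerated (the mean is over those present), but a
    combination with no replicates at all — i.e. absent rows — simply does
    not appear; an explicit row with a missing value is an error naming the
    combination.
    """
    _check_columns(table, _KEY + ["value"])
    if table["value"].isna().any():
        bad = table[table["value"].isna()].iloc[0]
        raise ValueError(
            "no usable replicate value for "
            f"({bad['strain']}, {bad['host_genotype']}, {bad['trait']})"
        )
    if (table["value"] < 0).any():
        bad = table[table["value"] < 0].iloc[0]
        raise ValueError(f"negative phenotype value for strain {bad['strain']!r}")
    out = table.groupby(_KEY, as_index=False, sort=True)["value"].mean()
    return out


def minmax_normalize(means: pd.DataFrame) -> pd.DataFrame:
    """Normalize to [0, 1] within each (host_genotype, trait) across strains.

    x' = (x - min) / (max - min); the minimum maps to 0 and the maximum to 1.
    A degenerate group (max == min) is set to 0 everywhere and logged as a
    warning.
    """
    _check_columns(means, _KEY + ["value"])
    out = means.copy()
    grouped = out.groupby(["host_genotype", "trait"])["value"]
    lo = grouped.transform("min")
    hi = grouped.transform("max")
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        for (g, t), _ in out[degenerate].groupby(["host_genotype", "trait"]):
            logger.warning(
                "constant phenotype for genotype %s, trait %s: normalized to 0", g, t
            )
    out["value"] = np.where(degenerate, 0.0, (out["value"] - lo) / span.replace(0, np.nan))
    return out


def strain_profiles(normalized: pd.DataFrame) -> pd.DataFrame:
    """Strain x trait matrix: normalized values averaged over host genotypes.

    Genotypes without data for a strain are excluded from that strain's
    mean. Raises on a strain with no genotype data at all.
    """
    _check_columns(normalized, _KEY + ["value"])
    if normalized.empty:
        raise ValueError("no phenotype data")
    profiles = (
        normalized.groupby(["strain", "trait"])["value"].mean().unstack("trait")
    )
    if profiles.isna().any().any():
        strain = profiles.index[profiles.isna().any(axis=1)][0]
        raise ValueError(f"strain {strain!r} has no data for some trait")
    return profiles


@dataclass
class PhenotypeClusterAssignment:
    """Strain -> phenotype-cluster labels plus the dendrogram merge history."""

    labels: dict[str, str]
    linkage_matrix: np.ndarray
    strain_order: list[str]

    def strains_in(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]


def cluster_strains(profiles: pd.DataFrame, k: int = 2) -> PhenotypeClusterAssignment:
    """Hierarchically cluster strain profiles and cut into k clusters.

    Agglomerative clustering with Euclidean distance and complete linkage on
    the profile rows (heatmap.2 defaults); the dendrogram is cut into k
    clusters. For k=2 the cluster with the higher grand-mean profile is
    labelled PC_I, the other PC_II; for larger k labels are PC_I, PC_II, ...
    in decreasing grand-mean order.
    """
    if k < 1 or k > len(profiles):
        raise ValueError(f"k={k} incompatible with {len(profiles)} strains")
    strains = list(profiles.index)
    Z = linkage(profiles.to_numpy(), method="complete", metric="euclidean")
    flat = fcluster(Z, t=k, criterion="maxclust")
    grand = profiles.mean(axis=1)
    order = sorted(
        set(flat), key=lambda c: -grand[np.array(flat) == c].mean()
    )
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    rename = {c: f"PC_{roman[i]}" for i, c in enumerate(order)}
    labels = {s: rename[c] for s, c in zip(strains, flat)}
    return PhenotypeClusterAssignment(
        labels=labels, linkage_matrix=Z, strain_order=strains
    )


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def presence_proportion_table(
    presence: pd.DataFrame,
    assignment: PhenotypeClusterAssignment | dict[str, str],
    species_map: SpeciesMap,
    gene_sets: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Per-(species, phenotype cluster) gene-set carrier proportions.

    ``presence`` is a strain x family boolean frame. A gene set counts as
    present in a strain only if ALL its member families are present
    (single-family sets degenerate to plain presence). Cells read
    "percent (carriers)" with percent rounded to the nearest integer (ties
    away from zero); empty (species, cluster) groups are blank.
    """
    labels = assignment.labels if isinstance(assignment, PhenotypeClusterAssignment) else assignment
    if gene_sets is None:
        gene_sets = {str(f): [f] for f in presence.columns}
    strains = [s for s in presence.index if s in labels]
    groups: dict[tuple[str, str], list[str]] = {}
    for sp in species_map.species:
        for pc in sorted(set(labels.values())):
            members = [
                s for s in strains
                if species_map.species_of(s) == sp and labels[s] == pc
            ]
            groups[(sp, pc)] = members
    rows = {}
    for set_name, fams in gene_sets.items():
        missing = [f for f in fams if f not in presence.columns]
        if missing:
            raise KeyError(f"gene set {set_name!r}: unknown families {missing}")
        carrier = presence[fams].all(axis=1)
        row = {}
        for (sp, pc), members in groups.items():
            if not members:
                row[(sp, pc)] = ""
                continue
            m = int(carrier.loc[members].sum())
            pct = round_half_away(100.0 * m / len(members))
            row[(sp, pc)] = f"{pct} ({m})"
        rows[set_name] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["species", "cluster"])
    out.index.name = "gene_set"
    return out
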
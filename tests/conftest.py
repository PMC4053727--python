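"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sinopan.cluster import _screened_identity
from sinopan.io import SequenceRecord, SpeciesMap


@pytest.fixture
def species_map():
    return SpeciesMap(
        {
            "strA1": "alpha",
            "strA2": "alpha",
            "strB1": "beta",
            "strB2": "beta",
        }
    )


def make_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def mutate_protein(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Exact-count point substitutions (never back to the original residue)."""
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        out[p] = rng.choice([c for c in aa if c != out[p]])
    return "".join(out)


def record(rec_id: str, residues: str, strain: str = "", alphabet: str = "protein"):
    if not strain and "|" in rec_id:
        strain = rec_id.partition("|")[0]
    return SequenceRecord(id=rec_id, residues=residues, alphabet=alphabet, strain=strain)


def connected_components_at_threshold(records, theta: float) -> list[int]:
    """Brute-force oracle: single-linkage components of the identity >= theta graph.

    Independent of the greedy strategy: every pair is tested (with the
    provable length/edit-distance screen, which cannot change the result)
    and components are built by union-find.
    """
    n = len(records)
    lens = np.array([len(r) for r in records])
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        si = records[i].residues
        ratio = np.minimum(lens[i + 1 :], lens[i]) / np.maximum(lens[i + 1 :], lens[i])
        for j in (np.nonzero(ratio >= theta)[0] + i + 1):
            ident = _screened_identity(si, records[int(j)].residues, theta)
            if ident is not None and ident >= theta:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[ri] = rj
    roots: dict[int, int] = {}
    labels = []
    for i in range(n):
        r = find(i)
        labels.append(roots.setdefault(r, len(roots)))
    return labels
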
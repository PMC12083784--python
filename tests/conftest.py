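"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import networkx as nx
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_records(rows) -> pd.DataFrame:
    """Build a records frame from (client, physician, clinic, drug, date) tuples."""
    df = pd.DataFrame(
        rows, columns=["client_id", "physician_id", "clinic_id", "drug", "dispense_date"]
    )
    df["dispense_date"] = pd.to_datetime(df["dispense_date"])
    return df


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two triangles joined by a single bridge edge; the optimal partition is
    the two triangles with Q = 5/14."""
    G = nx.Graph()
    G.add_edges_from(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")],
        weight=1,
    )
    return G


def all_partitions(items):
    """Enumerate every partition of ``items`` (Bell-number many)."""
    items = list(items)

    def rec(i, groups):
        if i == len(items):
            yield [set(g) for g in groups]
            return
        for g in groups:
            g.append(items[i])
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([items[i]])
        yield from rec(i + 1, groups)
        groups.pop()

    if not items:
        yield []
    else:
        yield from rec(0, [])


def exact_pair_metrics(a: int, b: int, c: int, d: int) -> dict:
    """Independent arithmetic oracle for the 2x2 agreement suite, in exact
    rational arithmetic (None where a denominator vanishes)."""
    from fractions import Fraction

    n = a + b + c + d
    out = {"overall": Fraction(a + d, n)}
    out["positive_agreement"] = Fraction(2 * a, 2 * a + b + c) if 2 * a + b + c else None
    out["negative_agreement"] = Fraction(2 * d, 2 * d + b + c) if 2 * d + b + c else None
    out["sensitivity"] = Fraction(a, a + c) if a + c else None
    out["specificity"] = Fraction(d, b + d) if b + d else None
    out["ppv"] = Fraction(a, a + b) if a + b else None
    out["npv"] = Fraction(d, c + d) if c + d else None
    pi = Fraction(2 * a + b + c, 2 * n)
    pe = 2 * pi * (1 - pi)
    out["ac1"] = (Fraction(a + d, n) - pe) / (1 - pe) if pe != 1 else None
    return out


def brute_force_best_partition(G: nx.Graph):
    """Exhaustive weighted-modularity maximization via networkx's scorer
    (independent of the package's implementation)."""
    best_q, best = float("-inf"), None
    for parts in all_partitions(G.nodes):
        q = nx.community.modularity(G, parts, weight="weight")
        if q > best_q:
            best_q, best = q, parts
    return best_q, best
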
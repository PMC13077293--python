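"""Shared fixtures and an independent brute-force matching oracle.

The oracle re-derives primer placement from first principles (per-position
IUPAC set intersection, full enumeration of placements) without touching
the package's vectorized engine, so engine/oracle agreement is a real
cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cladeprimer import ITS3_CORALF, ITS4, MatchPolicy
from cladeprimer.fixtures import FixtureSpec, make_host_set, make_mock, make_target_set

# Independent IUPAC table (deliberately restated, not imported).
ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def oracle_mask(primer: str, window: str, mode: str = "intersection") -> list[bool]:
    """Positionwise mismatch mask by set intersection (True = mismatch)."""
    out = []
    for p, t in zip(primer, window):
        if mode == "strict":
            out.append(t not in "ACGT" or t not in ORACLE_IUPAC[p])
        else:
            out.append(not (ORACLE_IUPAC[p] & ORACLE_IUPAC[t]))
    return out


def oracle_summarize(mask: list[bool], anchor_len: int) -> tuple[int, bool]:
    if anchor_len == 0:
        return sum(mask), True
    return sum(mask[:-anchor_len]), not any(mask[-anchor_len:])


def oracle_best(
    primer: str,
    template: str,
    budget: int,
    anchor_len: int = 2,
    mode: str = "intersection",
):
    """Enumerate every placement; best under (qualifying, count, leftmost).

    Returns (start, non_anchor_count, anchor_ok, qualified, mask) or None
    when the primer does not fit.
    """
    k = len(primer)
    if k > len(template):
        return None
    best = None
    best_key = None
    for s in range(len(template) - k + 1):
        mask = oracle_mask(primer, template[s:s + k], mode)
        count, anchor_ok = oracle_summarize(mask, min(anchor_len, k))
        qualified = anchor_ok and count <= budget
        key = (not qualified, count, s)
        if best_key is None or key < best_key:
            best_key = key
            best = (s, count, anchor_ok, qualified, mask)
    return best


def random_iupac_seq(rng: np.random.Generator, n: int, ambig_rate: float = 0.0) -> str:
    codes = "ACGT"
    ambig = "RYSWKMBDHVN"
    out = []
    for _ in range(n):
        if ambig_rate and rng.random() < ambig_rate:
            out.append(ambig[rng.integers(0, len(ambig))])
        else:
            out.append(codes[rng.integers(0, 4)])
    return "".join(out)


@pytest.fixture(scope="session")
def target_fixture():
    """The canonical 10-record spectrum fixture (7 exact / 2 one-mm / 1 anchor)."""
    return make_target_set(FixtureSpec(seed=42), ITS3_CORALF, ITS4)


@pytest.fixture(scope="session")
def host_fixture():
    """Three coral-pattern hosts (2-4 terminal mismatches, >=1 in final 2)."""
    return make_host_set(FixtureSpec(seed=42), ITS3_CORALF, ITS4)


@pytest.fixture(scope="session")
def mock_fixture():
    return make_mock(n_species=10, seed=7)


@pytest.fixture()
def default_policy():
    return MatchPolicy()
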
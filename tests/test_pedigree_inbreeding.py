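"""Pedigree inbreeding: closed forms, truncation, and the path-counting oracle."""

import math

import numpy as np
import pytest

from rohdiv.pedigree_inbreeding import (CycleError, Pedigree, cohort_fped_table,
                                        f_ped, pedigree_summaries,
                                        truncate_pedigree)


# ---------------------------------------------------------------------------
# independent oracle: Wright's path-counting formula
# F_X = sum over common ancestors A and over pairs of ascending paths
# (sire->A, dam->A) sharing no individual except A of
# (1/2)^(n1+n2+1) * (1 + F_A)
# ---------------------------------------------------------------------------

def _paths_up(ped, start):
    """All ascending paths: list of (ancestor, nodes on path incl. start, length)."""
    out = [(start, frozenset([start]), 0)]
    stack = [(start, frozenset([start]), 0)]
    while stack:
        node, nodes, length = stack.pop()
        for p in ped._known_parents(node):
            if p in nodes:  # cannot happen in a DAG, defensive
                continue
            out.append((p, nodes | {p}, length + 1))
            stack.append((p, nodes | {p}, length + 1))
    return out


def oracle_inbreeding(ped, iid, _memo=None):
    memo = _memo if _memo is not None else {}
    if iid in memo:
        return memo[iid]
    s, d = ped.get_parents(iid)
    if s is None or d is None or s not in ped or d not in ped:
        memo[iid] = 0.0
        return 0.0
    f = 0.0
    paths_d = _paths_up(ped, d)
    by_anc = {}
    for anc, nodes, length in paths_d:
        by_anc.setdefault(anc, []).append((nodes, length))
    for anc, nodes_s, n1 in _paths_up(ped, s):
        for nodes_d, n2 in by_anc.get(anc, ()):
            if (nodes_s - {anc}) & (nodes_d - {anc}):
                continue
            f += 0.5 ** (n1 + n2 + 1) * (1.0 + oracle_inbreeding(ped, anc, memo))
    memo[iid] = f
    return f


def random_pedigree(rng, n):
    """Generational random pedigree with consanguineous loops.

    Parents are drawn from the previous generation only, so ancestor-path
    counts stay bounded (~2^depth) and the exhaustive path-counting oracle
    remains tractable while loops (shared parents, repeated matings) are
    plentiful.
    """
    n_founders = int(rng.integers(6, 14))
    recs = [(f"I{i}", None, None) for i in range(n_founders)]
    depth = int(rng.integers(2, 7))
    prev = list(range(n_founders))
    total = n_founders
    per_gen = max(3, (n - n_founders) // depth)
    for _ in range(depth):
        cur = []
        for _ in range(per_gen):
            if total >= n:
                break
            a, b = rng.choice(prev, size=2, replace=False)
            recs.append((f"I{total}", f"I{a}", f"I{b}"))
            cur.append(total)
            total += 1
        if len(cur) >= 2:
            prev = cur
    return Pedigree.from_records(recs)


def trio_pedigree():
    return Pedigree.from_records([
        ("gs", None, None), ("gd", None, None),
        ("sire", "gs", "gd"), ("dam", "gs", "gd"),
        ("child", "sire", "dam"),
    ])


def test_textbook_closed_forms():
    """Full-sib 0.25, half-sib 0.125, parent-offspring 0.25, outbred 0."""
    assert f_ped(trio_pedigree(), "child").f_ped == pytest.approx(0.25)

    half = Pedigree.from_records([
        ("gs", None, None), ("gd1", None, None), ("gd2", None, None),
        ("sire", "gs", "gd1"), ("dam", "gs", "gd2"),
        ("child", "sire", "dam")])
    assert f_ped(half, "child").f_ped == pytest.approx(0.125)

    po = Pedigree.from_records([
        ("gs", None, None), ("gd", None, None),
        ("dam", "gs", "gd"), ("child", "gs", "dam")])
    assert f_ped(po, "child").f_ped == pytest.approx(0.25)

    out = Pedigree.from_records([("a", None, None), ("b", None, None),
                                 ("c", "a", "b")])
    assert f_ped(out, "c").f_ped == 0.0


def test_depth_monotonicity_and_truncation():
    """F_PED never decreases with depth; shallow truncation breaks the loop."""
    ped = trio_pedigree()
    f1 = f_ped(ped, "child", 1).f_ped
    f2 = f_ped(ped, "child", 2).f_ped
    finf = f_ped(ped, "child").f_ped
    assert f1 == 0.0  # parents made founders: loop invisible
    assert f2 == finf == pytest.approx(0.25)
    assert f1 <= f2 <= finf

    tr = truncate_pedigree(ped, "child", 1)
    assert tr.get_parents("sire") == (None, None)

    # depth beyond pedigree depth behaves like infinity
    assert f_ped(ped, "child", 50).f_ped == finf


def test_truncation_unknown_focal():
    with pytest.raises(KeyError):
        truncate_pedigree(trio_pedigree(), "nobody", 2)


def test_cycle_detection():
    ped = Pedigree.from_records([("a", "b", None), ("b", "a", None)])
    with pytest.raises(CycleError) as e:
        f_ped(ped, "a")
    assert set(e.value.path) >= {"a", "b"}


def test_summaries_founder_and_binary_tree():
    """Founder -> (0, 0); complete 3-generation ancestry -> (14, 3)."""
    recs = []
    # generation 3 (founders): 8; generation 2: 4; generation 1: 2; focal
    for i in range(8):
        recs.append((f"g3_{i}", None, None))
    for i in range(4):
        recs.append((f"g2_{i}", f"g3_{2*i}", f"g3_{2*i+1}"))
    for i in range(2):
        recs.append((f"g1_{i}", f"g2_{2*i}", f"g2_{2*i+1}"))
    recs.append(("focal", "g1_0", "g1_1"))
    ped = Pedigree.from_records(recs)
    assert pedigree_summaries(ped, "g3_0") == (0, 0)
    assert pedigree_summaries(ped, "focal") == (14, 3)


def test_summaries_collapsed_pedigree_set_semantics(rng):
    """Repeated ancestors are counted once (BFS set oracle)."""
    ped = trio_pedigree()
    n_anc, max_g = pedigree_summaries(ped, "child")
    assert n_anc == 4  # sire, dam, gs, gd — grandparents shared
    assert max_g == 2
    for _ in range(10):
        p = random_pedigree(rng, int(rng.integers(20, 60)))
        focal = p.ids()[-1]
        # explicit BFS oracle
        seen, frontier = set(), {focal}
        while frontier:
            nxt = set()
            for x in frontier:
                for par in p._known_parents(x):
                    if par not in seen:
                        seen.add(par)
                        nxt.add(par)
            frontier = nxt
        assert pedigree_summaries(p, focal)[0] == len(seen)


@pytest.mark.parametrize("seed", range(20))
def test_recursive_kinship_equals_path_counting_oracle(seed):
    """Recursive F equals exhaustive path enumeration on looped pedigrees."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, int(rng.integers(30, 120)))
    memo = {}
    for iid in ped.ids():
        expected = oracle_inbreeding(ped, iid, memo)
        assert f_ped(ped, iid).f_ped == pytest.approx(expected, abs=1e-12)


def test_depth_monotonicity_property(rng):
    for _ in range(10):
        ped = random_pedigree(rng, int(rng.integers(30, 80)))
        focal = ped.ids()[-1]
        fs = [f_ped(ped, focal, g).f_ped for g in (1, 2, 3, 5, 8, math.inf)]
        assert all(a <= b + 1e-12 for a, b in zip(fs, fs[1:]))


def test_cohort_table_means_and_errors():
    ped = trio_pedigree()
    per, summary = cohort_fped_table(ped, ["child"], depths=(1, math.inf))
    assert per.loc["child", "F_ped_ginf"] == pytest.approx(0.25)
    assert summary.loc["mean", "F_ped_ginf"] == pytest.approx(0.25)
    with pytest.raises(ValueError):
        cohort_fped_table(ped, [], depths=(1,))
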
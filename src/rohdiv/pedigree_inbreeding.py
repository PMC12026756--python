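"""Wright's pedigree inbreeding coefficient with generation-depth truncation.

F_PED of an individual is the kinship of its parents, computed with the
standard recursion

    phi(a, a) = (1 + F_a) / 2
    phi(a, b) = [phi(sire(a), b) + phi(dam(a), b)] / 2   (a not an ancestor of b)

with unknown parents contributing 0.  Truncating the pedigree to the most
recent ``g`` generations (ancestors further than ``g`` parent links away are
cut; those at exactly ``g`` become founders) reproduces the familiar
"5-generation / 10-generation F" of pedigree software, and F_PED is
monotone nondecreasing in ``g`` because deeper pedigrees only add positive
path terms.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN_CODES = {None, "", "0", "NA", "na", "nan"}


def _clean(pid) -> str | None:
    if pid is None:
        return None
    if isinstance(pid, float) and math.isnan(pid):
        return None
    s = str(pid).strip()
    return None if s in UNKNOWN_CODES else s


class CycleError(ValueError):
    """Raised when an individual is its own ancestor; carries the path."""

    def __init__(self, path):
        self.path = list(path)
        super().__init__("pedigree cycle: " + " -> ".join(map(str, path)))


@dataclass
class Pedigree:
    """Parent map over individuals: id -> (sire | None, dam | None)."""

    parents: dict
    years: dict | None = None

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from (id, sire, dam[, year]) iterables; '0'/''/'NA' = unknown."""
        parents, years = {}, {}
        for rec in records:
            iid = str(rec[0])
            if iid in parents:
                raise ValueError(f"duplicate individual id {iid!r}")
            parents[iid] = (_clean(rec[1]), _clean(rec[2]))
            if len(rec) > 3 and rec[3] is not None:
                years[iid] = rec[3]
        return cls(parents, years or None)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        recs = df[["id", "sire", "dam"] + (["year"] if "year" in cols else [])]
        return cls.from_records(recs.itertuples(index=False))

    def to_csv(self, path) -> None:
        rows = [{"id": i, "sire": s or "0", "dam": d or "0",
                 "year": (self.years or {}).get(i, "")}
                for i, (s, d) in self.parents.items()]
        pd.DataFrame(rows).to_csv(path, index=False)

    def __contains__(self, iid) -> bool:
        return str(iid) in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def ids(self):
        return list(self.parents)

    def get_parents(self, iid):
        return self.parents.get(str(iid), (None, None))

    def founders(self):
        return [i for i, (s, d) in self.parents.items() if s is None and d is None]

    def check_acyclic(self) -> None:
        """DFS cycle check; raises CycleError with the offending path."""
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.parents, WHITE)
        for root in self.parents:
            if color[root] != WHITE:
                continue
            stack = [(root, iter(self._known_parents(root)))]
            color[root] = GREY
            path = [root]
            while stack:
                node, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    color[node] = BLACK
                    stack.pop()
                    path.pop()
                    continue
                if color.get(nxt, BLACK) == GREY:
                    raise CycleError(path[path.index(nxt):] + [nxt])
                if color.get(nxt, BLACK) == WHITE:
                    color[nxt] = GREY
                    stack.append((nxt, iter(self._known_parents(nxt))))
                    path.append(nxt)

    def _known_parents(self, iid):
        return [p for p in self.get_parents(iid) if p is not None and p in self.parents]


@dataclass
class FpedResult:
    id: str
    f_ped: float
    depth: float  # generations used; math.inf for full pedigree
    unique_ancestors: int
    max_generations: int


def _min_depths(ped: Pedigree, focal: str) -> dict:
    """Minimum parent-link distance from focal to each ancestor (BFS)."""
    dist = {focal: 0}
    queue = deque([focal])
    while queue:
        node = queue.popleft()
        for p in ped._known_parents(node):
            if p not in dist:
                dist[p] = dist[node] + 1
                queue.append(p)
    return dist


def truncate_pedigree(ped: Pedigree, focal, depth) -> Pedigree:
    """Restrict the pedigree of ``focal`` to the most recent ``depth`` generations.

    Ancestors whose *minimum* distance exceeds ``depth`` are removed;
    individuals at exactly ``depth`` keep their id but lose their parents.
    """
    focal = str(focal)
    if focal not in ped:
        raise KeyError(f"unknown focal id {focal!r}")
    if depth == math.inf:
        return ped
    if depth < 1:
        raise ValueError("depth must be >= 1 or inf")
    dist = _min_depths(ped, focal)
    parents = {}
    for iid, d in dist.items():
        s, dm = ped.get_parents(iid)
        if d >= depth:
            s = dm = None
        else:
            s = s if s is not None and dist.get(s, math.inf) <= depth else None
            dm = dm if dm is not None and dist.get(dm, math.inf) <= depth else None
        parents[iid] = (s, dm)
    return Pedigree(parents, ped.years)


class _KinshipCalculator:
    """Memoized kinship/inbreeding over one (possibly truncated) pedigree."""

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self._phi: dict = {}
        self._f: dict = {}
        self._depth: dict = {}

    def inbreeding(self, iid) -> float:
        iid = str(iid)
        if iid in self._f:
            return self._f[iid]
        s, d = self.ped.get_parents(iid)
        f = 0.0
        if s is not None and d is not None and s in self.ped and d in self.ped:
            f = self.kinship(s, d)
        self._f[iid] = f
        return f

    def generation_number(self, iid) -> int:
        """Longest ancestor path below ``iid`` (founder = 0)."""
        iid = str(iid)
        if iid in self._depth:
            return self._depth[iid]
        # iterative longest-path over the ancestor DAG (post-order via stack)
        stack = [iid]
        while stack:
            node = stack[-1]
            if node in self._depth:
                stack.pop()
                continue
            ps = self.ped._known_parents(node)
            pending = [p for p in ps if p not in self._depth]
            if pending:
                stack.extend(pending)
            else:
                self._depth[node] = 0 if not ps else 1 + max(self._depth[p] for p in ps)
                stack.pop()
        return self._depth[iid]

    def kinship(self, a, b) -> float:
        return self._kin(str(a), str(b))

    def _kin(self, a, b) -> float:
        # always expand the individual with the deeper ancestor DAG: it can
        # never be an ancestor of the shallower one, which makes the
        # two-term recursion valid
        if self.generation_number(a) < self.generation_number(b):
            a, b = b, a
        key = (a, b) if a <= b else (b, a)
        if key in self._phi:
            return self._phi[key]
        if a == b:
            val = 0.5 * (1.0 + self.inbreeding(a))
        else:
            s, d = self.ped.get_parents(a)
            val = 0.0
            if s is not None and s in self.ped:
                val += 0.5 * self._kin(s, b)
            if d is not None and d in self.ped:
                val += 0.5 * self._kin(d, b)
        self._phi[key] = val
        return val


def f_ped(ped: Pedigree, focal, depth=math.inf) -> FpedResult:
    """Wright's F for ``focal`` on the pedigree truncated at ``depth``."""
    focal = str(focal)
    if focal not in ped:
        raise KeyError(f"unknown focal id {focal!r}")
    ped.check_acyclic()
    tr = truncate_pedigree(ped, focal, depth)
    calc = _KinshipCalculator(tr)
    f = calc.inbreeding(focal)
    n_anc, max_g = pedigree_summaries(ped, focal, depth)
    return FpedResult(focal, f, depth, n_anc, max_g)


def pedigree_summaries(ped: Pedigree, focal, depth=math.inf):
    """(unique ancestor count, longest ancestor path) within ``depth``."""
    focal = str(focal)
    if focal not in ped:
        raise KeyError(f"unknown focal id {focal!r}")
    tr = truncate_pedigree(ped, focal, depth)
    dist = _min_depths(tr, focal)
    n_anc = len(dist) - 1  # focal excluded
    max_g = _KinshipCalculator(tr).generation_number(focal)
    return n_anc, max_g


def cohort_fped_table(ped_or_values, ids=None, depths=(5, 10, math.inf)) -> pd.DataFrame:
    """Per-individual F_PED at each depth plus cohort mean/SD rows.

    ``ped_or_values`` is either a Pedigree (ids required) or a mapping
    depth -> iterable of already-computed F values (used to summarise
    published per-individual columns). SD is the sample SD (ddof=1).
    """
    if isinstance(ped_or_values, Pedigree):
        if not ids:
            raise ValueError("empty id list")
        data = {}
        for d in depths:
            data[d] = [f_ped(ped_or_values, i, d).f_ped for i in ids]
        index = list(map(str, ids))
    else:
        data = {d: list(v) for d, v in ped_or_values.items()}
        n = len(next(iter(data.values())))
        if n == 0:
            raise ValueError("empty id list")
        index = ids if ids else [str(i) for i in range(n)]
    df = pd.DataFrame(data, index=index)
    df.columns = [f"F_ped_g{'inf' if d == math.inf else f'{d:g}'}" for d in df.columns]
    summary = pd.DataFrame(
        {c: {"mean": df[c].mean(), "sd": df[c].std(ddof=1)} for c in df.columns})
    return df, summary
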
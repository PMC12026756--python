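"""Small statistics helpers: one-way ANOVA and Tukey compact letters."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def one_way_anova(groups) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA: returns (F, p).

    Requires >= 2 groups of >= 2 values each; degenerate input with zero
    variance everywhere raises rather than returning NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = [g.mean() for g in groups]
    if within == 0 and len(set(means)) == 1:
        raise ValueError("zero variance everywhere; F undefined")
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def tukey_groups(groups, labels=None, alpha: float = 0.01) -> dict:
    """Tukey HSD pairwise tests summarised as a compact letter display.

    Groups sharing a letter do not differ at level ``alpha``. Letters are
    assigned by the insert-and-absorb algorithm over the significance
    matrix, with groups ordered by mean.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if k < 2:
        return {labels[0]: "a"} if k == 1 else {}
    res = sps.tukey_hsd(*groups)
    differ = res.pvalue < alpha

    order = np.argsort([g.mean() for g in groups])[::-1]
    # letters: list of sets of group indices that may share a letter
    letters: list[set] = []
    for gi in order:
        placed = False
        for s in letters:
            if all(not differ[gi, gj] for gj in s):
                s.add(gi)
                placed = True
        if not placed:
            letters.append({gi})
    # absorb subsets
    letters = [s for i, s in enumerate(letters)
               if not any(i != j and s < t for j, t in enumerate(letters))]
    out = {lab: "" for lab in labels}
    for li, s in enumerate(letters):
        ch = chr(ord("a") + li)
        for gi in sorted(s):
            out[labels[gi]] += ch
    return out
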
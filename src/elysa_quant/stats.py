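"""Group comparison: one-way ANOVA, Tukey HSD and compact letter display.

The statistical unit is the cell (one summary value per oocyte/embryo), not
the object: per-object values within a cell are not independent.  Groups
with different letters differ at alpha = 0.05 under Tukey's multiple
comparison test; groups sharing any letter are not distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupComparison:
    groups: tuple[str, ...]
    means: dict
    sems: dict
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame            # group1, group2, meandiff, p_adj, reject
    letters: dict                  # group -> letter string, e.g. "a", "ab"
    note: str | None = None


def compact_letter_display(groups, significant_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant_pairs`` are unordered group pairs that differ
    significantly; the result assigns each group a string of letters such
    that two groups share a letter iff they are NOT significantly
    different.
    """
    groups = list(groups)
    letters: list[set] = [set(groups)]
    for a, b in significant_pairs:
        for bucket in [l for l in letters if a in l and b in l]:
            letters.remove(bucket)
            for new in (bucket - {b}, bucket - {a}):
                if new and not any(new <= other for other in letters):
                    letters.append(new)
    # absorb buckets fully contained in another
    letters = [l for l in letters if not any(l < m for m in letters)]
    # stable ordering: by first member's position in the group list
    letters.sort(key=lambda l: min(groups.index(g) for g in l))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, bucket in enumerate(letters):
        for g in groups:
            if g in bucket:
                out[g] += alphabet[i % len(alphabet)]
    return out


def compare_groups(values_by_group: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons.

    Requires >= 2 groups with >= 2 values each.  Mean and SEM per group are
    reported alongside the letters.  If every value in every group is
    identical the variance is degenerate; this is reported as no difference
    (all groups share one letter) with an explanatory note rather than an
    error.
    """
    groups = tuple(values_by_group)
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs at least two values")

    means = {g: float(a.mean()) for g, a in arrays.items()}
    sems = {g: float(a.std(ddof=1) / np.sqrt(a.size)) for g, a in arrays.items()}

    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        tukey = pd.DataFrame({"group1": [], "group2": [], "meandiff": [],
                              "p_adj": [], "reject": []})
        return GroupComparison(
            groups, means, sems, anova_f=np.nan, anova_p=np.nan, tukey=tukey,
            letters={g: "a" for g in groups},
            note="degenerate variance: all values identical; no differences")

    f, p = sps.f_oneway(*arrays.values())
    labels = np.concatenate([[g] * arrays[g].size for g in groups])
    res = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
    tukey = pd.DataFrame(res.summary().data[1:],
                         columns=[str(c) for c in res.summary().data[0]])
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    tukey["p_adj"] = tukey["p_adj"].astype(float)
    tukey["reject"] = tukey["reject"].astype(bool)

    sig = [(str(r["group1"]), str(r["group2"]))
           for _, r in tukey.iterrows() if r["reject"]]
    letters = compact_letter_display(groups, sig)
    return GroupComparison(groups, means, sems, float(f), float(p), tukey,
                           letters)
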
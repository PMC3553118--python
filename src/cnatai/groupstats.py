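"""Group-comparison battery for clinicopathological tables.

Two conventions are fixed because they reproduce published ovarian-cancer
cohort tables to three decimals:

* Fisher's exact test, two-sided, defined as the sum of the point
  hypergeometric probabilities of all tables (same margins) no more likely
  than the observed one, with a small relative slack (1e-7) on the
  comparison to absorb floating-point rounding.
* Mann-Whitney on grouped ordinal codes with midranks, tie-corrected
  variance, a 0.5 continuity correction and the normal approximation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_FISHER_RTOL = 1e-7


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; columns are TAI low/high, rows outcome levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")


def fisher_exact_two_sided(table: ContingencyTable2x2 | list | np.ndarray) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    A zero margin gives p = 1 by convention (no information), with a warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = np.asarray(table, dtype=int)
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        log.warning("degenerate 2x2 table (zero margin); p = 1 by convention")
        return 1.0
    hg = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = hg.pmf(support)
    p_obs = hg.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + _FISHER_RTOL)].sum())
    return min(p, 1.0)


@dataclass
class OrdinalGroupCounts:
    """Per-level counts of two groups over a shared ordered level list."""

    levels: list
    counts_low: list[int]
    counts_high: list[int]

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.counts_low) == len(self.counts_high)):
            raise ValueError("levels and counts must align")
        if min(self.counts_low) < 0 or min(self.counts_high) < 0:
            raise ValueError("counts must be non-negative")
        if sum(self.counts_low) < 1 or sum(self.counts_high) < 1:
            raise ValueError("each group needs at least one observation")


def mann_whitney_grouped(counts: OrdinalGroupCounts) -> float:
    """Tie-corrected, continuity-corrected normal-approximation p-value."""
    codes = np.arange(len(counts.levels))
    x = np.repeat(codes, counts.counts_low)
    y = np.repeat(codes, counts.counts_high)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        log.warning("all pooled observations share one level; p = 1")
        return 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    return float(res.pvalue)


def tai_by_category(tai: pd.Series | np.ndarray, category: pd.Series | list) -> pd.DataFrame:
    """Mean, SD (n-1) and n of TAI per category; empty categories omitted."""
    df = pd.DataFrame({"tai": np.asarray(tai, dtype=float), "category": list(category)})
    df = df.dropna(subset=["tai"])
    out = (
        df.groupby("category", sort=False)["tai"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0) if len(out) else out["sd"]
    return out


AGE_GROUP_EDGES = (45.0, 55.0)  # <45, 45-55, >55


def age_group(age: float) -> int:
    if age < AGE_GROUP_EDGES[0]:
        return 0
    if age <= AGE_GROUP_EDGES[1]:
        return 1
    return 2


def build_table1(clinical: pd.DataFrame, tai: pd.DataFrame) -> dict:
    """Cohort summary by TAI group with the test battery.

    Mann-Whitney tests for the ordinal characteristics (age group, stage,
    grade) and Fisher exact tests for the binary ones (chemotherapy
    response, progression).  Progression is taken from the PFS event
    indicator.  Returns ``{"summary": DataFrame, "pvalues": dict,
    "group_sizes": dict}``; missing values reduce the n of their
    characteristic only.  No multiplicity adjustment is applied.
    """
    df = clinical.merge(tai[["sample_id", "group"]], on="sample_id", how="inner")
    if df.empty:
        raise ValueError("no overlapping samples between clinical and TAI tables")
    low = df[df["group"] == "low"]
    high = df[df["group"] == "high"]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both TAI groups must be non-empty")

    def ordinal_counts(col: str, levels: list) -> OrdinalGroupCounts:
        cl = [int((low[col] == lv).sum()) for lv in levels]
        ch = [int((high[col] == lv).sum()) for lv in levels]
        return OrdinalGroupCounts(levels=levels, counts_low=cl, counts_high=ch)

    df = df.assign(age_grp=df["age"].map(age_group))
    low, high = df[df["group"] == "low"], df[df["group"] == "high"]

    pvalues: dict[str, float] = {}
    pvalues["age_groups"] = mann_whitney_grouped(ordinal_counts("age_grp", [0, 1, 2]))
    pvalues["stage"] = mann_whitney_grouped(ordinal_counts("stage", [2, 3, 4]))
    grade_counts = ordinal_counts("grade", [1, 2, 3])
    pvalues["grade"] = mann_whitney_grouped(grade_counts)
    chemo = ContingencyTable2x2(
        int((low["chemo_response"] == "sensitive").sum()),
        int((high["chemo_response"] == "sensitive").sum()),
        int((low["chemo_response"] == "resistant").sum()),
        int((high["chemo_response"] == "resistant").sum()),
    )
    pvalues["chemo_response"] = fisher_exact_two_sided(chemo)
    prog = ContingencyTable2x2(
        int((low["pfs_event"] == 1).sum()),
        int((high["pfs_event"] == 1).sum()),
        int((low["pfs_event"] == 0).sum()),
        int((high["pfs_event"] == 0).sum()),
    )
    pvalues["progression"] = fisher_exact_two_sided(prog)

    rows = []

    def add_counts(char: str, label: str, nl: int, nh: int) -> None:
        rows.append(
            {
                "characteristic": char,
                "level": label,
                "all": nl + nh,
                "low": nl,
                "high": nh,
                "low_pct": 100.0 * nl / len(low),
                "high_pct": 100.0 * nh / len(high),
                "p": pvalues.get(char, np.nan),
            }
        )

    add_counts("patients", "total", len(low), len(high))
    for code, label in zip([0, 1, 2], ["<45", "45-55", ">55"]):
        add_counts("age_groups", label, int((low["age_grp"] == code).sum()),
                   int((high["age_grp"] == code).sum()))
    for st in (2, 3, 4):
        add_counts("stage", {2: "II", 3: "III", 4: "IV"}[st],
                   int((low["stage"] == st).sum()), int((high["stage"] == st).sum()))
    for g in (1, 2, 3):
        add_counts("grade", str(g), int((low["grade"] == g).sum()),
                   int((high["grade"] == g).sum()))
    for resp in ("sensitive", "resistant"):
        add_counts("chemo_response", resp,
                   int((low["chemo_response"] == resp).sum()),
                   int((high["chemo_response"] == resp).sum()))
    for ev, label in ((1, "progression"), (0, "no progression")):
        add_counts("progression", label,
                   int((low["pfs_event"] == ev).sum()), int((high["pfs_event"] == ev).sum()))
    for col, char in (("age", "age_median"), ("pfs_months", "pfs_median"),
                      ("os_months", "os_median")):
        rows.append(
            {
                "characteristic": char,
                "level": "median",
                "all": df[col].median(),
                "low": low[col].median(),
                "high": high[col].median(),
                "low_pct": np.nan,
                "high_pct": np.nan,
                "p": np.nan,
            }
        )

    return {
        "summary": pd.DataFrame(rows),
        "pvalues": pvalues,
        "group_sizes": {"low": len(low), "high": len(high)},
    }
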
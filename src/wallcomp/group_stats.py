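"""Replicate summaries and two-tier significance flagging.

Composition comparisons report mean ± SD over biological replicates and a
classical pooled-variance Student's t-test.  Significance is flagged on two
tiers following the composition-figure convention: ``*`` for p < 0.05 and
``**`` for 0.05 <= p < 0.1 (the tiers are mutually exclusive).  No
multiple-testing correction is applied to composition comparisons — each
comparison is reported at its nominal p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .composition_io import ValidationError


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_a: tuple[str, int]
    group_b: tuple[str, int]
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_stat: float
    p_value: float
    tier: str | None


def tier_for_p(p: float) -> str | None:
    """Two-tier flag: '*' iff p < 0.05, '**' iff 0.05 <= p < 0.1."""
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "**"
    return None


def summarize(values) -> tuple[float, float, int, list[str]]:
    """Arithmetic mean, sample SD (n-1 denominator) and n.

    A single observation has no sample SD; it is reported as 0 with
    warning ``N1``.
    """
    vals = [float(v) for v in values]
    n = len(vals)
    if n == 0:
        raise ValidationError("cannot summarize an empty list")
    mean = sum(vals) / n
    if n == 1:
        return mean, 0.0, 1, ["N1"]
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var), n, []


def student_t(a, b, *, welch: bool = False) -> tuple[float, float, str | None]:
    """Two-sided Student's t-test on two groups of replicate values.

    Pooled-variance by default (classical Student); Welch available via
    flag.  Zero pooled variance with equal means yields t=0, p=1.
    Returns (t, p, tier).
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 replicates")
    na, nb = len(a), len(b)
    ma, sa, _, _ = summarize(a)
    mb, sb, _, _ = summarize(b)
    if welch:
        se2 = sa * sa / na + sb * sb / nb
        if se2 == 0.0:
            t = 0.0 if ma == mb else math.inf * (1 if ma > mb else -1)
            p = 1.0 if ma == mb else 0.0
            return t, p, tier_for_p(p)
        t = (ma - mb) / math.sqrt(se2)
        num = se2 * se2
        den = (sa * sa / na) ** 2 / (na - 1) + (sb * sb / nb) ** 2 / (nb - 1)
        df = num / den
    else:
        sp2 = ((na - 1) * sa * sa + (nb - 1) * sb * sb) / (na + nb - 2)
        if sp2 == 0.0:
            t = 0.0 if ma == mb else math.inf * (1 if ma > mb else -1)
            p = 1.0 if ma == mb else 0.0
            return t, p, tier_for_p(p)
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, min(p, 1.0), tier_for_p(p)


def compare_groups(
    variable: str,
    group_a: tuple[str, int],
    group_b: tuple[str, int],
    a,
    b,
    *,
    welch: bool = False,
) -> GroupComparison:
    ma, sa, na, _ = summarize(a)
    mb, sb, nb, _ = summarize(b)
    t, p, tier = student_t(a, b, welch=welch)
    return GroupComparison(
        variable=variable,
        group_a=group_a,
        group_b=group_b,
        mean_a=ma,
        mean_b=mb,
        sd_a=sa,
        sd_b=sb,
        n_a=na,
        n_b=nb,
        t_stat=t,
        p_value=p,
        tier=tier,
    )


def compare_all(
    yields: pd.DataFrame,
    pairs: list[tuple[tuple[str, int], tuple[str, int]]],
    variables: list[str] | None = None,
    *,
    welch: bool = False,
) -> list[GroupComparison]:
    """One GroupComparison per (variable, group pair), deterministic order.

    ``yields`` is a yield table (or any replicate table) with tissue/stage/
    replicate columns; groups are (tissue, stage) cells.  Every group in
    ``pairs`` must carry at least 2 replicates.
    """
    if variables is None:
        skip = {"tissue", "stage", "replicate", "warnings", "closure_total",
                "sample_id"}
        variables = [c for c in yields.columns if c not in skip]
    out: list[GroupComparison] = []
    for var in variables:
        for ga, gb in pairs:
            va = _group_values(yields, ga, var)
            vb = _group_values(yields, gb, var)
            out.append(compare_groups(var, ga, gb, va, vb, welch=welch))
    return out


def _group_values(df: pd.DataFrame, group: tuple[str, int], var: str):
    tissue, stage = group
    sel = df[(df["tissue"] == tissue) & (df["stage"].astype(int) == int(stage))]
    if len(sel) == 0:
        raise ValidationError(f"missing group {tissue}{stage}")
    return sel[var].astype(float).tolist()


def comparisons_to_table(comps: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comps:
        rows.append(
            {
                "variable": c.variable,
                "group_a": f"{c.group_a[0]}{c.group_a[1]}",
                "group_b": f"{c.group_b[0]}{c.group_b[1]}",
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "sd_a": c.sd_a,
                "sd_b": c.sd_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "t": c.t_stat,
                "p": c.p_value,
                "tier": c.tier or "",
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "GroupComparison",
    "tier_for_p",
    "summarize",
    "student_t",
    "compare_groups",
    "compare_all",
    "comparisons_to_table",
]
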
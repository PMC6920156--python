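"""Two-location replication of heterotic loci.

A set of QTLs mapped genome-wide in a first environment is re-assayed
in a second one by genotyping the population only at those target loci.
Per locus the second-location evidence is a one-way fixed-effects ANOVA
across the MM/MF/FF classes; loci with P >= 0.05 cannot have their
heterotic effects evaluated and are excluded from the cross-location
comparison. Concordance of heterotic mode between environments is the
Pearson correlation of log(d/a + 1) over the evaluable loci — the log
compresses the heavy right tail of the ratio, and Pearson r is
invariant to the log base. No multiple-testing correction is applied at
alpha = 0.05 by default; a Bonferroni option exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._codes import FF, MF, MM, MISSING
from . import heterosis
from .simdata import table1_fixture

__all__ = [
    "ConcordanceResult",
    "anova_per_locus",
    "evaluate_locus",
    "significance_tally",
    "concordance",
    "table1_records",
]


def anova_per_locus(genotypes: np.ndarray, y: np.ndarray) -> float:
    """One-way ANOVA P-value across the three genotype classes.

    Requires all three classes present with >= 2 observations each;
    returns NaN otherwise (the locus is flagged, not an error).
    """
    g = np.asarray(genotypes)
    y = np.asarray(y, dtype=float)
    groups = [y[g == c] for c in (MM, MF, FF)]
    if any(len(grp) < 2 for grp in groups):
        return float("nan")
    if all(np.ptp(grp) == 0 for grp in groups) and len({grp[0] for grp in groups}) == 1:
        return 1.0  # zero between- and within-class variance: F = 0
    return float(stats.f_oneway(*groups).pvalue)


def evaluate_locus(
    genotypes: np.ndarray,
    y: np.ndarray,
    polarity: str = "higher",
    min_class_n: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Second-location assessment of one target locus.

    Returns the ANOVA P, the heterotic-effect estimate and an
    ``evaluable`` flag (P < alpha); class/parent are None when not
    evaluable, matching how replication tables report such loci.
    """
    p = anova_per_locus(genotypes, y)
    eff = heterosis.estimate_effects(genotypes, y, polarity=polarity, min_class_n=min_class_n)
    evaluable = bool(np.isfinite(p) and p < alpha)
    return {
        "p": p,
        "evaluable": evaluable,
        "d_over_a": eff.d_over_a if evaluable else float("nan"),
        "class": eff.heterotic_class if evaluable else None,
        "advantageous": eff.advantageous if evaluable else None,
        "effect": eff,
    }


def significance_tally(p_values, alpha: float = 0.05, bonferroni: bool = False) -> int:
    """Number of loci with ANOVA P below alpha (raw by default)."""
    p = np.asarray(p_values, dtype=float)
    thr = alpha / len(p) if bonferroni else alpha
    return int(np.nansum(p < thr))


@dataclass
class ConcordanceResult:
    """Cross-location agreement of the dominance degree."""

    n_used: int
    r: float
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (locus id, reason)


def concordance(
    records: pd.DataFrame,
    log_base: float | None = None,
) -> ConcordanceResult:
    """Pearson r of log(d/a + 1) between two locations.

    ``records`` needs columns ``d_over_a_1``, ``d_over_a_2`` and
    ``evaluable`` (plus optionally ``locus`` for the exclusion list).
    Non-evaluable loci and loci with d/a <= -1 in either location
    (log undefined) are excluded with a reason. The correlation is
    base-invariant; ``log_base`` exists only for emitted log values.
    """
    ids = records["locus"] if "locus" in records.columns else records.index.astype(str)
    excluded: list[tuple[str, str]] = []
    keep = np.ones(len(records), dtype=bool)
    d1 = records["d_over_a_1"].to_numpy(dtype=float)
    d2 = records["d_over_a_2"].to_numpy(dtype=float)
    ev = records["evaluable"].to_numpy(dtype=bool)
    for i, locus in enumerate(ids):
        if not ev[i]:
            keep[i] = False
            excluded.append((str(locus), "not evaluable (P >= 0.05)"))
        elif not (np.isfinite(d1[i]) and np.isfinite(d2[i])):
            keep[i] = False
            excluded.append((str(locus), "d/a undefined"))
        elif d1[i] <= -1 or d2[i] <= -1:
            keep[i] = False
            excluded.append((str(locus), "d/a <= -1: log(d/a + 1) undefined"))
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"only {n} evaluable loci; need >= 3")
    base = np.log(log_base) if log_base else 1.0
    x = np.log1p(d1[keep]) / base
    y = np.log1p(d2[keep]) / base
    r = float(stats.pearsonr(x, y).statistic)
    return ConcordanceResult(n_used=n, r=r, excluded=excluded)


def table1_records() -> pd.DataFrame:
    """The embedded published replication table in concordance shape."""
    t = table1_fixture()
    return pd.DataFrame(
        {
            "locus": [
                f"{tr}:chr{c}:{mb}Mb" for tr, c, mb in zip(t["trait"], t["chrom"], t["peak_mb"])
            ],
            "d_over_a_1": t["shandong_d_over_a"],
            "d_over_a_2": t["heilongjiang_d_over_a"],
            "p_2": t["heilongjiang_p"],
            "evaluable": t["heilongjiang_evaluable"],
        }
    )
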
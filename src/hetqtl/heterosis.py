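"""Heterotic-effect estimation, classification and heterosis indices.

At a locus with genotype-class means m_MM, m_MF and m_FF, the additive
effect is ``a = |m_MM - m_FF| / 2`` (a magnitude; the direction is
carried by the advantageous parent) and the dominance deviation is
``d = m_MF - (m_MM + m_FF) / 2``. Their ratio, the dominance degree
d/a, places the locus into one of five heterotic modes:

=====================================  =====================
mode                                   d/a interval
=====================================  =====================
Overdominance                          d/a > 1.25
Complete–incomplete dominance          0.25 < d/a <= 1.25
Additive effect                        -0.25 < d/a <= 0.25
Incomplete recessive                   -1.25 < d/a <= -0.25
Underdominance                         d/a <= -1.25
=====================================  =====================

d is oriented so that a positive value means the heterozygote is
shifted toward the *better* phenotype, where "better" is declared per
trait by a polarity registry (more yield, taller plants; for flowering
time, late flowering is counted as the advantage direction). Locus-
level mid-parent heterosis is d expressed as a percentage of the
mid-homozygote mean; trait-level MPH/BPH compare the F1 line with the
mid-parent and better-parent values.

When the two homozygote means nearly coincide (a -> 0) the ratio d/a
explodes; such loci are flagged as unstable rather than classified
silently, mirroring the behaviour of real scans where near-equal
homozygotes produce outrageously large dominance degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codes import FF, MF, MM, MISSING

__all__ = [
    "OVERDOMINANCE",
    "COMPLETE_INCOMPLETE_DOMINANCE",
    "ADDITIVE",
    "INCOMPLETE_RECESSIVE",
    "UNDERDOMINANCE",
    "CLASS_NAMES",
    "EffectEstimate",
    "HeterosisIndices",
    "classify",
    "estimate_effects",
    "locus_mph",
    "trait_heterosis",
    "allele_direction_summary",
    "dova_vs_lod_profile",
    "TRAIT_POLARITY",
]

OVERDOMINANCE = "Overdominance"
COMPLETE_INCOMPLETE_DOMINANCE = "Complete–incomplete dominance"
ADDITIVE = "Additive effect"
INCOMPLETE_RECESSIVE = "Incomplete recessive"
UNDERDOMINANCE = "Underdominance"
CLASS_NAMES = [
    UNDERDOMINANCE,
    INCOMPLETE_RECESSIVE,
    ADDITIVE,
    COMPLETE_INCOMPLETE_DOMINANCE,
    OVERDOMINANCE,
]

# Per-trait advantage direction: "higher" (default — yield, size) or
# "lower". Late flowering is registered as the advantageous direction,
# so flowering traits keep "higher" polarity on days-to-flowering.
TRAIT_POLARITY: dict[str, str] = {
    "kernel_yield_per_ear": "higher",
    "plant_height": "higher",
    "flowering_time": "higher",  # late flowering counted as the advantage
}


def classify(d_over_a: float) -> str:
    """Heterotic mode from the dominance degree (half-open intervals)."""
    if not math.isfinite(d_over_a):
        raise ValueError("d/a must be finite")
    if d_over_a > 1.25:
        return OVERDOMINANCE
    if d_over_a > 0.25:
        return COMPLETE_INCOMPLETE_DOMINANCE
    if d_over_a > -0.25:
        return ADDITIVE
    if d_over_a > -1.25:
        return INCOMPLETE_RECESSIVE
    return UNDERDOMINANCE


@dataclass
class EffectEstimate:
    """Genotype-class means and derived heterotic quantities at a locus."""

    mean_MM: float
    mean_MF: float
    mean_FF: float
    a: float  # |m_MM - m_FF| / 2, magnitude
    d: float  # m_MF - mid-homozygote, in raw trait orientation
    d_over_a: float  # polarity-oriented; NaN when a == 0
    advantageous: str | None  # "M" or "F"; None when a == 0
    heterotic_class: str | None
    unstable_ratio: bool
    n_per_class: tuple[int, int, int]  # (n_MM, n_MF, n_FF)

    @property
    def mid_homozygote(self) -> float:
        return (self.mean_MM + self.mean_FF) / 2.0


def estimate_effects(
    genotypes: np.ndarray,
    y: np.ndarray,
    polarity: str = "higher",
    min_class_n: int = 30,
) -> EffectEstimate:
    """Estimate (a, d, d/a) and the advantageous parent at one locus.

    ``genotypes`` are codes over individuals aligned with ``y``; each
    genotype class must contain at least ``min_class_n`` individuals.
    When the homozygote means coincide exactly (a = 0) the ratio is
    undefined: the estimate is flagged unstable and, if d != 0, the
    class is reported as the over/underdominance candidate implied by
    the sign of d.
    """
    if polarity not in ("higher", "lower"):
        raise ValueError("polarity must be 'higher' or 'lower'")
    g = np.asarray(genotypes)
    y = np.asarray(y, dtype=float)
    means, counts = {}, {}
    for code in (MM, MF, FF):
        mask = g == code
        counts[code] = int(mask.sum())
        if counts[code] < min_class_n:
            raise ValueError(
                f"genotype class {code} has {counts[code]} < {min_class_n} individuals"
            )
        means[code] = float(y[mask].mean())
    a = abs(means[MM] - means[FF]) / 2.0
    d = means[MF] - (means[MM] + means[FF]) / 2.0
    s = 1.0 if polarity == "higher" else -1.0
    if a > 0:
        better_is_m = (means[MM] > means[FF]) if polarity == "higher" else (means[MM] < means[FF])
        adv = "M" if better_is_m else "F"
        doa = s * d / a
        klass = classify(doa)
        unstable = False
    else:
        adv = None
        doa = float("nan")
        unstable = True
        if d != 0:
            klass = OVERDOMINANCE if s * d > 0 else UNDERDOMINANCE
        else:
            klass = None
    return EffectEstimate(
        mean_MM=means[MM],
        mean_MF=means[MF],
        mean_FF=means[FF],
        a=a,
        d=d,
        d_over_a=doa,
        advantageous=adv,
        heterotic_class=klass,
        unstable_ratio=unstable,
        n_per_class=(counts[MM], counts[MF], counts[FF]),
    )


def locus_mph(effect: EffectEstimate) -> float:
    """Locus-level mid-parent heterosis, % of the mid-homozygote mean.

    ``100 * d / ((m_MM + m_FF) / 2)`` — the heterozygote's deviation
    from the locus mid-parent point, relative to that point.
    """
    mid = effect.mid_homozygote
    if mid == 0:
        raise ValueError("mid-homozygote mean is zero; locus MPH undefined")
    return 100.0 * effect.d / mid


@dataclass(frozen=True)
class HeterosisIndices:
    """Trait-level heterosis of an F1 line versus its parents (%)."""

    mph: float  # (F1 - midparent) / |midparent| * 100
    bph: float  # (F1 - better parent) / |better parent| * 100
    better_parent: str  # "M" or "F"


def trait_heterosis(
    parent_m_mean: float,
    parent_f_mean: float,
    f1_mean: float,
    polarity: str = "higher",
) -> HeterosisIndices:
    """Mid-parent and better-parent heterosis for one trait.

    The better parent is chosen under the trait's polarity; BPH is
    negative when the F1 falls short of it in the advantage direction
    (e.g. an F1 flowering earlier than both parents when late flowering
    is the registered advantage).
    """
    if polarity not in ("higher", "lower"):
        raise ValueError("polarity must be 'higher' or 'lower'")
    mid = (parent_m_mean + parent_f_mean) / 2.0
    if parent_m_mean == 0 and parent_f_mean == 0:
        raise ValueError("both parental means are zero; indices undefined")
    if polarity == "higher":
        bp, bp_name = max((parent_m_mean, "M"), (parent_f_mean, "F"))
    else:
        bp, bp_name = min((parent_m_mean, "M"), (parent_f_mean, "F"))
    mph = 100.0 * (f1_mean - mid) / abs(mid) if mid != 0 else float("nan")
    bph = 100.0 * (f1_mean - bp) / abs(bp) if bp != 0 else float("nan")
    return HeterosisIndices(mph=mph, bph=bph, better_parent=bp_name)


def allele_direction_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Share of QTLs whose advantageous allele comes from each parent.

    Expects a QTL-record frame with ``trait`` and ``advantageous``
    columns; returns percentages overall (trait "all") and per trait.
    """
    if len(records) == 0:
        raise ValueError("no QTL records")
    recs = records.dropna(subset=["advantageous"])

    def _prop(df: pd.DataFrame) -> pd.Series:
        n = len(df)
        n_m = int((df["advantageous"] == "M").sum())
        return pd.Series(
            {"n": n, "pct_M": 100.0 * n_m / n, "pct_F": 100.0 * (n - n_m) / n}
        )

    rows = {"all": _prop(recs)}
    for trait, grp in recs.groupby("trait", sort=False):
        rows[trait] = _prop(grp)
    return pd.DataFrame(rows).T.rename_axis("trait")


def dova_vs_lod_profile(
    records: pd.DataFrame,
    clip: float = 3.0,
    lod_bins: tuple[float, ...] = (3.5, 5.0, 7.0, 10.0, float("inf")),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dominance degree versus LOD, with display clipping.

    Returns ``(points, strata)``: per-QTL (lod, d/a, clipped display
    value, class) and an overdominance count/fraction per LOD stratum
    — the diagnostic that overdominance calls concentrate among
    low-LOD (small-effect) loci, where the ratio estimate is noisiest.
    Stored d/a values are never clipped; only the display column is.
    """
    pts = records[["lod", "d_over_a", "class"]].copy()
    pts["d_over_a_display"] = pts["d_over_a"].clip(-clip, clip)
    if len(pts) == 0:
        return pts, pd.DataFrame(columns=["lod_min", "lod_max", "n", "n_overdominant", "frac_overdominant"])
    edges = list(lod_bins)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = pts[(pts["lod"] >= lo) & (pts["lod"] < hi)]
        n = len(sel)
        n_od = int((sel["class"] == OVERDOMINANCE).sum())
        rows.append((lo, hi, n, n_od, n_od / n if n else float("nan")))
    strata = pd.DataFrame(rows, columns=["lod_min", "lod_max", "n", "n_overdominant", "frac_overdominant"])
    return pts, strata
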
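"""Genetic map estimation from the bin-genotype matrix.

Bin order is fixed by physical coordinates (reference-anchored design),
so the map reduces to estimating the recombination fraction r between
each pair of adjacent bins and converting it to map distance with a
mapping function (Haldane by default, matching the interference-free
simulator; Kosambi available).

For an F2 intercross with co-dominant markers the likelihood of r given
the 3x3 table of two-locus genotype classes has no closed-form maximum
(the double-heterozygote class mixes 0- and 2-recombinant gamete
pairs), so r is found by EM over the latent gamete phase. The E-step
weights are derived numerically from the 16 ordered gamete-pair
configurations, which keeps the implementation transparent and lets the
same code run vectorized over every adjacent bin pair at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._codes import MISSING
from .skimgeno import BinGenotypeMatrix

__all__ = [
    "GeneticMap",
    "haldane_cm",
    "haldane_rf",
    "kosambi_cm",
    "kosambi_rf",
    "pair_counts",
    "estimate_rf",
    "estimate_rf_many",
    "build_map",
    "write_map",
    "read_map",
]


def haldane_cm(r):
    """Map distance (cM) from recombination fraction, Haldane."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log1p(-2.0 * r)


def haldane_rf(d_cm):
    """Recombination fraction from map distance (cM), Haldane."""
    d_cm = np.asarray(d_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-d_cm / 50.0))


def kosambi_cm(r):
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_rf(d_cm):
    d_cm = np.asarray(d_cm, dtype=float)
    return 0.5 * np.tanh(d_cm / 50.0)


_MAPPING = {"haldane": (haldane_cm, haldane_rf), "kosambi": (kosambi_cm, kosambi_rf)}

# Ordered gamete-pair machinery. A gamete carries alleles (x, y) at the
# two loci, x/y in {0=F, 1=M}; type index t = 2x + y. Under Haldane its
# probability is (1-r)/2 for parental types (x == y) and r/2 for
# recombinants. An individual is an ordered pair (t1, t2); the observed
# class is (g1, g2) = (x1+x2, y1+y2) flattened to 3*g1 + g2.
_GAM_X = np.array([0, 0, 1, 1])
_GAM_Y = np.array([0, 1, 0, 1])
_GAM_REC = (_GAM_X != _GAM_Y).astype(float)  # recombinant indicator
_PAIR_CLASS = np.empty(16, dtype=np.intp)
_PAIR_REC = np.empty(16)
for _t1 in range(4):
    for _t2 in range(4):
        _g1 = _GAM_X[_t1] + _GAM_X[_t2]
        _g2 = _GAM_Y[_t1] + _GAM_Y[_t2]
        _PAIR_CLASS[4 * _t1 + _t2] = 3 * _g1 + _g2
        _PAIR_REC[4 * _t1 + _t2] = _GAM_REC[_t1] + _GAM_REC[_t2]
# selection matrix: class c <- ordered pairs
_CLS_SEL = np.zeros((9, 16))
_CLS_SEL[_PAIR_CLASS, np.arange(16)] = 1.0


def pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """9-vector of two-locus genotype-class counts (missing dropped).

    Classes are indexed ``3 * g1 + g2`` with g in {0=FF, 1=MF, 2=MM}.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    idx = 3 * g1[ok].astype(np.intp) + g2[ok].astype(np.intp)
    return np.bincount(idx, minlength=9).astype(float)


def class_probabilities(r) -> np.ndarray:
    """3x3-class probabilities (flattened, 9) as a function of r.

    Vectorized: input shape ``s`` gives output shape ``s + (9,)``.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    p_gam = np.stack(
        [np.where(_GAM_REC[t] > 0, r / 2.0, (1.0 - r) / 2.0) for t in range(4)], axis=-1
    )  # (..., 4)
    pp = p_gam[..., :, None] * p_gam[..., None, :]  # (..., 4, 4)
    pp = pp.reshape(pp.shape[:-2] + (16,))
    return pp @ _CLS_SEL.T  # (..., 9)


def estimate_rf_many(counts: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """EM estimate of r for many independent 9-class count vectors.

    ``counts`` has shape (m, 9); returns shape (m,). Pairs with zero
    informative individuals come back as NaN.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n = counts.sum(axis=1)
    r = np.full(len(counts), 0.25)
    active = n > 0
    for _ in range(max_iter):
        if not active.any():
            break
        ra = r[active]
        p_gam = np.stack(
            [np.where(_GAM_REC[t] > 0, ra / 2.0, (1.0 - ra) / 2.0) for t in range(4)], axis=-1
        )
        pp = (p_gam[:, :, None] * p_gam[:, None, :]).reshape(-1, 16)  # (ma, 16)
        denom = pp @ _CLS_SEL.T  # (ma, 9) class probabilities
        num = (pp * _PAIR_REC) @ _CLS_SEL.T  # expected rec gametes (unnormalized)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_rec = np.where(denom > 0, num / denom, 0.0)
        r_new = (counts[active] * e_rec).sum(axis=1) / (2.0 * n[active])
        r_new = np.clip(r_new, 1e-12, 0.5 - 1e-12)
        moved = np.abs(r_new - ra) > tol
        r[active] = r_new
        idx = np.flatnonzero(active)
        active[idx[~moved]] = False
    r[n == 0] = np.nan
    return r


def estimate_rf(g1: np.ndarray, g2: np.ndarray, min_informative: int = 30) -> float:
    """Maximum-likelihood recombination fraction between two markers.

    ``g1``/``g2`` are genotype-code vectors over the same individuals;
    raises ``ValueError`` when fewer than ``min_informative``
    individuals are non-missing at both (callers fall back to physical
    interpolation).
    """
    counts = pair_counts(g1, g2)
    if counts.sum() < min_informative:
        raise ValueError(
            f"only {int(counts.sum())} informative individuals (< {min_informative})"
        )
    return float(estimate_rf_many(counts[None, :])[0])


class GeneticMap:
    """Cumulative cM positions of the bins of a bin-genotype matrix.

    ``table`` is aligned row-for-row with the source matrix's bins and
    has columns ``chrom, start, end, bp_mid, cm, flag`` (flag in
    {"", "interpolated", "capped"} describing how the distance to the
    previous bin was obtained).
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)

    @property
    def total_cm(self) -> float:
        return float(
            sum(g["cm"].iloc[-1] - g["cm"].iloc[0] for _, g in self.table.groupby("chrom", sort=False))
        )

    def chromosome_lengths(self) -> pd.Series:
        return self.table.groupby("chrom", sort=False)["cm"].agg(lambda c: c.iloc[-1] - c.iloc[0])

    def attach(self, bm: BinGenotypeMatrix) -> BinGenotypeMatrix:
        """Return a copy of ``bm`` with the cm column on its bins."""
        if len(bm.bins) != len(self.table):
            raise ValueError("map was not built from this bin matrix")
        bins = bm.bins.copy()
        bins["cm"] = self.table["cm"].to_numpy()
        return BinGenotypeMatrix(bins=bins, G=bm.G, individuals=bm.individuals)


def build_map(
    bm: BinGenotypeMatrix,
    min_informative: int = 30,
    mapping: str = "haldane",
    max_gap_cm: float = 50.0,
) -> GeneticMap:
    """Estimate cumulative cM positions for every bin.

    Adjacent-bin recombination fractions (EM, see module docstring) are
    converted to distances with the chosen mapping function. Pairs with
    fewer than ``min_informative`` complete observations are
    interpolated from physical distance at the chromosome's average
    cM/Mb (flag "interpolated"); pairs whose estimate hits r = 0.5 get
    ``max_gap_cm`` (flag "capped").
    """
    to_cm, _ = _MAPPING[mapping]
    pieces = []
    for chrom, idx in bm.bins.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        G = bm.G[idx]
        nb = len(idx)
        dist = np.zeros(nb)
        flag = np.array([""] * nb, dtype=object)
        if nb > 1:
            a, b = G[:-1], G[1:]
            ok = (a != MISSING) & (b != MISSING)
            cls = (3 * a.astype(np.intp) + b.astype(np.intp))
            m = nb - 1
            flat = (np.arange(m)[:, None] * 9 + cls)[ok]
            counts = np.bincount(flat, minlength=m * 9).reshape(m, 9).astype(float)
            n_inf = counts.sum(axis=1)
            rf = estimate_rf_many(counts)
            capped = np.isfinite(rf) & (rf >= 0.5 - 1e-9)
            unreliable = (n_inf < min_informative) | ~np.isfinite(rf)
            with np.errstate(invalid="ignore"):
                d = to_cm(np.where(unreliable | capped, 0.0, rf))
            d[capped & ~unreliable] = max_gap_cm
            # physical interpolation for unreliable pairs, using the
            # chromosome-average rate over reliable pairs
            mids = ((bm.bins["start"].to_numpy() + bm.bins["end"].to_numpy()) / 2.0)[idx]
            gap_bp = np.diff(mids)
            reliable = ~unreliable
            rate = (d[reliable].sum() / gap_bp[reliable].sum()) if reliable.any() and gap_bp[reliable].sum() > 0 else 0.0
            d[unreliable] = gap_bp[unreliable] * rate
            dist[1:] = d
            flag_pair = np.array([""] * m, dtype=object)
            flag_pair[capped & ~unreliable] = "capped"
            flag_pair[unreliable] = "interpolated"
            flag[1:] = flag_pair
        else:
            mids = ((bm.bins["start"].to_numpy() + bm.bins["end"].to_numpy()) / 2.0)[idx]
        tab = bm.bins.loc[idx, ["chrom", "start", "end"]].copy()
        tab["bp_mid"] = (tab["start"].to_numpy() + tab["end"].to_numpy()) / 2.0
        tab["cm"] = np.cumsum(dist)
        tab["flag"] = flag
        pieces.append(tab)
    return GeneticMap(pd.concat(pieces, ignore_index=True))


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return GeneticMap(df)
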
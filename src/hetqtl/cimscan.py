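"""Composite interval mapping (CIM) with additive and dominance effects.

The scan moves along each chromosome on a cM grid and, at every test
position, fits the Haley–Knott regression

    y = mu + a * x_a + d * x_d + (cofactor terms) + e

where ``x_a = P(MM) - P(FF)`` and ``x_d = P(MF)`` are expectations of
the additive and dominance design codes under the F2 conditional
genotype probabilities given the flanking bins (Haldane). The LOD is
the classical regression form

    LOD = (n / 2) * log10(RSS_reduced / RSS_full)

with the reduced model dropping (a, d) but keeping the cofactors.
Cofactors are marker bins pre-selected by forward stepwise regression
on their (x_a, x_d) code pair and are excluded from the model whenever
they sit within ``cofactor_window`` cM of the test position. With zero
cofactors the scan reduces to simple interval mapping, and at a marker
bin it equals the two-degree-of-freedom single-marker regression.

Peaks above the LOD threshold become QTL records carrying the effect
estimates, the dominance degree d/a, its heterotic classification and
the parent contributing the advantageous allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._codes import FF, MF, MM, MISSING
from .genmap import GeneticMap, haldane_rf
from .skimgeno import BinGenotypeMatrix
from . import heterosis

__all__ = [
    "ScanConfig",
    "genotype_probabilities",
    "select_cofactors",
    "scan_trait",
    "call_peaks",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings: 2 cM steps, a 10 cM cofactor exclusion window and
    a LOD 3.5 call threshold by default."""

    step: float = 2.0
    cofactor_window: float = 10.0
    max_cofactors: int = 5
    lod_threshold: float = 3.5
    peak_merge_radius: float = 20.0
    f_to_enter: float = 0.01

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.cofactor_window < self.step:
            raise ValueError("cofactor_window must be >= step")
        if self.lod_threshold <= 0:
            raise ValueError("lod_threshold must be > 0")


_PRIOR = np.array([0.25, 0.5, 0.25])  # FF, MF, MM Mendelian prior


def _joint_tensor(r_left: float, r_right: float) -> np.ndarray:
    """Joint P(gL, gQ, gR), each axis (FF, MF, MM), for one gamete pair.

    Built from the per-gamete origin Markov chain: an origin switch
    between two points d cM apart has probability r = Haldane(d); the
    two gametes of an F2 individual are independent.
    """
    out = np.zeros((3, 3, 3))
    tl = np.array([[1 - r_left, r_left], [r_left, 1 - r_left]])
    tr = np.array([[1 - r_right, r_right], [r_right, 1 - r_right]])
    # per-gamete joint over (aL, aQ, aR), a in {0=F, 1=M}
    gam = 0.5 * tl[:, :, None] * tr[None, :, :]
    for a in np.ndindex(2, 2, 2):
        for b in np.ndindex(2, 2, 2):
            out[a[0] + b[0], a[1] + b[1], a[2] + b[2]] += gam[a] * gam[b]
    return out


def _conditional_lookup(r_left: float, r_right: float) -> np.ndarray:
    """(4, 4, 3) table of P(gQ | gL, gR) indexed by (gL+1, gR+1).

    Index 0 on either flank axis means that flank is missing and is
    marginalized out; both missing gives the Mendelian prior.
    """
    J = _joint_tensor(r_left, r_right)
    tab = np.empty((4, 4, 3))
    tab[0, 0] = _PRIOR
    jl = J.sum(axis=2)  # (gL, gQ)
    jr = J.sum(axis=0)  # (gQ, gR)
    for gl in range(3):
        tab[gl + 1, 0] = jl[gl] / jl[gl].sum()
        tab[0, gl + 1] = jr[:, gl] / jr[:, gl].sum()
    for gl in range(3):
        for gr in range(3):
            s = J[gl, :, gr].sum()
            tab[gl + 1, gr + 1] = J[gl, :, gr] / s if s > 0 else _PRIOR
    return tab


def genotype_probabilities(
    d_left_cm: float | None,
    d_right_cm: float | None,
    g_left: np.ndarray | None,
    g_right: np.ndarray | None,
) -> np.ndarray:
    """F2 conditional genotype probabilities at a test position.

    ``d_left_cm``/``d_right_cm`` are the distances to the flanking
    bins (``None`` when a flank does not exist, e.g. beyond the
    terminal bin); ``g_left``/``g_right`` the flank genotype codes per
    individual (missing codes are marginalized). Returns an (n, 3)
    array of (P(FF), P(MF), P(MM)) rows summing to 1.
    """
    if g_left is None and g_right is None:
        raise ValueError("at least one flank required")
    n = len(g_left) if g_left is not None else len(g_right)
    gl = np.full(n, MISSING, dtype=np.int8) if g_left is None else np.asarray(g_left, dtype=np.int8)
    gr = np.full(n, MISSING, dtype=np.int8) if g_right is None else np.asarray(g_right, dtype=np.int8)
    rl = float(haldane_rf(d_left_cm)) if d_left_cm is not None else 0.5
    rr = float(haldane_rf(d_right_cm)) if d_right_cm is not None else 0.5
    tab = _conditional_lookup(rl, rr)
    return tab[gl + 1, gr + 1]


def _design_codes(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Haley–Knott codes: x_a = P(MM) - P(FF), x_d = P(MF)."""
    return probs[:, 2] - probs[:, 0], probs[:, 1]


def _marker_codes(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design codes at an observed marker; missing -> prior expectation."""
    x_a = np.where(g == MISSING, 0.0, g - 1.0)
    x_d = np.where(g == MISSING, 0.5, (g == MF).astype(float))
    return x_a, x_d


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def select_cofactors(
    bm: BinGenotypeMatrix,
    y: np.ndarray,
    cfg: ScanConfig = ScanConfig(),
    candidates: np.ndarray | None = None,
) -> list[int]:
    """Forward stepwise selection of background marker bins.

    Each candidate bin contributes an (x_a, x_d) column pair; at each
    step the pair giving the largest residual-sum-of-squares drop
    enters if its 2-df F-to-enter p-value is below ``f_to_enter``,
    stopping at ``max_cofactors``. Once a bin is selected, candidates
    within ``cofactor_window`` cM of it on the same chromosome are
    removed, avoiding near-collinear cofactor stacks.

    Returns row indices into ``bm.bins``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if candidates is None:
        candidates = np.arange(bm.n_bins)
    cand = list(map(int, candidates))
    chrom = bm.bins["chrom"].to_numpy()
    cm = bm.bins["cm"].to_numpy() if "cm" in bm.bins.columns else None

    codes = {j: _marker_codes(bm.G[j]) for j in cand}
    selected: list[int] = []
    X = np.ones((n, 1))
    rss0 = _rss(X, y)
    while len(selected) < cfg.max_cofactors and cand:
        best_j, best_rss = None, rss0
        for j in cand:
            x_a, x_d = codes[j]
            rss1 = _rss(np.column_stack([X, x_a, x_d]), y)
            if rss1 < best_rss:
                best_j, best_rss = j, rss1
        if best_j is None:
            break
        p_full = X.shape[1] + 2
        df2 = n - p_full
        if df2 <= 0 or best_rss <= 0:
            break
        f = ((rss0 - best_rss) / 2.0) / (best_rss / df2)
        if stats.f.sf(f, 2, df2) >= cfg.f_to_enter:
            break
        selected.append(best_j)
        x_a, x_d = codes[best_j]
        X = np.column_stack([X, x_a, x_d])
        rss0 = best_rss
        if cm is not None:
            cand = [
                j
                for j in cand
                if j != best_j
                and not (chrom[j] == chrom[best_j] and abs(cm[j] - cm[best_j]) < cfg.cofactor_window)
            ]
        else:
            cand.remove(best_j)
    return selected


def _scan_positions(cm: np.ndarray, step: float) -> np.ndarray:
    """Union of the step grid and the marker positions themselves."""
    grid = np.arange(cm.min(), cm.max() + 1e-9, step)
    return np.unique(np.concatenate([grid, cm]))


def scan_trait(
    bm: BinGenotypeMatrix,
    y: np.ndarray,
    cfg: ScanConfig = ScanConfig(),
    cofactors: list[int] | None = None,
) -> pd.DataFrame:
    """Genome scan; returns ``chrom, cm, lod, a_hat, d_hat`` per position.

    ``bm`` must carry a ``cm`` column (see ``GeneticMap.attach``).
    ``cofactors`` are bin indices (``select_cofactors`` output); pass
    an empty list (or leave ``max_cofactors=0``) for simple interval
    mapping. Individuals must be aligned between matrix columns and
    ``y``; the trait must be non-constant.
    """
    if "cm" not in bm.bins.columns:
        raise ValueError("bin matrix has no cm positions; attach a GeneticMap first")
    y = np.asarray(y, dtype=float)
    if len(y) != bm.n_individuals:
        raise ValueError("trait vector not aligned with bin matrix individuals")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant")
    n = len(y)
    if cofactors is None:
        cofactors = select_cofactors(bm, y, cfg) if cfg.max_cofactors > 0 else []

    cof_pos = {
        j: (bm.bins["chrom"].iloc[j], float(bm.bins["cm"].iloc[j])) for j in cofactors
    }
    cof_cols = {j: np.column_stack(_marker_codes(bm.G[j])) for j in cofactors}

    out = []
    for chrom, idx in bm.bins.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        mc = bm.bins["cm"].to_numpy()[idx]
        Gc = bm.G[idx]
        for pos in _scan_positions(mc, cfg.step):
            iL = int(np.searchsorted(mc, pos, side="right")) - 1
            iR = int(np.searchsorted(mc, pos, side="left"))
            g_left = Gc[iL] if iL >= 0 else None
            g_right = Gc[iR] if iR < len(mc) else None
            d_left = pos - mc[iL] if iL >= 0 else None
            d_right = mc[iR] - pos if iR < len(mc) else None
            probs = genotype_probabilities(d_left, d_right, g_left, g_right)
            x_a, x_d = _design_codes(probs)

            keep = [
                j
                for j in cofactors
                if not (cof_pos[j][0] == chrom and abs(cof_pos[j][1] - pos) < cfg.cofactor_window)
            ]
            base = [np.ones((n, 1))] + [cof_cols[j] for j in keep]
            X_red = np.column_stack(base) if len(base) > 1 else base[0]
            X_full = np.column_stack([X_red, x_a, x_d])
            beta, _, rank, _ = np.linalg.lstsq(X_full, y, rcond=None)
            resid = y - X_full @ beta
            rss_full = float(resid @ resid)
            rss_red = _rss(X_red, y)
            if rss_full <= 0 or not np.isfinite(rss_full):
                warnings.warn(f"degenerate fit at {chrom}:{pos:.2f} cM; position skipped")
                continue
            lod = (n / 2.0) * np.log10(rss_red / rss_full)
            out.append((chrom, float(pos), max(lod, 0.0), float(beta[-2]), float(beta[-1])))
    return pd.DataFrame(out, columns=["chrom", "cm", "lod", "a_hat", "d_hat"])


def call_peaks(
    scan: pd.DataFrame,
    cfg: ScanConfig = ScanConfig(),
    gmap: GeneticMap | None = None,
    trait: str = "trait",
    polarity: str = "higher",
) -> pd.DataFrame:
    """Local LOD maxima above threshold, merged within a radius.

    Maxima within ``peak_merge_radius`` cM of a higher maximum on the
    same chromosome are absorbed into it. Effect estimates are taken at
    the peak; the dominance degree, heterotic class and advantageous
    parent derive from them (``polarity`` states whether larger trait
    values are the advantage, as for yield, or smaller, as for early
    flowering when lateness is not desired).
    """
    records = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        grp = grp.sort_values("cm")
        lod = grp["lod"].to_numpy()
        cm = grp["cm"].to_numpy()
        if len(lod) == 0:
            continue
        is_max = np.ones(len(lod), dtype=bool)
        if len(lod) > 1:
            is_max[1:] &= lod[1:] >= lod[:-1]
            is_max[:-1] &= lod[:-1] >= lod[1:]
        cand = np.flatnonzero(is_max & (lod > cfg.lod_threshold))
        accepted: list[int] = []
        for i in cand[np.argsort(lod[cand])[::-1]]:
            if all(abs(cm[i] - cm[j]) > cfg.peak_merge_radius for j in accepted):
                accepted.append(i)
        for i in sorted(accepted):
            a_hat, d_hat = grp["a_hat"].iloc[i], grp["d_hat"].iloc[i]
            rec = _qtl_record(trait, chrom, cm[i], lod[i], a_hat, d_hat, polarity)
            if gmap is not None:
                sub = gmap.table[gmap.table["chrom"] == chrom]
                rec["bp"] = float(np.interp(cm[i], sub["cm"], sub["bp_mid"]))
            records.append(rec)
    cols = ["trait", "chrom", "cm", "bp", "lod", "a_hat", "d_hat", "d_over_a", "class", "advantageous"]
    df = pd.DataFrame(records)
    return df.reindex(columns=[c for c in cols if gmap is not None or c != "bp"])


def _qtl_record(trait, chrom, cm, lod, a_hat, d_hat, polarity) -> dict:
    s = 1.0 if polarity == "higher" else -1.0
    a_mag = abs(a_hat)
    if a_mag > 0:
        d_over_a = s * d_hat / a_mag
        klass = heterosis.classify(d_over_a)
        adv = ("M" if a_hat > 0 else "F") if polarity == "higher" else ("F" if a_hat > 0 else "M")
    else:
        d_over_a, klass, adv = np.nan, None, None
    return {
        "trait": trait,
        "chrom": chrom,
        "cm": float(cm),
        "lod": float(lod),
        "a_hat": float(a_hat),
        "d_hat": float(d_hat),
        "d_over_a": d_over_a,
        "class": klass,
        "advantageous": adv,
    }
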
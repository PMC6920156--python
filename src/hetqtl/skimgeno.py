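"""Genotype calling from sparse skim-sequencing allele observations.

At ~0.2x coverage most SNPs carry zero or one read per individual, so
genotypes cannot be called per site. Instead, observations of the two
parental alleles are pooled in sliding windows of a fixed number of
informative observations; each window is called MM/MF/FF from the
binomial fraction of male-parent alleles, consecutive identical calls
are merged into segments, isolated discordant windows are smoothed out,
and recombination breakpoints are placed at the physical midpoint
between flanking windows. The union of all individuals' breakpoints
then partitions each chromosome into recombination bins, yielding the
bins-by-individuals genotype matrix used for map construction and QTL
scanning.

Windows advance by observation count rather than fixed bp so that call
confidence is homogeneous along the chromosome; bp spans (1-based,
inclusive) are recorded for coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._codes import FF, MF, MM, MISSING, CODE_TO_LABEL

__all__ = [
    "BinGenotypeMatrix",
    "call_windows",
    "infer_mosaics",
    "build_bin_map",
    "filter_bins",
    "recombination_profile",
    "count_recombination_events",
    "write_bin_matrix",
    "read_bin_matrix",
]


@dataclass
class BinGenotypeMatrix:
    """Recombination-bin genotype matrix.

    ``bins`` holds one row per bin (``chrom, start, end`` 1-based
    inclusive, plus ``cm`` once a genetic map has been attached);
    ``G`` is an int8 array of genotype codes, bins x individuals.
    """

    bins: pd.DataFrame
    G: np.ndarray
    individuals: list[str]

    def __post_init__(self):
        if self.G.shape != (len(self.bins), len(self.individuals)):
            raise ValueError("G shape does not match bins x individuals")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def frequencies(self) -> pd.DataFrame:
        """Per-bin MM/MF/FF frequencies over non-missing calls."""
        counts = np.stack([(self.G == c).sum(axis=1) for c in (MM, MF, FF)], axis=1)
        denom = counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = counts / denom
        out = self.bins[["chrom", "start", "end"]].copy()
        out[["freq_MM", "freq_MF", "freq_FF"]] = freq
        out["n_called"] = counts.sum(axis=1)
        return out

    def call_rate(self) -> np.ndarray:
        return (self.G != MISSING).mean(axis=1)


def call_windows(
    obs: pd.DataFrame,
    window_size: int = 15,
    min_obs: int = 10,
    het_band: tuple[float, float] = (0.15, 0.85),
) -> pd.DataFrame:
    """Call genotypes in consecutive windows of informative observations.

    For each individual and chromosome, observations (sorted by
    position) are chunked into windows of ``window_size``; with
    ``p = n_M / (n_M + n_F)`` the window is called MM when
    ``p >= het_band[1]``, FF when ``p <= het_band[0]``, MF otherwise,
    and missing whenever fewer than ``min_obs`` observations are
    available (only the trailing partial window can be short).

    Returns columns ``individual, chrom, start, end, n_m, n_f, call``.
    """
    lo, hi = het_band
    if not 0 <= lo < hi <= 1:
        raise ValueError("het_band must satisfy 0 <= lo < hi <= 1")
    if window_size < 1 or min_obs < 1:
        raise ValueError("window_size and min_obs must be >= 1")
    bad = set(obs["allele"].unique()) - {"M", "F"}
    if bad:
        raise ValueError(f"unknown allele symbols: {sorted(bad)}")

    rows = []
    for (ind, chrom), grp in obs.groupby(["individual", "chrom"], sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"observations not sorted by position for {ind}/{chrom}")
        is_m = (grp["allele"].to_numpy() == "M").astype(np.int64)
        n = len(pos)
        starts = np.arange(0, n, window_size)
        n_tot = np.add.reduceat(np.ones(n, dtype=np.int64), starts)
        n_m = np.add.reduceat(is_m, starts)
        n_f = n_tot - n_m
        w_start = pos[starts]
        w_end = pos[np.minimum(starts + window_size, n) - 1]
        with np.errstate(invalid="ignore"):
            p = n_m / n_tot
        call = np.where(p >= hi, MM, np.where(p <= lo, FF, MF)).astype(np.int8)
        call[n_tot < min_obs] = MISSING
        rows.append(
            pd.DataFrame(
                {
                    "individual": ind,
                    "chrom": chrom,
                    "start": w_start,
                    "end": w_end,
                    "n_m": n_m,
                    "n_f": n_f,
                    "call": call,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["individual", "chrom", "start", "end", "n_m", "n_f", "call"])
    return pd.concat(rows, ignore_index=True)


def _smooth_singletons(calls: np.ndarray) -> np.ndarray:
    """Replace single-window calls discordant with both (equal) flanks."""
    out = calls.copy()
    for i in range(1, len(out) - 1):
        if out[i - 1] == out[i + 1] != out[i]:
            # only smooth true singletons (flanks belong to runs)
            out[i] = out[i - 1]
    return out


def infer_mosaics(
    calls: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    smooth: bool = True,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Merge window calls into genotype segment mosaics per individual.

    Missing windows are dropped; if ``smooth``, an isolated window
    discordant with two equal flanking calls is rewritten to the
    flanking call (guarding against single-window errors at low
    coverage). Consecutive identical calls merge into one segment, and
    each breakpoint is placed at the bp midpoint between the last
    window of one segment and the first window of the next. Segments
    are extended to the chromosome ends so they tile [1, length].

    Returns ``(mosaic frame, flagged)`` where the mosaic frame has
    columns ``individual, chrom, start, end, genotype`` and ``flagged``
    lists ``(individual, chrom)`` pairs with no callable window (these
    are absent from the mosaic and must be treated as missing).
    """
    rows: list[tuple] = []
    flagged: list[tuple[str, str]] = []
    for (ind, chrom), grp in calls.groupby(["individual", "chrom"], sort=False):
        keep = grp["call"].to_numpy() != MISSING
        if not keep.any():
            flagged.append((ind, chrom))
            continue
        g = grp.loc[keep]
        cvec = g["call"].to_numpy()
        if smooth and len(cvec) >= 3:
            cvec = _smooth_singletons(cvec)
        w_start = g["start"].to_numpy()
        w_end = g["end"].to_numpy()
        change = np.flatnonzero(cvec[1:] != cvec[:-1])  # last index of each run
        # breakpoint bp midpoint between flanking windows
        cut = (w_end[change] + w_start[change + 1]) // 2
        L = int(chrom_lengths[chrom])
        starts = np.concatenate([[1], cut + 1])
        ends = np.concatenate([cut, [L]])
        genos = cvec[np.concatenate([change, [len(cvec) - 1]])]
        for s, e, gg in zip(starts, ends, genos):
            rows.append((ind, chrom, int(s), int(e), int(gg)))
    mosaic = pd.DataFrame(rows, columns=["individual", "chrom", "start", "end", "genotype"])
    return mosaic, flagged


def build_bin_map(
    mosaics: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    individuals: list[str] | None = None,
) -> BinGenotypeMatrix:
    """Partition chromosomes at the union of all breakpoints.

    Bin boundaries are the union over individuals of segment
    boundaries; each individual's code per bin is read off its mosaic
    (bin midpoint lookup). Individuals lacking a mosaic on some
    chromosome get missing codes there.
    """
    if individuals is None:
        individuals = list(pd.unique(mosaics["individual"]))
    if len(individuals) < 2:
        raise ValueError("bin map requires >= 2 individuals")
    ind_index = {name: i for i, name in enumerate(individuals)}

    bin_frames = []
    G_blocks = []
    for chrom in chrom_lengths:
        seg = mosaics[mosaics["chrom"] == chrom]
        L = int(chrom_lengths[chrom])
        cuts = np.unique(seg["end"].to_numpy())
        cuts = cuts[cuts < L]
        starts = np.concatenate([[1], cuts + 1])
        ends = np.concatenate([cuts, [L]])
        mids = (starts + ends) / 2.0
        nb = len(starts)
        block = np.full((nb, len(individuals)), MISSING, dtype=np.int8)
        for ind, g in seg.groupby("individual", sort=False):
            col = ind_index.get(ind)
            if col is None:
                continue
            seg_ends = g["end"].to_numpy()
            seg_geno = g["genotype"].to_numpy()
            idx = np.searchsorted(seg_ends, mids)
            idx = np.minimum(idx, len(seg_ends) - 1)
            block[:, col] = seg_geno[idx]
        bin_frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        G_blocks.append(block)
    bins = pd.concat(bin_frames, ignore_index=True)
    G = np.vstack(G_blocks) if G_blocks else np.empty((0, len(individuals)), dtype=np.int8)
    return BinGenotypeMatrix(bins=bins, G=G, individuals=list(individuals))


def filter_bins(bm: BinGenotypeMatrix, min_call_rate: float = 0.8) -> BinGenotypeMatrix:
    """Drop bins with a call rate below ``min_call_rate``.

    Downstream scans require well-observed markers; at skim coverage a
    bin seen in few individuals mostly adds noise.
    """
    keep = bm.call_rate() >= min_call_rate
    return BinGenotypeMatrix(
        bins=bm.bins.loc[keep].reset_index(drop=True),
        G=bm.G[keep],
        individuals=bm.individuals,
    )


def thin_bins(bm: BinGenotypeMatrix, min_spacing_cm: float) -> BinGenotypeMatrix:
    """Subsample bins to a minimum cM spacing (for scan marker grids).

    In a large population the union of breakpoints produces bins far
    denser than any scan step resolves; scanning every bin only adds
    noise-level local maxima. Keeps the first bin per chromosome, then
    greedily every bin at least ``min_spacing_cm`` past the last kept
    one. Requires a ``cm`` column.
    """
    if "cm" not in bm.bins.columns:
        raise ValueError("thin_bins requires cm positions; attach a GeneticMap first")
    keep = np.zeros(len(bm.bins), dtype=bool)
    for _, idx in bm.bins.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        cm = bm.bins["cm"].to_numpy()[idx]
        last = -np.inf
        for k, c in zip(idx, cm):
            if c - last >= min_spacing_cm:
                keep[k] = True
                last = c
    return BinGenotypeMatrix(
        bins=bm.bins.loc[keep].reset_index(drop=True),
        G=bm.G[keep],
        individuals=bm.individuals,
    )


def count_recombination_events(mosaics: pd.DataFrame) -> pd.DataFrame:
    """Recombination events (= segments - 1) per individual per chromosome."""
    counts = (
        mosaics.groupby(["individual", "chrom"], sort=False)
        .size()
        .sub(1)
        .rename("events")
        .reset_index()
    )
    return counts


def recombination_summary(counts: pd.DataFrame) -> pd.Series:
    ev = counts["events"]
    return pd.Series(
        {
            "mean": ev.mean(),
            "q25": ev.quantile(0.25),
            "median": ev.median(),
            "q75": ev.quantile(0.75),
        }
    )


def recombination_profile(
    mosaics: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_individuals: int,
    window_mb: float = 10.0,
) -> pd.DataFrame:
    """Population recombination rate (cM/Mb) in physical windows.

    Each junction between adjacent segments of a genotype mosaic marks
    one crossover in one of the individual's two gametes, so the local
    genetic length of a window is ``100 * events / (2n)`` cM and the
    rate is that divided by the window size in Mb.
    """
    if window_mb <= 0:
        raise ValueError("window_mb must be > 0")
    win_bp = int(window_mb * 1e6)
    out = []
    for chrom, L in chrom_lengths.items():
        seg = mosaics[mosaics["chrom"] == chrom]
        # breakpoint positions = segment ends that are not chromosome ends
        cut = seg.loc[seg["end"] < int(L), "end"].to_numpy()
        edges = np.arange(0, int(L) + win_bp, win_bp)
        edges[-1] = max(edges[-1], int(L))
        hist, _ = np.histogram(cut, bins=edges)
        width_mb = np.diff(edges) / 1e6
        cm = 100.0 * hist / (2 * n_individuals)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": edges[:-1] + 1,
                    "end": edges[1:],
                    "events": hist,
                    "cm": cm,
                    "cm_per_mb": cm / width_mb,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_bin_matrix(bm: BinGenotypeMatrix, path) -> None:
    """Bins as rows, individuals as columns, genotypes as labels."""
    df = bm.bins.copy()
    lut = {MM: "MM", MF: "MF", FF: "FF", MISSING: "NA"}
    for j, ind in enumerate(bm.individuals):
        df[ind] = [lut[int(c)] for c in bm.G[:, j]]
    df.to_csv(path, sep="\t", index=False)


def read_bin_matrix(path) -> BinGenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in ("chrom", "start", "end", "cm") if c in df.columns]
    ind_cols = [c for c in df.columns if c not in meta_cols]
    lut = {"MM": MM, "MF": MF, "FF": FF, "NA": MISSING}
    G = np.empty((len(df), len(ind_cols)), dtype=np.int8)
    for j, c in enumerate(ind_cols):
        G[:, j] = [lut[v] for v in df[c]]
    return BinGenotypeMatrix(bins=df[meta_cols].copy(), G=G, individuals=ind_cols)
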
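"""Synthetic F2 populations with known QTL architecture.

This module generates everything the downstream pipeline consumes, with
full knowledge of the truth so that every stage can be validated by
parameter recovery:

* parental inbred lines, fully homozygous and informative at every SNP;
* F2 individuals as pairs of recombinant gametes produced by a Poisson
  (Haldane, interference-free) crossover process on a genetic map;
* very-low-coverage ("skim") sequencing reduced to per-SNP observations
  of a parental allele, with a configurable error rate;
* quantitative traits as sums of per-QTL genotypic values — ``+a`` for
  the homozygote carrying the advantageous allele, ``-a`` for the other
  homozygote, ``d`` (measured from the mid-homozygote point) for the
  heterozygote — plus Gaussian noise;
* a second "location" in which each QTL's (a, d) is jittered, emulating
  genotype-by-environment shifts for replication analyses.

It also embeds the published 17-locus two-location replication table
(:func:`table1_fixture`), the only real-data fixture in the package.

All randomness flows through explicit integer seeds: the same seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._codes import FF, MF, MM, MISSING  # noqa: F401  (re-exported)

__all__ = [
    "SimConfig",
    "QTL",
    "QTLArchitecture",
    "Gamete",
    "F2Individual",
    "TraitTable",
    "MAIZE_CHROMOSOMES",
    "simulate_gamete",
    "simulate_f2_population",
    "perturbed_architecture",
    "simulate_parental_haplotypes",
    "simulate_observations",
    "genotypes_at",
    "truth_mosaics",
    "table1_fixture",
    "write_parental_vcf",
    "read_parental_vcf",
    "write_config",
    "read_config",
]

# Ten chromosomes with physical sizes close to the maize reference
# genome (AGPv4, Mb scale) and genetic lengths distributing a 1588.8 cM
# genome total proportionally to physical size.
_MAIZE_BP = [307, 244, 235, 247, 224, 174, 182, 181, 160, 151]  # Mb
_TOTAL_CM = 1588.8
MAIZE_CHROMOSOMES: tuple[tuple[int, float], ...] = tuple(
    (mb * 1_000_000, round(_TOTAL_CM * mb / sum(_MAIZE_BP), 2)) for mb in _MAIZE_BP
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for a simulated F2 population.

    Parameters
    ----------
    n_individuals
        Number of F2 plants.
    chromosomes
        One ``(physical length bp, genetic length cM)`` pair per
        chromosome. Defaults to a maize-like 10-chromosome genome whose
        genetic lengths sum to 1588.8 cM.
    snp_density
        Parent-informative SNPs per Mb.
    coverage
        Mean sequencing observations per SNP per individual (0.2 for
        skim sequencing).
    obs_error_rate
        Probability that an observation reports the wrong parental
        allele.
    seed
        Base RNG seed; identical seeds give identical outputs.
    noninformative_intervals
        Optional ``(chrom, start_bp, end_bp)`` regions in which no
        informative SNPs are emitted, emulating identical-by-state
        segments between the parents.
    """

    n_individuals: int
    chromosomes: tuple[tuple[int, float], ...] = MAIZE_CHROMOSOMES
    snp_density: float = 100.0
    coverage: float = 0.2
    obs_error_rate: float = 0.01
    seed: int = 0
    noninformative_intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0 <= self.obs_error_rate < 0.5:
            raise ValueError("obs_error_rate must be in [0, 0.5)")
        for bp, cm in self.chromosomes:
            if bp <= 0:
                raise ValueError("physical lengths must be positive")
            if cm < 0:
                raise ValueError("genetic lengths must be >= 0")
        object.__setattr__(self, "chromosomes", tuple(tuple(c) for c in self.chromosomes))

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosomes))]

    @property
    def chrom_lengths_bp(self) -> dict[str, int]:
        return {n: int(bp) for n, (bp, _) in zip(self.chrom_names, self.chromosomes)}

    @property
    def chrom_lengths_cm(self) -> dict[str, float]:
        return {n: float(cm) for n, (_, cm) in zip(self.chrom_names, self.chromosomes)}

    @property
    def total_cm(self) -> float:
        return float(sum(cm for _, cm in self.chromosomes))

    # The simulator places crossovers on the cM axis; physical
    # coordinates are obtained by a linear cM <-> bp change of scale
    # within each chromosome (uniform recombination unless the genetic
    # length is locally modified by the caller).
    def cm_to_bp(self, chrom: str, cm) -> np.ndarray:
        bp_len = self.chrom_lengths_bp[chrom]
        cm_len = self.chrom_lengths_cm[chrom]
        frac = np.asarray(cm, dtype=float) / cm_len if cm_len > 0 else np.zeros_like(np.asarray(cm, dtype=float))
        return np.clip(np.rint(frac * bp_len), 1, bp_len).astype(np.int64)

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray:
        bp_len = self.chrom_lengths_bp[chrom]
        cm_len = self.chrom_lengths_cm[chrom]
        return np.asarray(bp, dtype=float) / bp_len * cm_len


@dataclass(frozen=True)
class QTL:
    """One trait locus: position, additive effect ``a`` (>= 0, carried
    by the advantageous parent), dominance deviation ``d`` and the
    parent ("M" or "F") contributing the advantageous allele."""

    chrom: str
    pos_cm: float
    a: float
    d: float
    advantageous: str = "M"

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("a is a magnitude; use `advantageous` for direction")
        if self.advantageous not in ("M", "F"):
            raise ValueError("advantageous parent must be 'M' or 'F'")


@dataclass(frozen=True)
class QTLArchitecture:
    """Genetic architecture of one trait.

    ``baseline`` is the trait intercept (the genotypic value of a
    genome carrying the mid-homozygote value at every locus); per-QTL
    effects are deviations from it, so heterosis indices have a
    meaningful absolute scale. ``location_effect_perturbation`` is the
    standard deviation of the multiplicative jitter applied to each
    locus's (a, d) when phenotypes are re-drawn for a second
    environment (see :func:`perturbed_architecture`).
    """

    loci: tuple[QTL, ...]
    residual_sd: float
    trait: str = "trait"
    baseline: float = 0.0
    location_effect_perturbation: float = 0.0

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        object.__setattr__(self, "loci", tuple(self.loci))

    def validate_against(self, cfg: SimConfig) -> None:
        lengths = cfg.chrom_lengths_cm
        for q in self.loci:
            if q.chrom not in lengths:
                raise ValueError(f"QTL on unknown chromosome {q.chrom}")
            if not 0 <= q.pos_cm <= lengths[q.chrom]:
                raise ValueError(
                    f"QTL at {q.pos_cm} cM outside {q.chrom} (0..{lengths[q.chrom]} cM)"
                )


@dataclass(frozen=True)
class Gamete:
    """A recombinant gamete as a mosaic of parental origins.

    ``breakpoints`` are ascending crossover positions (cM) in the open
    interval (0, length); the origin switches at each one, starting from
    ``first_origin`` (1 = male-parent haplotype, 0 = female-parent).
    """

    length_cm: float
    breakpoints: np.ndarray
    first_origin: int

    def origin_at(self, pos_cm) -> np.ndarray:
        """Parental origin (1 = M, 0 = F) at each query position."""
        k = np.searchsorted(self.breakpoints, np.asarray(pos_cm, dtype=float), side="right")
        return (self.first_origin ^ (k & 1)).astype(np.int8)

    @property
    def segments(self) -> list[tuple[float, float, int]]:
        """``(start cM, end cM, origin)`` tiles of [0, length]."""
        cuts = [0.0, *map(float, self.breakpoints), self.length_cm]
        out = []
        origin = self.first_origin
        for s, e in zip(cuts[:-1], cuts[1:]):
            out.append((s, e, origin))
            origin ^= 1
        return out


@dataclass
class F2Individual:
    """Ground-truth genome of one F2 plant: two gametes per chromosome."""

    name: str
    gametes: dict[str, tuple[Gamete, Gamete]]

    def genotype_at(self, chrom: str, pos_cm) -> np.ndarray:
        g1, g2 = self.gametes[chrom]
        return (g1.origin_at(pos_cm) + g2.origin_at(pos_cm)).astype(np.int8)

    def crossover_count(self, chrom: str) -> int:
        g1, g2 = self.gametes[chrom]
        return len(g1.breakpoints) + len(g2.breakpoints)


@dataclass
class TraitTable:
    """Phenotypes of the F2 individuals plus line means.

    ``line_means`` has rows ``P_M`` (male parent), ``P_F`` (female
    parent) and ``F1``, holding genotypic values of the all-MM, all-FF
    and all-heterozygous genomes respectively.
    """

    values: pd.DataFrame  # index: individual, columns: traits
    line_means: pd.DataFrame  # index: P_M, P_F, F1

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


def simulate_gamete(length_cm: float, rng: np.random.Generator) -> Gamete:
    """Draw one gamete under the Haldane model.

    The crossover count is Poisson with mean ``length_cm / 100`` (the
    map length in Morgans), breakpoints are uniform on (0, length), and
    the starting parental origin is a fair coin flip — no chiasma
    interference.
    """
    if length_cm < 0:
        raise ValueError("chromosome genetic length must be >= 0")
    n_xo = rng.poisson(length_cm / 100.0)
    breaks = np.sort(rng.uniform(0.0, length_cm, size=n_xo)) if n_xo else np.empty(0)
    return Gamete(length_cm, breaks, int(rng.integers(2)))


def _genotypic_value(arch: QTLArchitecture, codes_per_locus: np.ndarray) -> np.ndarray:
    """Baseline plus per-QTL genotypic values; codes is (n, n_loci)."""
    total = np.full(codes_per_locus.shape[0], arch.baseline)
    for j, q in enumerate(arch.loci):
        g = codes_per_locus[:, j]
        sign = 1.0 if q.advantageous == "M" else -1.0
        hom = q.a * sign * (g - 1)  # +a advantageous hom, -a the other
        val = np.where(g == MF, q.d, hom)
        total += val
    return total


def simulate_f2_population(
    cfg: SimConfig,
    architectures: QTLArchitecture | Sequence[QTLArchitecture],
    rng: np.random.Generator | None = None,
) -> tuple[list[F2Individual], TraitTable]:
    """Simulate F2 genomes and phenotypes for one or more traits.

    Each individual is the union of two independently drawn gametes per
    chromosome; its phenotype per trait is the sum of per-QTL genotypic
    values plus N(0, residual_sd) noise. Parental-line and F1 means are
    the genotypic values of the all-homozygous and all-heterozygous
    genomes.
    """
    if isinstance(architectures, QTLArchitecture):
        architectures = [architectures]
    for arch in architectures:
        arch.validate_against(cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    population: list[F2Individual] = []
    for i in range(cfg.n_individuals):
        gametes = {
            name: (simulate_gamete(cm, rng), simulate_gamete(cm, rng))
            for name, (_, cm) in zip(cfg.chrom_names, cfg.chromosomes)
        }
        population.append(F2Individual(f"F2_{i + 1:05d}", gametes))

    values = {}
    line_rows = {"P_M": {}, "P_F": {}, "F1": {}}
    for arch in architectures:
        if arch.loci:
            codes = np.column_stack(
                [
                    np.concatenate([ind.genotype_at(q.chrom, [q.pos_cm]) for ind in population])
                    for q in arch.loci
                ]
            )
        else:
            codes = np.zeros((cfg.n_individuals, 0), dtype=np.int8)
        geno_val = _genotypic_value(arch, codes)
        values[arch.trait] = geno_val + rng.normal(0.0, arch.residual_sd, cfg.n_individuals)
        n = len(arch.loci)
        all_mm = np.full((1, n), MM, dtype=np.int8)
        all_ff = np.full((1, n), FF, dtype=np.int8)
        all_mf = np.full((1, n), MF, dtype=np.int8)
        line_rows["P_M"][arch.trait] = float(_genotypic_value(arch, all_mm)[0])
        line_rows["P_F"][arch.trait] = float(_genotypic_value(arch, all_ff)[0])
        line_rows["F1"][arch.trait] = float(_genotypic_value(arch, all_mf)[0])

    names = [ind.name for ind in population]
    table = TraitTable(
        values=pd.DataFrame(values, index=pd.Index(names, name="individual")),
        line_means=pd.DataFrame(line_rows).T.rename_axis("line"),
    )
    return population, table


def perturbed_architecture(arch: QTLArchitecture, rng: np.random.Generator) -> QTLArchitecture:
    """Jitter each locus's effects for a second environment.

    ``a`` is scaled by ``exp(N(0, s))`` (stays non-negative) and ``d``
    by ``1 + N(0, s)`` with ``s = location_effect_perturbation``,
    emulating genotype-by-environment shifts in effect size and in
    dominance degree.
    """
    s = arch.location_effect_perturbation
    loci = tuple(
        dataclasses.replace(
            q,
            a=q.a * math.exp(rng.normal(0.0, s)),
            d=q.d * (1.0 + rng.normal(0.0, s)),
        )
        for q in arch.loci
    )
    return dataclasses.replace(arch, loci=loci)


# ---------------------------------------------------------------------------
# Parental haplotypes and skim-seq observations
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_parental_haplotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Informative SNPs between two fully homozygous inbred parents.

    Returns a frame with columns ``chrom, pos, ref, alt, m_allele,
    f_allele`` (nucleotides; m/f differ at every row). SNP counts per
    chromosome are ``round(snp_density × Mb)`` with uniform positions;
    no SNPs fall inside configured non-informative intervals.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    frames = []
    for name, (bp_len, _) in zip(cfg.chrom_names, cfg.chromosomes):
        n_snp = int(round(cfg.snp_density * bp_len / 1e6))
        pos = np.sort(rng.integers(1, bp_len + 1, size=n_snp))
        pos = np.unique(pos)
        for c, s, e in cfg.noninformative_intervals:
            if c == name:
                pos = pos[(pos < s) | (pos > e)]
        ref_i = rng.integers(0, 4, size=len(pos))
        alt_i = (ref_i + rng.integers(1, 4, size=len(pos))) % 4
        m_is_ref = rng.random(len(pos)) < 0.5
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "ref": _BASES[ref_i],
                    "alt": _BASES[alt_i],
                    "m_allele": np.where(m_is_ref, _BASES[ref_i], _BASES[alt_i]),
                    "f_allele": np.where(m_is_ref, _BASES[alt_i], _BASES[ref_i]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_observations(
    population: Iterable[F2Individual],
    parents: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Skim-sequencing allele observations for every individual.

    Per individual and SNP, the number of observations is
    Poisson(coverage); each observation samples one of the individual's
    two haplotypes uniformly and reports that parental allele, flipped
    with probability ``obs_error_rate``. Output columns:
    ``individual, chrom, pos, allele`` with allele in {"M", "F"},
    sorted by individual, chromosome and position.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    by_chrom = {c: g for c, g in parents.groupby("chrom", sort=False)}
    rows = []
    for ind in population:
        for chrom, snps in by_chrom.items():
            pos_bp = snps["pos"].to_numpy()
            counts = rng.poisson(cfg.coverage, size=len(pos_bp))
            tot = int(counts.sum())
            if tot == 0:
                continue
            pos_rep = np.repeat(pos_bp, counts)
            g_rep = np.repeat(ind.genotype_at(chrom, cfg.bp_to_cm(chrom, pos_bp)), counts)
            is_m = rng.random(tot) < g_rep / 2.0
            flip = rng.random(tot) < cfg.obs_error_rate
            is_m ^= flip
            rows.append(
                pd.DataFrame(
                    {
                        "individual": ind.name,
                        "chrom": chrom,
                        "pos": pos_rep,
                        "allele": np.where(is_m, "M", "F"),
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["individual", "chrom", "pos", "allele"])
    obs = pd.concat(rows, ignore_index=True)
    return obs.sort_values(["individual", "chrom", "pos"], kind="stable").reset_index(drop=True)


def genotypes_at(
    population: Sequence[F2Individual], chrom: str, positions_cm: np.ndarray
) -> np.ndarray:
    """True genotype codes, shape ``(n_individuals, n_positions)``."""
    positions_cm = np.asarray(positions_cm, dtype=float)
    return np.vstack([ind.genotype_at(chrom, positions_cm) for ind in population])


def truth_mosaics(population: Sequence[F2Individual], cfg: SimConfig) -> pd.DataFrame:
    """True genotype segments in physical coordinates.

    Returns the same shape the skim-seq caller emits — columns
    ``individual, chrom, start, end, genotype`` with 1-based inclusive
    bp spans tiling each chromosome — so bin maps can be built from
    either truth or calls interchangeably.
    """
    rows = []
    for ind in population:
        for chrom in cfg.chrom_names:
            g1, g2 = ind.gametes[chrom]
            cuts_cm = np.unique(np.concatenate([g1.breakpoints, g2.breakpoints]))
            cuts_bp = cfg.cm_to_bp(chrom, cuts_cm) if len(cuts_cm) else np.empty(0, dtype=np.int64)
            L = cfg.chrom_lengths_bp[chrom]
            mids_cm = ((np.concatenate([[0.0], cuts_cm]) + np.concatenate([cuts_cm, [cfg.chrom_lengths_cm[chrom]]])) / 2)
            genos = ind.genotype_at(chrom, mids_cm)
            starts = np.concatenate([[1], cuts_bp + 1])
            ends = np.concatenate([cuts_bp, [L]])
            keep = starts <= ends  # drop zero-width segments after rounding
            prev = None
            for s, e, g in zip(starts[keep], ends[keep], genos[keep]):
                if prev is not None and prev[4] == g:
                    prev[3] = int(e)  # merge adjacent equal genotypes
                else:
                    prev = [ind.name, chrom, int(s), int(e), int(g)]
                    rows.append(prev)
    return pd.DataFrame(rows, columns=["individual", "chrom", "start", "end", "genotype"])


# ---------------------------------------------------------------------------
# The published 17-locus replication table (the only real-data fixture)
# ---------------------------------------------------------------------------

# Columns: trait, chrom, peak Mb, Shandong (LOD, d/a, class, advantaged
# parent, unstable-ratio footnote), Heilongjiang (ANOVA P printed, d/a,
# class, advantaged parent). Class/parent are None where the printed
# table says NA (effects not evaluable at P >= 0.05). The two
# "unstable" rows are the footnoted outrageously-high d/a ratios caused
# by near-identical homozygote means.
_OD = "Overdominance"
_CID = "Complete–incomplete dominance"
_ADD = "Additive effect"
_Z58 = "Zheng58"  # female parent of Zhengdan958
_C72 = "Chang7-2"  # male parent

_TABLE1 = [
    ("Hundred grain weight", 1, 36, 12.4, 0.21, _ADD, _Z58, False, "<2e-16", 0.74, _CID, _Z58),
    ("Kernel yield per ear", 1, 95, 3.9, 2.25, _OD, _C72, False, "5.5E-09", 1.82, _OD, _C72),
    ("Plant height", 1, 218, 8.0, 2.75, _OD, _C72, False, "1.9E-07", 1.32, _OD, _C72),
    ("Kernel yield per ear", 2, 55, 7.4, 3.26, _OD, _C72, False, "7.1E-05", 3.02, _OD, _C72),
    ("Ear diameter", 2, 158, 8.7, 0.25, _CID, _C72, False, "<2e-16", 0.51, _CID, _C72),
    ("Ear diameter", 2, 225, 3.8, 1.13, _CID, _C72, False, "5.0E-03", 0.99, _CID, _C72),
    ("Kernel yield per ear", 3, 19, 6.8, 46.16, _OD, _Z58, True, "1.1E-05", 3.11, _OD, _Z58),
    ("Bottom leaf length", 3, 184, 6.5, 0.33, _CID, _Z58, False, "8.2E-12", 0.92, _CID, _Z58),
    ("Kernel yield per ear", 4, 191, 6.7, 0.97, _CID, _Z58, False, "1.1E-08", 4.04, _OD, _Z58),
    ("Bottom leaf width", 5, 29, 6.0, 0.96, _CID, _Z58, False, "1.1E-03", 0.65, _CID, _Z58),
    ("Plant height", 5, 214, 3.7, 49.92, _OD, _Z58, True, "1.8E-01", -0.37, None, None),
    ("Bottom leaf length", 6, 101, 9.5, 0.79, _CID, _Z58, False, "1.1E-04", 1.48, _OD, _Z58),
    ("Kernel yield per ear", 6, 169, 7.4, 6.36, _OD, _C72, False, "6.5E-02", 5.60, None, None),
    ("Bottom leaf length", 7, 169, 38.3, 0.33, _CID, _Z58, False, "<2e-16", 0.30, _CID, _Z58),
    ("Kernel yield per ear", 8, 55, 10.0, 0.87, _CID, _C72, False, "4.1E-03", 1.23, _CID, _Z58),
    ("Ear height", 8, 134, 18.8, -0.06, _ADD, _C72, False, "2.0E-04", 0.05, _ADD, _C72),
    ("Average kernels in ear row", 10, 138, 4.2, 1.36, _OD, _Z58, False, "1.0E-06", 4.95, _OD, _Z58),
]

PARENT_ROLE = {_Z58: "F", _C72: "M"}


def table1_fixture() -> pd.DataFrame:
    """The published two-location replication of 17 heterotic loci.

    One row per locus, with Shandong (genome-wide scan) and
    Heilongjiang (targeted marker assay) results. ``heilongjiang_p``
    is numeric ("<2e-16" is stored as 2e-16; the printed string is kept
    in ``heilongjiang_p_printed``); ``heilongjiang_evaluable`` is False
    for the two loci whose effects could not be evaluated (P >= 0.05);
    ``shandong_unstable_ratio`` marks the two footnoted loci whose
    near-equal homozygote means produced outlying d/a ratios.
    """
    df = pd.DataFrame(
        _TABLE1,
        columns=[
            "trait",
            "chrom",
            "peak_mb",
            "shandong_lod",
            "shandong_d_over_a",
            "shandong_class",
            "shandong_parent",
            "shandong_unstable_ratio",
            "heilongjiang_p_printed",
            "heilongjiang_d_over_a",
            "heilongjiang_class",
            "heilongjiang_parent",
        ],
    )
    df["heilongjiang_p"] = [float(p.lstrip("<")) for p in df["heilongjiang_p_printed"]]
    df["heilongjiang_evaluable"] = df["heilongjiang_p"] < 0.05
    return df


# ---------------------------------------------------------------------------
# File I/O (all outputs round-trip through the readers below)
# ---------------------------------------------------------------------------


def write_parental_vcf(parents: pd.DataFrame, cfg: SimConfig, path) -> None:
    """Write the informative SNP set as a two-sample phased VCF.

    Samples are named ``M`` and ``F``; each is homozygous for its own
    allele at every site (``0|0`` / ``1|1`` depending on which parent
    carries REF).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hetqtl.simdata\n")
        for name, (bp_len, _) in zip(cfg.chrom_names, cfg.chromosomes):
            fh.write(f"##contig=<ID={name},length={bp_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tM\tF\n")
        for row in parents.itertuples(index=False):
            m_gt, f_gt = ("0|0", "1|1") if row.m_allele == row.ref else ("1|1", "0|0")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{m_gt}\t{f_gt}\n"
            )


def read_parental_vcf(path) -> pd.DataFrame:
    """Read a two-sample parental VCF back into the haplotype frame."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    i_m, i_f = samples.index("M"), samples.index("F")
    rows = []
    for var in vcf:
        alleles = [var.REF] + var.ALT
        gt_m = alleles[var.genotypes[i_m][0]]
        gt_f = alleles[var.genotypes[i_f][0]]
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], gt_m, gt_f))
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "m_allele", "f_allele"])


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, sep="\t", index=False)


def read_observations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual": str, "chrom": str, "pos": np.int64, "allele": str})


def write_traits(table: TraitTable, values_path, line_means_path=None) -> None:
    table.values.to_csv(values_path, sep="\t")
    if line_means_path is not None:
        table.line_means.to_csv(line_means_path, sep="\t", index_label="line")


def read_traits(values_path, line_means_path=None) -> TraitTable:
    values = pd.read_csv(values_path, sep="\t", index_col="individual")
    if line_means_path is not None:
        line_means = pd.read_csv(line_means_path, sep="\t", index_col="line")
    else:
        line_means = pd.DataFrame(columns=values.columns)
    return TraitTable(values=values, line_means=line_means)


def write_config(cfg: SimConfig, path) -> None:
    """Flat key=value text serialization of a :class:`SimConfig`."""
    with open(path, "w") as fh:
        fh.write(f"n_individuals={cfg.n_individuals}\n")
        chroms = ",".join(f"{bp}:{cm}" for bp, cm in cfg.chromosomes)
        fh.write(f"chromosomes={chroms}\n")
        fh.write(f"snp_density={cfg.snp_density}\n")
        fh.write(f"coverage={cfg.coverage}\n")
        fh.write(f"obs_error_rate={cfg.obs_error_rate}\n")
        fh.write(f"seed={cfg.seed}\n")
        if cfg.noninformative_intervals:
            ni = ",".join(f"{c}:{s}:{e}" for c, s, e in cfg.noninformative_intervals)
            fh.write(f"noninformative_intervals={ni}\n")


def read_config(path) -> SimConfig:
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                k, _, v = line.partition("=")
                kv[k] = v
    chroms = tuple(
        (int(p.split(":")[0]), float(p.split(":")[1])) for p in kv["chromosomes"].split(",")
    )
    ni = ()
    if kv.get("noninformative_intervals"):
        ni = tuple(
            (p.split(":")[0], int(p.split(":")[1]), int(p.split(":")[2]))
            for p in kv["noninformative_intervals"].split(",")
        )
    return SimConfig(
        n_individuals=int(kv["n_individuals"]),
        chromosomes=chroms,
        snp_density=float(kv["snp_density"]),
        coverage=float(kv["coverage"]),
        obs_error_rate=float(kv["obs_error_rate"]),
        seed=int(kv["seed"]),
        noninformative_intervals=ni,
    )
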
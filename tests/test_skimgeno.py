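"""Window calling, breakpoint inference, bin maps and recombination stats."""

import numpy as np
import pandas as pd
import pytest

from hetqtl import FF, MF, MM, MISSING, simdata, skimgeno


def _obs(individual, chrom, positions, alleles):
    return pd.DataFrame(
        {"individual": individual, "chrom": chrom, "pos": positions, "allele": list(alleles)}
    )


def _calls(individual, chrom, starts, ends, calls):
    return pd.DataFrame(
        {
            "individual": individual,
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "n_m": 12,
            "n_f": 0,
            "call": np.asarray(calls, dtype=np.int8),
        }
    )


class TestWindowCalls:
    def test_pure_m_window_called_mm(self):
        obs = _obs("i1", "chr1", np.arange(1, 13) * 1000, "M" * 12)
        calls = skimgeno.call_windows(obs, window_size=12, min_obs=10)
        assert list(calls["call"]) == [MM]
        assert calls["n_m"].iloc[0] == 12 and calls["n_f"].iloc[0] == 0

    def test_balanced_window_called_mf(self):
        obs = _obs("i1", "chr1", np.arange(1, 13) * 1000, "MF" * 6)
        calls = skimgeno.call_windows(obs, window_size=12, min_obs=10)
        assert list(calls["call"]) == [MF]

    def test_missing_iff_below_min_obs(self):
        # 20 observations -> one full window of 15 and a trailing 5
        obs = _obs("i1", "chr1", np.arange(1, 21) * 1000, "M" * 20)
        calls = skimgeno.call_windows(obs, window_size=15, min_obs=10)
        assert list(calls["call"]) == [MM, MISSING]
        n_tot = calls["n_m"] + calls["n_f"]
        assert ((calls["call"] == MISSING) == (n_tot < 10)).all()

    def test_unsorted_observations_rejected(self):
        obs = _obs("i1", "chr1", [3000, 1000, 2000], "MMM")
        with pytest.raises(ValueError, match="sorted"):
            skimgeno.call_windows(obs)

    def test_unknown_allele_symbol_rejected(self):
        obs = _obs("i1", "chr1", [1000, 2000], ["M", "X"])
        with pytest.raises(ValueError, match="allele"):
            skimgeno.call_windows(obs)

    def test_het_band_boundaries(self):
        # p = 0.85 exactly -> MM (p >= upper); p = 0.15 exactly -> FF
        obs_hi = _obs("i1", "chr1", np.arange(1, 21) * 100, "M" * 17 + "F" * 3)
        obs_lo = _obs("i1", "chr1", np.arange(1, 21) * 100, "M" * 3 + "F" * 17)
        hi = skimgeno.call_windows(obs_hi, window_size=20, min_obs=10)
        lo = skimgeno.call_windows(obs_lo, window_size=20, min_obs=10)
        assert hi["call"].iloc[0] == MM
        assert lo["call"].iloc[0] == FF


class TestMosaics:
    def test_single_breakpoint_at_window_midpoint(self):
        """[MM x10, MF x10] -> one breakpoint halfway between the last
        MM window and the first MF window."""
        starts = np.arange(20) * 1000 + 1
        ends = starts + 800
        calls = _calls("i1", "chr1", starts, ends, [MM] * 10 + [MF] * 10)
        mosaic, flagged = skimgeno.infer_mosaics(calls, {"chr1": 100_000})
        assert not flagged
        assert len(mosaic) == 2
        expected_cut = (ends[9] + starts[10]) // 2
        assert mosaic["end"].iloc[0] == expected_cut
        assert mosaic["start"].iloc[1] == expected_cut + 1
        assert list(mosaic["genotype"]) == [MM, MF]
        # segments tile [1, L]
        assert mosaic["start"].iloc[0] == 1 and mosaic["end"].iloc[1] == 100_000

    def test_singleton_smoothed_away(self):
        """[MM x5, FF, MM x5] -> the lone discordant window is rewritten
        and no breakpoint remains."""
        starts = np.arange(11) * 1000 + 1
        calls = _calls("i1", "chr1", starts, starts + 800, [MM] * 5 + [FF] + [MM] * 5)
        mosaic, _ = skimgeno.infer_mosaics(calls, {"chr1": 50_000})
        assert len(mosaic) == 1
        assert mosaic["genotype"].iloc[0] == MM

    def test_smoothing_preserves_runs(self):
        starts = np.arange(10) * 1000 + 1
        calls = _calls("i1", "chr1", starts, starts + 800, [MM] * 5 + [FF] * 5)
        mosaic, _ = skimgeno.infer_mosaics(calls, {"chr1": 50_000})
        assert list(mosaic["genotype"]) == [MM, FF]

    def test_all_missing_chromosome_flagged(self):
        starts = np.arange(5) * 1000 + 1
        calls = _calls("i1", "chr1", starts, starts + 800, [MISSING] * 5)
        mosaic, flagged = skimgeno.infer_mosaics(calls, {"chr1": 50_000})
        assert flagged == [("i1", "chr1")]
        assert len(mosaic) == 0


class TestBinMap:
    def test_two_individuals_three_bins(self):
        """Breakpoints at 10 Mb and 20 Mb -> three bins tiling the
        chromosome."""
        mosaics = pd.DataFrame(
            [
                ("i1", "chr1", 1, 10_000_000, MM),
                ("i1", "chr1", 10_000_001, 30_000_000, MF),
                ("i2", "chr1", 1, 20_000_000, FF),
                ("i2", "chr1", 20_000_001, 30_000_000, MF),
            ],
            columns=["individual", "chrom", "start", "end", "genotype"],
        )
        bm = skimgeno.build_bin_map(mosaics, {"chr1": 30_000_000})
        assert bm.n_bins == 3
        assert list(bm.bins["start"]) == [1, 10_000_001, 20_000_001]
        assert list(bm.bins["end"]) == [10_000_000, 20_000_000, 30_000_000]
        assert list(bm.G[:, 0]) == [MM, MF, MF]
        assert list(bm.G[:, 1]) == [FF, FF, MF]

    def test_requires_two_individuals(self):
        mosaics = pd.DataFrame(
            [("i1", "chr1", 1, 100, MM)],
            columns=["individual", "chrom", "start", "end", "genotype"],
        )
        with pytest.raises(ValueError):
            skimgeno.build_bin_map(mosaics, {"chr1": 100})

    def test_frequencies_sum_to_one_and_matrix_shape(self, small_cfg, small_population):
        pop, _ = small_population
        mosaics = simdata.truth_mosaics(pop, small_cfg)
        bm = skimgeno.build_bin_map(mosaics, small_cfg.chrom_lengths_bp)
        assert bm.G.shape[1] == len(pop)
        freqs = bm.frequencies()
        total = freqs[["freq_MM", "freq_MF", "freq_FF"]].sum(axis=1)
        np.testing.assert_allclose(total[freqs["n_called"] > 0], 1.0)
        # bins tile each chromosome exactly
        for chrom, length in small_cfg.chrom_lengths_bp.items():
            sub = bm.bins[bm.bins["chrom"] == chrom]
            assert sub["start"].iloc[0] == 1 and sub["end"].iloc[-1] == length
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1] + 1).all()

    def test_filter_bins_drops_low_call_rate(self):
        bins = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [1, 51], "end": [50, 100]})
        G = np.array([[MM, MF, FF, MM], [MISSING, MISSING, MISSING, MM]], dtype=np.int8)
        bm = skimgeno.BinGenotypeMatrix(bins=bins, G=G, individuals=list("abcd"))
        out = skimgeno.filter_bins(bm, min_call_rate=0.8)
        assert out.n_bins == 1 and out.bins["start"].iloc[0] == 1


class TestCallerOnSimulatedData:
    def test_noiseless_high_coverage_calls_match_truth(self):
        """With zero observation error, deep coverage and windows
        pooled deeply enough that the heterozygote binomial tail is
        negligible, every window call equals the true genotype at the
        window midpoint and every individual recovers its exact
        crossover count."""
        cfg = simdata.SimConfig(
            n_individuals=40,
            chromosomes=((40_000_000, 40.0),),
            snp_density=100.0,
            coverage=5.0,
            obs_error_rate=0.0,
            seed=21,
        )
        pop, _ = simdata.simulate_f2_population(cfg, simdata.QTLArchitecture(loci=(), residual_sd=1.0))
        parents = simdata.simulate_parental_haplotypes(cfg)
        obs = simdata.simulate_observations(pop, parents, cfg)
        calls = skimgeno.call_windows(obs, window_size=40, min_obs=20)
        by_name = {ind.name: ind for ind in pop}
        mids_bp = ((calls["start"] + calls["end"]) / 2).to_numpy()
        ok = calls["call"].to_numpy() != MISSING
        window_span = np.median((calls["end"] - calls["start"]).to_numpy())
        correct = 0
        checked = 0
        for (_, row), mid in zip(calls[ok].iterrows(), mids_bp[ok]):
            ind = by_name[row["individual"]]
            g1, g2 = ind.gametes[row["chrom"]]
            # skip windows straddling a true crossover: their mixed
            # counts legitimately call either side
            cuts_cm = np.concatenate([g1.breakpoints, g2.breakpoints])
            cuts_bp = cfg.cm_to_bp(row["chrom"], cuts_cm) if len(cuts_cm) else np.array([])
            if len(cuts_bp) and np.min(np.abs(cuts_bp - mid)) < window_span:
                continue
            truth = ind.genotype_at(row["chrom"], cfg.bp_to_cm(row["chrom"], [mid]))[0]
            correct += int(row["call"] == truth)
            checked += 1
        assert checked > 0 and correct == checked
        # exact segment-count recovery
        mosaics, flagged = skimgeno.infer_mosaics(calls, cfg.chrom_lengths_bp)
        assert not flagged
        events = skimgeno.count_recombination_events(mosaics)
        for row in events.itertuples(index=False):
            assert row.events == by_name[row.individual].crossover_count(row.chrom)

    def test_breakpoint_recovery_at_skim_coverage(self):
        """At 0.2x coverage and 1% observation error, >= 95% of the
        detectable true crossovers are recovered to within one window.

        Crossovers closer than one window span to a chromosome end, or
        closer than two spans to another crossover in the same
        individual, are excluded: the resulting genotype segment is
        shorter than the caller's resolution element, so no windowed
        method can see it. The recovery tolerance is 1.5x the median
        window span (spans vary with the Poisson observation spacing).
        """
        cfg = simdata.SimConfig(
            n_individuals=400,
            chromosomes=((60_000_000, 60.0), (60_000_000, 60.0)),
            snp_density=100.0,
            coverage=0.2,
            obs_error_rate=0.01,
            seed=31,
        )
        pop, _ = simdata.simulate_f2_population(cfg, simdata.QTLArchitecture(loci=(), residual_sd=1.0))
        parents = simdata.simulate_parental_haplotypes(cfg)
        obs = simdata.simulate_observations(pop, parents, cfg)
        calls = skimgeno.call_windows(obs)
        window_span = float(np.median((calls["end"] - calls["start"]).to_numpy()))
        mosaics, _ = skimgeno.infer_mosaics(calls, cfg.chrom_lengths_bp)
        inferred = {
            key: grp.loc[grp["end"] < cfg.chrom_lengths_bp[key[1]], "end"].to_numpy()
            for key, grp in mosaics.groupby(["individual", "chrom"], sort=False)
        }
        recovered = total = 0
        for ind in pop:
            for chrom in cfg.chrom_names:
                g1, g2 = ind.gametes[chrom]
                cuts_cm = np.concatenate([g1.breakpoints, g2.breakpoints])
                if len(cuts_cm) == 0:
                    continue
                L = cfg.chrom_lengths_bp[chrom]
                true_bp = cfg.cm_to_bp(chrom, np.sort(cuts_cm))
                found = inferred.get((ind.name, chrom), np.array([]))
                for j, t in enumerate(true_bp):
                    if min(t, L - t) < window_span:
                        continue  # terminal segment below resolution
                    others = np.delete(true_bp, j)
                    if len(others) and np.min(np.abs(others - t)) < 2 * window_span:
                        continue  # merged double crossover below resolution
                    total += 1
                    if len(found) and np.min(np.abs(found - t)) <= 1.5 * window_span:
                        recovered += 1
        assert total > 500
        assert recovered / total >= 0.95

    def test_accuracy_monotone_in_coverage_and_window(self):
        """Call accuracy against truth does not decrease when coverage
        or window size increases (fixed seed grid)."""

        def accuracy(coverage, window_size):
            cfg = simdata.SimConfig(
                n_individuals=60,
                chromosomes=((30_000_000, 30.0),),
                snp_density=100.0,
                coverage=coverage,
                obs_error_rate=0.03,
                seed=41,
            )
            pop, _ = simdata.simulate_f2_population(
                cfg, simdata.QTLArchitecture(loci=(), residual_sd=1.0)
            )
            parents = simdata.simulate_parental_haplotypes(cfg)
            obs = simdata.simulate_observations(pop, parents, cfg)
            calls = skimgeno.call_windows(obs, window_size=window_size, min_obs=min(10, window_size))
            ok = calls["call"].to_numpy() != MISSING
            by_name = {ind.name: ind for ind in pop}
            mids = ((calls["start"] + calls["end"]) / 2).to_numpy()
            good = 0
            for (_, row), mid in zip(calls[ok].iterrows(), mids[ok]):
                truth = by_name[row["individual"]].genotype_at(
                    row["chrom"], cfg.bp_to_cm(row["chrom"], [mid])
                )[0]
                good += int(row["call"] == truth)
            return good / ok.sum()

        acc_cov = [accuracy(c, 15) for c in (0.05, 0.2, 0.8)]
        assert acc_cov[0] <= acc_cov[1] + 0.01 and acc_cov[1] <= acc_cov[2] + 0.01
        acc_win = [accuracy(0.2, w) for w in (5, 15, 30)]
        assert acc_win[0] <= acc_win[1] + 0.01 and acc_win[1] <= acc_win[2] + 0.01

    def test_low_min_obs_depresses_heterozygote_calls(self):
        """Calling single observations as genotypes (window 1) cannot
        see heterozygosity: the MF fraction collapses, motivating
        pooled windows."""
        cfg = simdata.SimConfig(
            n_individuals=50,
            chromosomes=((20_000_000, 20.0),),
            coverage=0.3,
            obs_error_rate=0.0,
            seed=51,
        )
        pop, _ = simdata.simulate_f2_population(cfg, simdata.QTLArchitecture(loci=(), residual_sd=1.0))
        parents = simdata.simulate_parental_haplotypes(cfg)
        obs = simdata.simulate_observations(pop, parents, cfg)
        narrow = skimgeno.call_windows(obs, window_size=1, min_obs=1)
        pooled = skimgeno.call_windows(obs, window_size=15, min_obs=10)
        frac_mf_narrow = (narrow["call"] == MF).sum() / (narrow["call"] != MISSING).sum()
        frac_mf_pooled = (pooled["call"] == MF).sum() / (pooled["call"] != MISSING).sum()
        assert frac_mf_narrow < 0.1  # single reads can never show both alleles
        assert frac_mf_pooled > 0.35


class TestRecombinationStatistics:
    def test_zero_events_on_single_segment(self):
        mosaics = pd.DataFrame(
            [("i1", "chr1", 1, 100, MM), ("i2", "chr1", 1, 100, MF)],
            columns=["individual", "chrom", "start", "end", "genotype"],
        )
        events = skimgeno.count_recombination_events(mosaics)
        assert (events["events"] == 0).all()

    def test_mean_events_match_map_length(self, small_cfg, small_population):
        """Mean per-individual events per chromosome ~ 2 x Morgans."""
        pop, _ = small_population
        mosaics = simdata.truth_mosaics(pop, small_cfg)
        events = skimgeno.count_recombination_events(mosaics)
        assert (events["events"] >= 0).all()
        for chrom, cm in small_cfg.chrom_lengths_cm.items():
            mean = events.loc[events["chrom"] == chrom, "events"].mean()
            expected = 2 * cm / 100
            se = np.sqrt(expected / len(pop))
            assert abs(mean - expected) < 4 * se

    def test_profile_flat_conserves_map_length_and_zero_window_rejected(
        self, small_cfg, small_population
    ):
        pop, _ = small_population
        mosaics = simdata.truth_mosaics(pop, small_cfg)
        profile = skimgeno.recombination_profile(
            mosaics, small_cfg.chrom_lengths_bp, n_individuals=len(pop), window_mb=10.0
        )
        # conservation: total cM across windows ~ realized map length
        total_cm = profile["cm"].sum()
        assert total_cm == pytest.approx(small_cfg.total_cm, rel=0.15)
        # uniform map -> no window wildly off the chromosome mean rate
        for chrom in small_cfg.chrom_names:
            rates = profile.loc[profile["chrom"] == chrom, "cm_per_mb"]
            assert rates.std() / rates.mean() < 0.6
        with pytest.raises(ValueError):
            skimgeno.recombination_profile(
                mosaics, small_cfg.chrom_lengths_bp, n_individuals=len(pop), window_mb=0
            )

    def test_suppressed_recombination_interval_shows_zero_rate(self):
        """A chromosome whose middle has no genetic length yields a
        near-zero cM/Mb profile there, as for regions of suppressed
        recombination (e.g. inversions between the parents)."""
        # emulate suppression by concentrating all crossovers outside
        # the middle third: build mosaics whose cuts avoid 20-40 Mb
        rng = np.random.default_rng(61)
        rows = []
        for i in range(200):
            name = f"i{i}"
            cut = rng.choice([rng.integers(1, 20_000_000), rng.integers(40_000_000, 60_000_000)])
            g = [MM, MF] if rng.random() < 0.5 else [MF, FF]
            rows += [(name, "chr1", 1, int(cut), g[0]), (name, "chr1", int(cut) + 1, 60_000_000, g[1])]
        mosaics = pd.DataFrame(rows, columns=["individual", "chrom", "start", "end", "genotype"])
        profile = skimgeno.recombination_profile(
            mosaics, {"chr1": 60_000_000}, n_individuals=200, window_mb=10.0
        )
        mid = profile[(profile["start"] >= 20_000_001) & (profile["end"] <= 40_000_000)]
        outer = profile[(profile["start"] < 20_000_001) | (profile["end"] > 40_000_000)]
        assert mid["cm_per_mb"].max() == 0.0
        assert outer["cm_per_mb"].mean() > 0


class TestBinMatrixIO:
    def test_roundtrip(self, tmp_path, small_cfg, small_population):
        pop, _ = small_population
        mosaics = simdata.truth_mosaics(pop[:20], small_cfg)
        bm = skimgeno.build_bin_map(mosaics, small_cfg.chrom_lengths_bp)
        path = tmp_path / "bins.tsv"
        skimgeno.write_bin_matrix(bm, path)
        back = skimgeno.read_bin_matrix(path)
        assert back.individuals == bm.individuals
        np.testing.assert_array_equal(back.G, bm.G)
        pd.testing.assert_frame_equal(
            back.bins.astype({"start": "int64", "end": "int64"}),
            bm.bins.astype({"start": "int64", "end": "int64"}),
        )
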
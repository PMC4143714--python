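"""Ped/map I/O, allele orientation, filters and map interpolation."""

import numpy as np
import pandas as pd
import pytest

from kinscan import pedio, simulate
from kinscan.pedio import MISSING, GenotypeMatrix


class TestReadPedmap:
    def test_toy_transcription(self, toy_pedmap):
        records, geno, markers = pedio.read_pedmap(*toy_pedmap)
        assert list(records["iid"]) == ["A", "B"]
        assert geno.n_markers == 2
        # snp1: alleles A A / A C -> C is minor (freq 0.25)
        assert markers.loc[0, "allele_minor"] == "C"
        assert list(geno.codes[:, 0]) == [0, 1]
        # snp2: A C / C C -> A is minor
        assert markers.loc[1, "allele_minor"] == "A"
        assert list(geno.codes[:, 1]) == [1, 0]
        assert markers["freq_minor"].tolist() == [0.25, 0.25]

    def test_zero_allele_is_missing(self, tmp_path):
        (tmp_path / "m.ped").write_text("F A 0 0 1 0 A 0\nF B 0 0 1 0 0 0\n")
        (tmp_path / "m.map").write_text("1 s1 0 1\n")
        _, geno, markers = pedio.read_pedmap(tmp_path / "m.ped", tmp_path / "m.map")
        assert list(geno.codes[:, 0]) == [MISSING, MISSING]
        assert markers.loc[0, "n_missing"] == 2

    def test_column_count_error_names_line(self, tmp_path):
        (tmp_path / "b.ped").write_text("F A 0 0 1 0 A A\nF B 0 0 1 0 A\n")
        (tmp_path / "b.map").write_text("1 s1 0 1\n")
        with pytest.raises(pedio.MalformedFileError, match="line 2"):
            pedio.read_pedmap(tmp_path / "b.ped", tmp_path / "b.map")

    def test_duplicate_individual_rejected(self, tmp_path):
        (tmp_path / "d.ped").write_text("F A 0 0 1 0 A A\nF A 0 0 1 0 A C\n")
        (tmp_path / "d.map").write_text("1 s1 0 1\n")
        with pytest.raises(pedio.DuplicateKeyError):
            pedio.read_pedmap(tmp_path / "d.ped", tmp_path / "d.map")

    def test_round_trip_lossless(self, tmp_path, random_dataset):
        records, geno, markers = random_dataset
        ped, map_ = tmp_path / "rt.ped", tmp_path / "rt.map"
        pedio.write_pedmap(ped, map_, records, geno, markers)
        rec2, geno2, markers2 = pedio.read_pedmap(ped, map_)
        assert np.array_equal(geno.codes, geno2.codes)
        assert geno2.individuals == geno.individuals
        assert list(markers2["marker_id"]) == list(markers["marker_id"])
        assert list(markers2["position_bp"]) == list(markers["position_bp"])


class TestFilters:
    def test_missingness_threshold_inclusive(self):
        codes = np.array([
            [0, 1, 2, 0, 1, MISSING, MISSING, MISSING, MISSING, MISSING],  # 50%
            [0] * 10,                                                      # 0%
            [MISSING] * 9 + [0],                                           # 90%
        ], dtype=np.int8)
        g = GenotypeMatrix([("F", "a"), ("F", "b"), ("F", "c")], codes)
        kept = pedio.filter_individuals_by_missingness(g, 0.8)
        assert [k[1] for k in kept.individuals] == ["a", "b"]
        # exactly at threshold retained
        kept2 = pedio.filter_individuals_by_missingness(g, 0.5)
        assert [k[1] for k in kept2.individuals] == ["a", "b"]
        # vacuous filter
        assert pedio.filter_individuals_by_missingness(g, 1.0).n_individuals == 3

    def test_all_removed_warns(self):
        g = GenotypeMatrix([("F", "a")], np.full((1, 4), MISSING, dtype=np.int8))
        with pytest.warns(UserWarning):
            out = pedio.filter_individuals_by_missingness(g, 0.5)
        assert out.n_individuals == 0

    def test_maf_filter_boundary(self):
        markers = pd.DataFrame({"freq_minor": [0.0, 0.04, 0.05, 0.3]})
        assert list(pedio.filter_markers_maf(markers, 0.05)) == [2, 3]
        assert list(pedio.filter_markers_maf(markers, 0.0)) == [0, 1, 2, 3]
        assert list(pedio.filter_markers_maf(markers, 0.5)) == []

    def test_filters_idempotent(self, random_dataset):
        _, geno, markers = random_dataset
        once = pedio.filter_individuals_by_missingness(geno, 0.04)
        twice = pedio.filter_individuals_by_missingness(once, 0.04)
        assert np.array_equal(once.codes, twice.codes)
        keep = pedio.filter_markers_maf(markers, 0.1)
        again = pedio.filter_markers_maf(markers.iloc[keep].reset_index(drop=True), 0.1)
        assert len(again) == len(keep)


class TestAlleleFreqs:
    def test_matches_brute_force_counting(self, random_dataset):
        _, geno, _ = random_dataset
        est = pedio.estimate_allele_freqs(geno)
        for m in range(geno.n_markers):
            col = geno.codes[:, m]
            ok = col != MISSING
            expect = col[ok].sum() / (2 * ok.sum())
            assert est[m] == pytest.approx(expect, abs=1e-12)

    def test_simple_cases(self):
        g = GenotypeMatrix([("F", "a"), ("F", "b"), ("F", "c")],
                           np.array([[0, 0], [1, 0], [2, MISSING]], dtype=np.int8))
        est = pedio.estimate_allele_freqs(g)
        assert est[0] == pytest.approx(0.5)
        assert est[1] == pytest.approx(0.0)

    def test_all_missing_marker_is_nan(self):
        g = GenotypeMatrix([("F", "a")], np.array([[MISSING]], dtype=np.int8))
        assert np.isnan(pedio.estimate_allele_freqs(g)[0])

    def test_hwe_sampling_accuracy(self):
        rng = np.random.default_rng(0)
        p = 0.3
        n = 1000
        codes = (rng.random((n, 1, 2)) < p).sum(axis=2).astype(np.int8)
        g = GenotypeMatrix([("F", str(i)) for i in range(n)], codes)
        est = pedio.estimate_allele_freqs(g)[0]
        assert abs(est - p) < 3 * np.sqrt(p * (1 - p) / (2 * n))


class TestLDPrune:
    def _geno(self, cols):
        codes = np.array(cols, dtype=np.int8).T
        return GenotypeMatrix([("F", str(i)) for i in range(codes.shape[0])], codes)

    def _markers(self, n, freqs=None):
        mk = simulate.uniform_genetic_map(n)
        mk["chromosome"] = "1"
        mk["freq_minor"] = freqs if freqs is not None else np.full(n, 0.3)
        return mk

    def test_duplicate_column_pruned(self):
        col = [0, 1, 2, 1, 0, 2, 1, 1]
        g = self._geno([col, col])
        kept = pedio.ld_prune(g, self._markers(2, [0.4, 0.3]), 10, 5, 0.2)
        assert list(kept) == [0]  # lower-MAF member removed

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(1)
        n, m = 400, 20
        codes = (rng.random((n, m, 2)) < 0.4).sum(axis=2).astype(np.int8)
        g = GenotypeMatrix([("F", str(i)) for i in range(n)], codes)
        kept = pedio.ld_prune(g, self._markers(m), 10, 5, 0.2)
        assert len(kept) == m

    def test_greedy_rule_hand_trace(self):
        # marker 1 in LD with 2 and 3 (r2 ~ 0.25), markers 2 and 3
        # independent; marker 1 has the lowest MAF, so the greedy rule
        # removes it first and the other two survive
        rng = np.random.default_rng(5)
        n = 4000
        b = rng.integers(0, 2, n)
        c = rng.integers(0, 2, n)
        mix = rng.random(n) < 0.5
        a = np.where(mix, b, c)
        g = self._geno([a, b, c])
        mk = self._markers(3, [0.2, 0.3, 0.3])
        kept = pedio.ld_prune(g, mk, 10, 5, 0.2)
        assert list(kept) == [1, 2]

    def test_no_retained_pair_violates_r2(self):
        rng = np.random.default_rng(2)
        n, m = 150, 60
        base = (rng.random((n, m, 2)) < 0.3).sum(axis=2).astype(np.int8)
        # duplicate a run of columns to create LD blocks
        base[:, 1::7] = base[:, 0::7][:, : base[:, 1::7].shape[1]]
        g = GenotypeMatrix([("F", str(i)) for i in range(n)], base)
        mk = self._markers(m, np.linspace(0.1, 0.45, m))
        window, step, r2max = 12, 4, 0.2
        kept = pedio.ld_prune(g, mk, window, step, r2max)
        # idempotent: pruning the pruned set removes nothing
        sub = g.take_markers(kept)
        again = pedio.ld_prune(sub, mk.iloc[kept].reset_index(drop=True),
                               window, step, r2max)
        assert len(again) == len(kept)
        # exhaustive recheck of every window over the retained set
        keptset = set(kept)
        start = 0
        while start < m:
            win = [j for j in range(start, min(start + window, m)) if j in keptset]
            if len(win) > 1:
                r2 = pedio._r2_matrix(g.codes[:, win])
                off = r2[~np.eye(len(win), dtype=bool)]
                assert (off <= r2max).all()
            if start + window >= m:
                break
            start += step

    def test_window_size_validation(self, random_dataset):
        _, geno, markers = random_dataset
        with pytest.raises(ValueError):
            pedio.ld_prune(geno, markers, window_size=1)


class TestGeneticMap:
    def _ref(self):
        return pd.DataFrame({
            "chromosome": ["1", "1", "1"],
            "position_bp": [1_000_000, 2_000_000, 4_000_000],
            "position_cm": [1.0, 3.0, 3.5],
        })

    def _mk(self, bps, chrom="1"):
        return pd.DataFrame({
            "marker_id": [f"s{i}" for i in range(len(bps))],
            "chromosome": chrom,
            "position_bp": bps,
            "position_cm": np.nan,
            "allele_minor": "A", "allele_major": "C",
            "freq_minor": 0.2, "n_missing": 0,
        })

    def test_midpoint_and_anchor(self):
        out = pedio.interpolate_genetic_map(self._mk([1_500_000, 2_000_000]), self._ref())
        assert out["position_cm"].tolist() == [2.0, 3.0]

    def test_extrapolation_clamps(self):
        out = pedio.interpolate_genetic_map(self._mk([10, 9_000_000]), self._ref())
        assert out["position_cm"].tolist() == [1.0, 3.5]

    def test_monotone_in_bp(self):
        rng = np.random.default_rng(3)
        bps = np.sort(rng.integers(1_000_000, 4_000_000, 10))
        out = pedio.interpolate_genetic_map(self._mk(bps), self._ref())
        assert (np.diff(out["position_cm"]) >= 0).all()

    def test_missing_chromosome_raises(self):
        with pytest.raises(ValueError, match="'7'"):
            pedio.interpolate_genetic_map(self._mk([1_500_000], chrom="7"), self._ref())

    def test_reference_map_file_round_trip(self, tmp_path):
        path = tmp_path / "ref.map"
        path.write_text("chrom\tbp\tcM\n1\t1000000\t1.0\n1\t2000000\t3.0\n")
        ref = pedio.read_reference_map(path)
        assert len(ref) == 2
        out = pedio.interpolate_genetic_map(self._mk([1_500_000]), ref)
        assert out["position_cm"].tolist() == [2.0]


class TestAutosomeMask:
    def test_sex_chromosomes_excluded(self):
        markers = pd.DataFrame({"chromosome": ["1", "22", "X", "Y", "23", "chr7", "MT"]})
        assert list(pedio.autosomal_marker_mask(markers)) == [
            True, True, False, False, False, True, False]


class TestSubsample:
    def test_identity_and_determinism(self):
        idx = np.arange(100)
        assert list(pedio.subsample_markers(idx, 100, 0)) == list(idx)
        a = pedio.subsample_markers(idx, 30, 7)
        b = pedio.subsample_markers(idx, 30, 7)
        assert np.array_equal(a, b)
        assert np.array_equal(a, np.sort(a))
        with pytest.raises(ValueError):
            pedio.subsample_markers(idx, 101, 0)

    def test_uniform_inclusion_rate(self):
        idx = np.arange(5000)
        hits = np.zeros(5000)
        n_seeds = 200
        for s in range(n_seeds):
            hits[pedio.subsample_markers(idx, 200, s)] += 1
        rate = hits.mean() / n_seeds
        assert rate == pytest.approx(0.04, abs=1e-9)
        # no marker grossly over/under-sampled
        assert hits.max() / n_seeds < 0.12
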
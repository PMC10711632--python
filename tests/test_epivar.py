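"""Hypergeometric window scoring (vs an exact rational-arithmetic oracle),
region merging/trimming, annotation and the case-exclusivity rule."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from epidrift import (
    annotate_regions,
    call_epivariations,
    case_exclusive_genes,
    generate_cohort,
    hypergeom_tail,
    inject_epivariation,
    inject_sems,
    scan_windows,
)
from epidrift.epivar import WindowScanResult
from epidrift.sem import call_sems, control_bounds

from conftest import NO_FLAGS, small_config, toy_sheet


def exact_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact rational pmf summation."""
    if k <= 0:
        return 1.0
    total = Fraction(0)
    for j in range(k, min(n, K) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


class TestHypergeomTail:
    def test_worked_case(self):
        """N=20, K=4, n=5, k=4 -> C(4,4)C(16,1)/C(20,5) = 16/15504."""
        assert hypergeom_tail(4, 20, 4, 5) == pytest.approx(16 / 15504, abs=1e-15)

    def test_k_zero_is_one(self):
        assert hypergeom_tail(0, 100, 10, 5) == 1.0

    def test_k_above_support_is_zero(self):
        assert hypergeom_tail(6, 20, 4, 5) == 0.0

    def test_matches_exact_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            N = int(rng.integers(10, 2000))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, min(N, 50) + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_tail(k, N, K, n) == pytest.approx(
                exact_tail(k, N, K, n), abs=1e-12)

    def test_strictly_decreasing_in_k(self):
        N, K, n = 200, 30, 10
        tails = [hypergeom_tail(k, N, K, n) for k in range(0, min(n, K) + 1)]
        assert all(a > b for a, b in zip(tails, tails[1:]))


def _toy_calls(n_probes, subjects, sem_cells):
    """sem_cells: dict subject -> list of (probe index, +-1)."""
    calls = pd.DataFrame(0, index=[f"p{i}" for i in range(n_probes)],
                         columns=subjects, dtype=np.int8)
    for subject, cells in sem_cells.items():
        for idx, val in cells:
            calls.iloc[idx, calls.columns.get_loc(subject)] = val
    return calls


def _toy_annot(n_probes, probes_per_gene=5, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 1 + 100 * np.arange(n_probes),
            "gene": [f"G{i // probes_per_gene}" for i in range(n_probes)],
        },
        index=pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id"),
    )


class TestScanWindows:
    def test_window_counts_match_manual(self):
        calls = _toy_calls(30, ["s1"], {"s1": [(10, 1), (12, 1), (14, -1)]})
        scan = scan_windows(calls, _toy_annot(30), window_probes=5)
        assert scan.N == 30 and scan.n_windows_tested["s1"] == 26
        win = scan.windows.set_index("start_idx")
        # window starting at 10 covers probes 10-14: all three SEMs
        assert win.loc[10, "k"] == 3 and win.loc[10, "K"] == 3
        assert win.loc[10, "p"] == pytest.approx(exact_tail(3, 30, 3, 5), abs=1e-14)
        # windows with no SEM are omitted (p = 1 by construction)
        assert 0 not in win.index and 20 not in win.index

    def test_windows_do_not_span_chromosomes(self):
        annot = _toy_annot(30)
        annot.iloc[15:, annot.columns.get_loc("chrom")] = "chr2"
        annot["pos"] = list(range(1, 16)) + list(range(1, 16))
        calls = _toy_calls(30, ["s1"], {"s1": [(14, 1), (15, 1)]})
        scan = scan_windows(calls, annot, window_probes=4)
        # 2 chromosomes x (15 - 4 + 1) windows
        assert scan.n_windows_tested["s1"] == 24
        win = scan.windows
        for _, row in win.iterrows():
            assert row["end_idx"] - row["start_idx"] == 3
            assert (row["start_idx"] < 15) == (row["end_idx"] < 15)

    def test_short_chromosome_skipped(self):
        annot = _toy_annot(10)
        annot.iloc[8:, annot.columns.get_loc("chrom")] = "chr2"
        annot["pos"] = list(range(1, 9)) + [1, 2]
        calls = _toy_calls(10, ["s1"], {"s1": [(9, 1)]})
        scan = scan_windows(calls, annot, window_probes=5)
        assert scan.skipped_chroms == ["chr2"]

    def test_subject_without_sems_yields_nothing(self):
        calls = _toy_calls(20, ["s1", "s2"], {"s1": [(3, 1), (4, 1), (5, 1)]})
        scan = scan_windows(calls, _toy_annot(20), window_probes=5)
        assert "s2" not in set(scan.windows["subject_id"])


class TestCallEpivariations:
    def _scan(self, calls, annot, window=5):
        return scan_windows(calls, annot, window_probes=window)

    def test_contiguous_run_recovered_and_trimmed(self):
        cells = {"s1": [(i, 1) for i in range(10, 18)]}
        calls = _toy_calls(60, ["s1"], cells)
        annot = _toy_annot(60)
        scan = self._scan(calls, annot)
        regions = call_epivariations(scan, calls, annot, alpha=0.05, min_sems=3)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r.start_idx, r.end_idx) == (10, 17)
        assert r.direction == "hyper" and r.n_sems == 8
        assert r.min_window_p <= 0.05 / scan.n_windows_tested["s1"]

    def test_no_sems_no_regions(self):
        calls = _toy_calls(30, ["s1"], {})
        annot = _toy_annot(30)
        regions = call_epivariations(self._scan(calls, annot), calls, annot)
        assert regions.empty

    def test_direction_labels(self):
        hypo = {"s1": [(i, -1) for i in range(5, 13)]}
        mixed = {"s2": [(i, 1 if i % 2 else -1) for i in range(5, 13)]}
        calls = _toy_calls(60, ["s1", "s2"], {**hypo, **mixed})
        annot = _toy_annot(60)
        regions = call_epivariations(self._scan(calls, annot), calls, annot)
        bysub = regions.set_index("subject_id")
        assert bysub.loc["s1", "direction"] == "hypo"
        assert bysub.loc["s2", "direction"] == "mixed"

    def test_min_sems_filters_region(self):
        cells = {"s1": [(10, 1), (11, 1)]}
        calls = _toy_calls(200, ["s1"], cells)
        annot = _toy_annot(200)
        scan = self._scan(calls, annot)
        with_floor = call_epivariations(scan, calls, annot, min_sems=3)
        without = call_epivariations(scan, calls, annot, min_sems=1,
                                     correction="none", alpha=1e-3)
        assert with_floor.empty and len(without) == 1

    def test_lower_alpha_never_adds_regions(self):
        beta, sheet, annot = generate_cohort(small_config(flag_rates=NO_FLAGS, seed=61))
        beta, _ = inject_sems(beta, sheet, 0.002, 0.002, seed=62)
        beta, _ = inject_epivariation(beta, annot, 3, 8, ["case_001", "ctrl_001"],
                                      "hyper", 0.3, seed=63)
        calls = call_sems(beta, control_bounds(beta, sheet))
        scan = scan_windows(calls, annot, 10)
        prev = None
        for alpha in (0.5, 0.05, 0.005):
            n = len(call_epivariations(scan, calls, annot, alpha=alpha,
                                       correction="none"))
            if prev is not None:
                assert n <= prev
            prev = n


class TestAnnotateAndExclusivity:
    def _regions(self, rows):
        return pd.DataFrame(rows, columns=[
            "subject_id", "chrom", "start", "end", "start_idx", "end_idx",
            "n_probes", "n_sems", "direction", "min_window_p"])

    def test_region_maps_to_overlapped_genes(self):
        annot = _toy_annot(20, probes_per_gene=5)
        regions = self._regions(
            [("s1", "chr1", 301, 801, 3, 8, 6, 4, "hyper", 1e-6)])
        pairs = annotate_regions(regions, annot)
        assert set(pairs["gene"]) == {"G0", "G1"}

    def test_intergenic_region_retained(self):
        annot = _toy_annot(10)
        annot["gene"] = ""
        regions = self._regions(
            [("s1", "chr1", 1, 501, 0, 5, 6, 3, "hypo", 1e-5)])
        pairs = annotate_regions(regions, annot)
        assert len(pairs) == 1 and pairs.iloc[0]["gene"] == ""

    def test_exclusivity_rule(self):
        sheet = toy_sheet(3, 3, seed=1)
        case1, case2 = sheet.index[0], sheet.index[1]
        ctrl1 = sheet.index[3]
        annotated = pd.DataFrame({
            "subject_id": [case1, case2, case1, ctrl1],
            "gene": ["A", "A", "B", "B"],
            "direction": ["hyper", "hyper", "hypo", "hypo"],
        })
        out = case_exclusive_genes(annotated, sheet)
        assert list(out.index) == ["A"]
        assert out.loc["A", "n_case_carriers"] == 2
        assert out.loc["A", "n_hyper"] == 2 and out.loc["A", "n_hypo"] == 0

    def test_injected_case_regions_recovered_exclusively(self):
        """Gene-aligned regions injected into cases only are recovered as
        exactly the injected gene set."""
        beta, sheet, annot = generate_cohort(small_config(
            n_cases=20, n_controls=20, probes_per_chromosome=1000,
            flag_rates=NO_FLAGS, seed=71))
        carriers = ["case_001", "case_002", "case_003"]
        beta, truth = inject_epivariation(beta, annot, 4, 10, carriers,
                                          "hyper", 0.3, seed=72,
                                          align_to_genes=True)
        calls = call_sems(beta, control_bounds(beta, sheet))
        scan = scan_windows(calls, annot, 10)
        regions = call_epivariations(scan, calls, annot, alpha=0.05, min_sems=3)
        exclusive = case_exclusive_genes(annotate_regions(regions, annot), sheet)
        injected = set()
        for genes in truth.regions["genes"]:
            injected.update(genes.split(","))
        assert set(exclusive.index) == injected
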
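import math
from fractions import Fraction

import numpy as np
import pytest

from pedlink.qc import (
    DropReason,
    QcConfig,
    founder_genotype_counts,
    hwe_exact,
    ld_thin,
    mendel_check,
    mendel_marker_rates,
    mendel_repair,
    missingness_by_marker,
    run_qc,
)

from conftest import make_map, make_pedigree


def _cohort_of_singletons(genotype_rows, phen=1):
    """One pedigree of unrelated typed founders; genotype_rows[i] is the
    per-marker pair list for founder i."""
    rows = [
        (f"i{k}", "0", "0", 1, phen, g) for k, g in enumerate(genotype_rows)
    ]
    return [make_pedigree("p1", rows)]


class TestMissingness:
    @pytest.mark.parametrize(
        "n_missing,dropped", [(6, True), (5, False), (0, False)]
    )
    def test_strict_exceedance_boundary(self, n_missing, dropped):
        # 100 genotyped founders, n_missing missing at marker 0
        rows = []
        for k in range(100):
            g0 = (0, 0) if k < n_missing else (1, 2)
            rows.append([g0, (1, 2)])
        peds = _cohort_of_singletons(rows)
        frac = missingness_by_marker(peds)
        assert frac[0] == pytest.approx(n_missing / 100)
        cfg = QcConfig()
        assert bool(frac[0] > cfg.marker_missingness_max) is dropped


class TestMendel:
    def _fam(self, father_g, mother_g, child_g):
        return make_pedigree(
            "p",
            [
                ("f", "0", "0", 1, 1, [father_g]),
                ("m", "0", "0", 2, 1, [mother_g]),
                ("c", "f", "m", 1, 2, [child_g]),
            ],
        )

    def test_impossible_transmission_detected(self):
        ped = self._fam((1, 1), (1, 1), (1, 2))
        assert len(mendel_check(ped, 0)) == 1

    def test_het_parents_compatible_with_everything(self):
        for child in [(1, 1), (1, 2), (2, 2)]:
            assert mendel_check(self._fam((1, 2), (1, 2), child), 0) == []

    def test_missing_parent_still_constrains(self):
        # father 1/1 must transmit allele 1; child 2/2 impossible
        ped = self._fam((1, 1), (0, 0), (2, 2))
        assert len(mendel_check(ped, 0)) == 1

    def test_repair_blanks_offending_family_only(self):
        ped = make_pedigree(
            "p",
            [
                ("gf", "0", "0", 1, 1, [(1, 1)]),
                ("gm", "0", "0", 2, 1, [(1, 1)]),
                ("f", "gf", "gm", 1, 1, [(1, 2)]),  # incident: parents 1/1 x 1/1
                ("m", "0", "0", 2, 1, [(2, 2)]),
                ("c", "f", "m", 1, 2, [(1, 2)]),
            ],
        )
        assert len(mendel_check(ped, 0)) == 1
        mendel_repair([ped], 0)
        # offending nuclear family (gf, gm, f) blanked at the marker
        for iid in ("gf", "gm", "f"):
            assert (ped.members[iid].genotypes[0] == 0).all()
        # the other nuclear family is untouched
        assert (ped.members["m"].genotypes[0] == (2, 2)).all()
        assert (ped.members["c"].genotypes[0] == (1, 2)).all()
        assert mendel_check(ped, 0) == []

    def test_repair_noop_when_consistent(self):
        ped = self._fam((1, 2), (1, 2), (1, 1))
        before = ped.genotype_matrix().copy()
        assert mendel_repair([ped], 0) == 0
        assert (ped.genotype_matrix() == before).all()

    def test_marker_rate_counts_incident_families(self):
        # 2 of 2 informative families inconsistent -> rate 1.0 at marker 0
        peds = [
            self._fam((1, 1), (1, 1), (1, 2)),
            make_pedigree(
                "q",
                [
                    ("f", "0", "0", 1, 1, [(2, 2)]),
                    ("m", "0", "0", 2, 1, [(2, 2)]),
                    ("c", "f", "m", 1, 2, [(1, 2)]),
                ],
            ),
        ]
        rates = mendel_marker_rates(peds, 1)
        assert rates[0] == pytest.approx(1.0)


def hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Exact-fraction enumeration of the conditional heterozygote
    distribution, independent of the package's log-space implementation."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hr = (rare - het) // 2
        hc = n - het - hr
        probs[het] = Fraction(
            math.factorial(n) * 2**het * math.factorial(rare) * math.factorial(2 * n - rare),
            math.factorial(hr) * math.factorial(het) * math.factorial(hc) * math.factorial(2 * n),
        )
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHwe:
    @pytest.mark.parametrize(
        "counts",
        [(0, 100, 0), (25, 50, 25), (10, 10, 10), (3, 1, 7), (0, 3, 40)],
    )
    def test_matches_exact_fraction_oracle(self, counts):
        assert hwe_exact(*counts) == pytest.approx(hwe_exact_oracle(*counts), rel=1e-9)

    def test_all_heterozygote_rejected(self):
        assert hwe_exact(0, 100, 0) < 1e-4

    def test_hwe_proportions_kept(self):
        assert hwe_exact(25, 50, 25) > 0.5

    def test_single_observation_cannot_violate(self):
        assert hwe_exact(1, 0, 0) == 1.0

    def test_zero_counts_warn(self):
        with pytest.warns(UserWarning):
            assert hwe_exact(0, 0, 0) == 1.0

    def test_founder_counts_exclude_nonfounders(self, trio):
        counts = founder_genotype_counts([trio], 0)
        assert sum(counts) == 2  # child excluded


class TestLdThin:
    def test_identical_columns_second_dropped(self):
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(60):
            g = tuple(rng.integers(1, 3, size=2))
            rows.append([g, g])  # marker 2 duplicates marker 1
        peds = _cohort_of_singletons(rows)
        mm = make_map((0.5, 0.5))
        keep, dropped = ld_thin(peds, mm)
        assert keep.tolist() == [True, False]
        assert dropped == [("m2", DropReason.LD)]

    def test_windows_never_span_chromosomes(self):
        rng = np.random.default_rng(2)
        rows = []
        for _ in range(60):
            g = tuple(rng.integers(1, 3, size=2))
            rows.append([g, g])
        peds = _cohort_of_singletons(rows)
        mm = make_map((0.5,)).frame
        import pandas as pd

        from pedlink.pedigree import MarkerMap

        frame = pd.DataFrame(
            {
                "marker": ["m1", "m2"],
                "chrom": ["1", "2"],
                "cm": [0.0, 0.0],
                "freq1": [0.5, 0.5],
                "freq2": [0.5, 0.5],
            }
        )
        keep, dropped = ld_thin(peds, MarkerMap(frame))
        assert keep.all() and dropped == []

    def test_independent_markers_kept(self):
        # 500 founders, independent genotypes: expected r2 ~ 1/n << 0.2
        rng = np.random.default_rng(3)
        rows = [
            [tuple(rng.integers(1, 3, size=2)), tuple(rng.integers(1, 3, size=2))]
            for _ in range(500)
        ]
        keep, dropped = ld_thin(_cohort_of_singletons(rows), make_map((0.5, 0.5)))
        assert keep.all()

    def test_monomorphic_excluded_with_reason(self):
        rows = [[(1, 1), (1, 2)] for _ in range(30)]
        keep, dropped = ld_thin(_cohort_of_singletons(rows), make_map((0.5, 0.5)))
        assert not keep[0]
        assert ("m1", DropReason.MONOMORPHIC) in dropped


class TestPipeline:
    def _cohort(self):
        rng = np.random.default_rng(7)
        rows = []
        for k in range(80):
            g = []
            for j in range(4):
                if j == 1 and k < 10:
                    g.append((0, 0))  # marker 2: 12.5% missing -> dropped
                elif j == 3:
                    g.append(tuple(rng.integers(1, 3, size=2)))
                else:
                    g.append(tuple(rng.integers(1, 3, size=2)))
            rows.append(g)
        return _cohort_of_singletons(rows), make_map((0.5, 0.5, 0.5, 0.5))

    def test_missingness_drop_and_idempotence(self):
        peds, mm = self._cohort()
        cleaned, cmap, report = run_qc(peds, mm)
        assert "m2" in [m for m, r in report.dropped_markers if r == DropReason.MISSINGNESS]
        # rerun on own output: nothing changes
        cleaned2, cmap2, report2 = run_qc(cleaned, cmap)
        assert report2.dropped_markers == []
        assert report2.repaired_genotypes == 0
        assert cmap2 == cmap
        assert all(
            (a.genotype_matrix() == b.genotype_matrix()).all()
            for a, b in zip(cleaned, cleaned2)
        )

    def test_post_repair_brute_force_consistency(self):
        # cohort with injected Mendel errors at a low rate: repaired not dropped
        peds = []
        for k in range(30):
            child_g = (1, 2) if k == 0 else (1, 1)
            peds.append(
                make_pedigree(
                    f"p{k}",
                    [
                        ("f", "0", "0", 1, 1, [(1, 1), (1, 2)]),
                        ("m", "0", "0", 2, 1, [(1, 1), (1, 2)]),
                        ("c", "f", "m", 1, 2, [child_g, (1, 2)]),
                    ],
                )
            )
        mm = make_map((0.5, 0.5))
        cleaned, cmap, report = run_qc(peds, mm)
        assert report.repaired_genotypes == 3  # one family blanked at one SNP
        for ped in cleaned:
            for j in range(len(cmap)):
                assert mendel_check(ped, j) == []

    def test_surviving_plus_dropped_covers_input(self):
        peds, mm = self._cohort()
        _, cmap, report = run_qc(peds, mm)
        assert len(cmap) + len(report.dropped_markers) == len(mm)
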
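import numpy as np
import pytest

from pedlink.likelihood import TraitModel, lod, pedigree_likelihood_enumerate
from pedlink.pedigree import recode_phenotypes
from pedlink.ppl import (
    ConfigError,
    Mode,
    PplConfig,
    ScanResult,
    fraction_against,
    genome_scan,
    integrate_br,
    penetrance_lattice,
    pooled_br,
    ppl_from_br,
    sequential_update,
)

from conftest import make_map, make_pedigree


@pytest.fixture
def small_ped(one_marker_map):
    rows = [
        ("gf", "0", "0", 1, 2, [(1, 2)]),
        ("gm", "0", "0", 2, 1, [(1, 1)]),
        ("f", "gf", "gm", 1, 2, [(1, 2)]),
        ("m", "0", "0", 2, 1, [(1, 1)]),
        ("c1", "f", "m", 1, 2, [(1, 2)]),
        ("c2", "f", "m", 2, 1, [(1, 1)]),
    ]
    return recode_phenotypes(make_pedigree("p", rows), "ASD")


@pytest.fixture
def untyped_ped(one_marker_map):
    rows = [
        ("f", "0", "0", 1, 2, [(0, 0)]),
        ("m", "0", "0", 2, 1, [(0, 0)]),
        ("c1", "f", "m", 1, 2, [(0, 0)]),
    ]
    return recode_phenotypes(make_pedigree("u", rows), "ASD")


SMALL = PplConfig(
    alpha_grid=(0.5, 1.0),
    p_grid=(0.05, 0.2),
    penetrance_grid=[(0.9, 0.9, 0.05), (0.8, 0.4, 0.02), (0.5, 0.5, 0.5)],
    theta_grid=(0.0, 0.1, 0.3),
)


class TestPplFromBr:
    def test_no_evidence_returns_prior(self):
        assert ppl_from_br(1.0, 0.02) == pytest.approx(0.02, abs=1e-15)

    def test_posterior_ten_times_prior(self):
        # BR 12.25 at the 2% prior lifts the posterior to 20%
        ppl = ppl_from_br(12.25, 0.02)
        assert ppl == pytest.approx(0.20, abs=1e-12)
        assert ppl / 0.02 == pytest.approx(10.0, abs=1e-9)

    def test_limit_and_monotonicity(self):
        brs = np.logspace(-3, 8, 40)
        ppls = [ppl_from_br(b, 0.02) for b in brs]
        assert (np.diff(ppls) > 0).all()
        assert ppl_from_br(1e300, 0.02) == pytest.approx(1.0)

    def test_invalid_br_rejected(self):
        with pytest.raises(ValueError):
            ppl_from_br(0.0)
        with pytest.raises(ValueError):
            ppl_from_br(-2.0)


class TestSequentialUpdate:
    def test_single_pedigree_matches_ppl_from_br(self):
        assert sequential_update([3.7]) == pytest.approx(ppl_from_br(3.7))

    def test_commutative(self):
        assert sequential_update([2.0, 3.0]) == pytest.approx(sequential_update([3.0, 2.0]))

    def test_uninformative_accumulation(self):
        assert sequential_update([1.0] * 10, 0.02) == pytest.approx(0.02)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sequential_update([2.0, 0.0])


class TestIntegrateBr:
    def test_untyped_pedigree_br_is_one(self, untyped_ped, one_marker_map):
        br = integrate_br(untyped_ped, 0, SMALL, one_marker_map)
        assert br == pytest.approx(1.0, abs=1e-12)

    def test_single_point_grid_is_exponentiated_lod(self, small_ped, one_marker_map):
        model = TraitModel(0.05, 0.9, 0.9, 0.05)
        cfg = PplConfig(
            alpha_grid=(1.0,),
            p_grid=(model.p,),
            penetrance_grid=[(model.f1, model.f2, model.f3)],
            theta_grid=(0.05,),
        )
        br = integrate_br(small_ped, 0, cfg, one_marker_map)
        expected = 10.0 ** lod(small_ped, 0, 0.05, model, one_marker_map)
        assert br == pytest.approx(expected, rel=1e-12)

    def test_matches_bruteforce_quadrature_oracle(self, small_ped, one_marker_map):
        """BR equals an explicit sum over grid points computed through the
        independent enumeration likelihood."""
        cfg = SMALL
        total = 0.0
        n = 0
        for p in cfg.p_grid:
            for f in cfg.penetrance_grid:
                model = TraitModel(p, *f)
                l_half = pedigree_likelihood_enumerate(
                    small_ped, 0, 0.5, model, one_marker_map
                )
                for theta in cfg.theta_grid:
                    l_theta = pedigree_likelihood_enumerate(
                        small_ped, 0, theta, model, one_marker_map
                    )
                    for alpha in cfg.alpha_grid:
                        total += (alpha * l_theta + (1 - alpha) * l_half) / l_half
                        n += 1
        oracle = total / n
        br = integrate_br(small_ped, 0, cfg, one_marker_map)
        assert br == pytest.approx(oracle, rel=1e-12)

    def test_empty_grid_is_config_error(self):
        with pytest.raises(ConfigError):
            PplConfig(penetrance_grid=[(0.1, 0.5, 0.9)])  # filtered to nothing

    def test_penetrance_lattice_respects_ordering(self):
        grid = penetrance_lattice(0.25)
        assert all(f1 >= f2 >= f3 for f1, f2, f3 in grid)
        assert len(grid) == 35  # C(5+2, 3) ordered triples from 5 values


class TestPooled:
    def test_single_pedigree_pooled_equals_sequential(self, small_ped, one_marker_map):
        br_seq = integrate_br(small_ped, 0, SMALL, one_marker_map)
        br_pool = pooled_br([small_ped], 0, SMALL, one_marker_map)
        assert br_pool == pytest.approx(br_seq, rel=1e-14)

    def test_two_pedigrees_single_point_grid_is_product_of_lrs(
        self, small_ped, untyped_ped, one_marker_map
    ):
        model = TraitModel(0.05, 0.9, 0.9, 0.05)
        cfg = PplConfig(
            alpha_grid=(1.0,),
            p_grid=(model.p,),
            penetrance_grid=[(model.f1, model.f2, model.f3)],
            theta_grid=(0.05,),
        )
        lr1 = 10.0 ** lod(small_ped, 0, 0.05, model, one_marker_map)
        lr2 = 10.0 ** lod(untyped_ped, 0, 0.05, model, one_marker_map)
        got = pooled_br([small_ped, untyped_ped], 0, cfg, one_marker_map)
        assert got == pytest.approx(lr1 * lr2, rel=1e-12)


class TestGenomeScan:
    def _cohort(self, n=3):
        mm = make_map((0.6, 0.4), spacing=5.0)
        peds = []
        for k in range(n):
            rows = [
                ("f", "0", "0", 1, 2, [(1, 2), (1, 2)]),
                ("m", "0", "0", 2, 1, [(1, 1), (2, 2)]),
                ("c1", "f", "m", 1, 2, [(1, 2), (1, 2)]),
                ("c2", "f", "m", 2, 1, [(1, 1), (2, 2)]),
            ]
            peds.append(recode_phenotypes(make_pedigree(f"p{k}", rows), "ASD"))
        return peds, mm

    def test_untyped_cohort_flat_at_prior(self, untyped_ped, one_marker_map):
        for mode in Mode:
            cfg = PplConfig(
                alpha_grid=SMALL.alpha_grid,
                p_grid=SMALL.p_grid,
                penetrance_grid=list(SMALL.penetrance_grid),
                theta_grid=SMALL.theta_grid,
                mode=mode,
            )
            scan = genome_scan([untyped_ped], one_marker_map, cfg)
            assert scan.ppl == pytest.approx(0.02, abs=1e-12)
            assert fraction_against(scan) == 100.0

    def test_mode_equivalence_single_pedigree(self, small_ped, one_marker_map):
        cfgs = {
            mode: PplConfig(
                alpha_grid=SMALL.alpha_grid,
                p_grid=SMALL.p_grid,
                penetrance_grid=list(SMALL.penetrance_grid),
                theta_grid=SMALL.theta_grid,
                mode=mode,
            )
            for mode in Mode
        }
        seq = genome_scan([small_ped], one_marker_map, cfgs[Mode.SEQUENTIAL])
        pool = genome_scan([small_ped], one_marker_map, cfgs[Mode.POOLED])
        assert seq.ppl == pytest.approx(pool.ppl, rel=1e-13)

    def test_split_scan_update_equals_joint_scan(self):
        peds, mm = self._cohort(4)
        cfg = SMALL
        joint = genome_scan(peds, mm, cfg)
        a = genome_scan(peds[:2], mm, cfg)
        b = genome_scan(peds[2:], mm, cfg)
        merged = a.update(b)
        assert merged.ppl == pytest.approx(joint.ppl, rel=1e-12)

    def test_update_requires_matching_grid(self):
        from pedlink.qc import subset_markers

        peds, mm = self._cohort(2)
        scan = genome_scan(peds, mm, SMALL)
        trimmed = subset_markers(peds, np.array([True, False]))
        other = genome_scan(trimmed, mm.subset([0]), SMALL)
        # position grids differ between the two scans
        with pytest.raises(ValueError, match="match"):
            scan.update(other)

    def test_pedigree_reorder_invariance(self):
        peds, mm = self._cohort(3)
        a = genome_scan(peds, mm, SMALL)
        b = genome_scan(peds[::-1], mm, SMALL)
        assert a.ppl == pytest.approx(b.ppl, rel=1e-12)

    def test_tsv_roundtrip(self, tmp_path):
        peds, mm = self._cohort(2)
        scan = genome_scan(peds, mm, SMALL)
        path = tmp_path / "scan.tsv"
        scan.to_tsv(path)
        back = ScanResult.read_tsv(path)
        assert back.mode == scan.mode
        assert back.prior_pi == scan.prior_pi
        assert back.ppl == pytest.approx(scan.ppl)


class TestFractionAgainst:
    def _scan_with_ppl(self, ppls, pi=0.02):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "chrom": ["1"] * len(ppls),
                "marker": [f"m{k}" for k in range(len(ppls))],
                "cm": np.arange(len(ppls), dtype=float),
                "log_br": np.zeros(len(ppls)),
                "br": np.ones(len(ppls)),
                "ppl": ppls,
            }
        )
        return ScanResult(frame, Mode.SEQUENTIAL, pi)

    def test_all_below(self):
        assert fraction_against(self._scan_with_ppl([0.01] * 5)) == 100.0

    def test_threshold_inclusive(self):
        assert fraction_against(self._scan_with_ppl([0.02] * 5)) == 100.0

    def test_mixed(self):
        assert fraction_against(self._scan_with_ppl([0.01, 0.5, 0.02, 0.9])) == 50.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fraction_against(self._scan_with_ppl([]))
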
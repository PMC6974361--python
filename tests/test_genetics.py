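"""Inheritance-cube unit and property tests.

Closed-form checks: in a drive/wild heterozygous germline with Cas9
present, the drive allele transmits at 1/2 + c*h/2, uncut wild-type at
(1-c)/2, and the cleaved non-HDR mass c*(1-h)/2 splits rho1 : (1-rho1)
between in-frame and out-of-frame resistant alleles.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import splitdrive as sd
from splitdrive.genetics import cost_class_mask


def target_marginal(gametes):
    """Collapse a split-system gamete distribution onto the target locus."""
    out = {}
    for alleles, p in gametes.items():
        out[alleles[-1]] = out.get(alleles[-1], 0.0) + p
    return out


class TestGameteDistribution:
    def test_no_drive_machinery_is_mendelian(self, split_system, default_drive):
        g = sd.gamete_distribution(split_system, "+/+;w/w", "female", default_drive)
        assert g == {("+", "w"): 1.0}

    @pytest.mark.parametrize(
        "sex,expected",
        [
            # 1/2 + c*h/2 etc. with (c_F, h_F) = (1.0, 0.805), rho1 = 1/6
            ("female", {"G": 0.90250, "w": 0.0, "r1": 0.01625, "r2": 0.08125}),
            # (c_M, h_M) = (0.51, 0.669)
            ("male", {"G": 0.670595, "w": 0.245, "r1": 0.01406750, "r2": 0.07033750}),
        ],
    )
    def test_trans_heterozygote_closed_form(self, split_system, default_drive, sex, expected):
        g = sd.gamete_distribution(split_system, "C/+;G/w", sex, default_drive)
        marg = target_marginal(g)
        for allele, p in expected.items():
            assert marg.get(allele, 0.0) == pytest.approx(p, abs=1e-12)
        # Cas9 locus assorts independently and Mendelianly
        cas9 = {}
        for alleles, p in g.items():
            cas9[alleles[0]] = cas9.get(alleles[0], 0.0) + p
        assert cas9["C"] == pytest.approx(0.5, abs=1e-12)
        assert cas9["+"] == pytest.approx(0.5, abs=1e-12)

    def test_no_cas9_no_homing(self, split_system, default_drive):
        g = sd.gamete_distribution(split_system, "+/+;G/w", "female", default_drive)
        assert target_marginal(g) == pytest.approx({"G": 0.5, "w": 0.5})

    def test_probabilities_sum_to_one(self, split_system, default_drive):
        for i in range(split_system.n):
            for sex in ("female", "male"):
                g = sd.gamete_distribution(split_system, i, sex, default_drive)
                assert sum(g.values()) == pytest.approx(1.0, abs=1e-12)

    def test_hdr_as_transmission_mode(self, split_system):
        """h read as the effective transmission rate reproduces that rate."""
        p = sd.DriveParams(h_f=0.9025, hdr_is_transmission=True)
        g = sd.gamete_distribution(split_system, "C/+;G/w", "female", p)
        assert target_marginal(g)["G"] == pytest.approx(0.9025, abs=1e-12)

    def test_unknown_genotype_raises(self, split_system, default_drive):
        with pytest.raises(sd.ConfigurationError):
            sd.gamete_distribution(split_system, "C/C;X/w", "female", default_drive)


def mendelian_oracle(system):
    """Independent Mendelian cube: outer product of 50:50 gametes."""
    n = system.n
    cube = np.zeros((n, n, n))
    for im, gm in enumerate(system.genotypes):
        for ip, gp in enumerate(system.genotypes):
            for picks in itertools.product(*[range(2)] * (2 * len(gm))):
                half = len(gm)
                child = tuple(
                    system.pair_index((gm[k][picks[k]], gp[k][picks[half + k]]), k)
                    for k in range(half)
                )
                cube[im, ip, system._by_pairs[child]] += 0.5 ** (2 * half)
    return cube


def chromatid_fate_oracle(mother_pair, father_pair, c_f, h_f, c_m, h_m, rho1):
    """Exhaustive enumeration over ordered chromatid fates (linked system).

    For each parent, pick a chromatid (1/2 each); a picked ``w`` chromatid
    in an H-carrying germline is either cut (then HDR -> H, or end-joined
    to r1/r2) or left intact.  Enumerates every discrete event explicitly.
    """
    system = sd.GeneticSystem("linked")

    def gamete_table(pair, c, h):
        table = {}
        active = "H" in pair
        for chromatid in pair:
            if active and chromatid == "w":
                events = [
                    ("H", c * h),  # cut, HDR
                    ("r1", c * (1 - h) * rho1),  # cut, in-frame join
                    ("r2", c * (1 - h) * (1 - rho1)),  # cut, out-of-frame join
                    ("w", 1 - c),  # not cut
                ]
            else:
                events = [(chromatid, 1.0)]
            for allele, p in events:
                table[allele] = table.get(allele, 0.0) + 0.5 * p
        return table

    out = np.zeros(system.n)
    for (am, pm), (ap, pp) in itertools.product(
        gamete_table(mother_pair, c_f, h_f).items(),
        gamete_table(father_pair, c_m, h_m).items(),
    ):
        child = (system.pair_index((am, ap), 0),)
        out[system._by_pairs[child]] += pm * pp
    return out


drive_params_strategy = st.builds(
    sd.DriveParams,
    c_f=st.floats(0, 1),
    c_m=st.floats(0, 1),
    h_f=st.floats(0, 1),
    h_m=st.floats(0, 1),
    rho1=st.floats(0, 1),
    deposition_rate=st.floats(0, 1),
)


class TestBuildCube:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(params=drive_params_strategy, system=st.sampled_from(sd.genetics.SYSTEMS))
    def test_rows_are_distributions(self, params, system):
        cube = sd.build_cube(params, system)
        assert np.all(cube.tensor >= 0)
        np.testing.assert_allclose(cube.tensor.sum(axis=2), 1.0, atol=1e-12)

    @pytest.mark.parametrize("system", ["split", "linked", "refractory"])
    def test_mendelian_reduction(self, system):
        params = sd.DriveParams(c_f=0.0, c_m=0.0)
        cube = sd.build_cube(params, system)
        np.testing.assert_allclose(
            cube.tensor, mendelian_oracle(cube.system), atol=1e-12
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(0, 1), h=st.floats(0, 1))
    def test_closed_form_transmission(self, c, h):
        """Marginal drive transmission of an active G/w x w/w cross is 1/2 + c*h/2."""
        params = sd.DriveParams(c_f=c, h_f=h, c_m=c, h_m=h)
        cube = sd.build_cube(params, "split")
        assert cube.carrier_probability("C/+;G/w", "+/+;w/w") == pytest.approx(
            0.5 + 0.5 * c * h, abs=1e-12
        )
        assert cube.carrier_probability("+/+;w/w", "C/C;G/w") == pytest.approx(
            0.5 + 0.5 * c * h, abs=1e-12
        )

    def test_brute_force_chromatid_oracle(self):
        params = sd.DriveParams(c_f=0.7, h_f=0.4, c_m=0.3, h_m=0.9, rho1=0.25)
        cube = sd.build_cube(params, "linked")
        system = cube.system
        for im, gm in enumerate(system.genotypes):
            for ip, gp in enumerate(system.genotypes):
                expected = chromatid_fate_oracle(
                    gm[0], gp[0], 0.7, 0.4, 0.3, 0.9, 0.25
                )
                np.testing.assert_allclose(cube.tensor[im, ip], expected, atol=1e-12)

    def test_mother_father_symmetry_without_deposition(self):
        params = sd.DriveParams(c_f=0.6, c_m=0.6, h_f=0.8, h_m=0.8, deposition_rate=0.0)
        cube = sd.build_cube(params, "split")
        np.testing.assert_allclose(
            cube.tensor, np.swapaxes(cube.tensor, 0, 1), atol=1e-12
        )

    def test_refractory_cross_is_mendelian(self):
        cube = sd.build_cube(sd.DriveParams(), "refractory")
        row = cube.row("R/w", "w/w")
        system = cube.system
        assert row[system.genotype_index("R/w")] == pytest.approx(0.5)
        assert row[system.genotype_index("w/w")] == pytest.approx(0.5)

    def test_split_row_marginal_example(self, default_cube):
        assert default_cube.carrier_probability("C/+;G/w", "+/+;w/w") == pytest.approx(
            0.90250, abs=1e-12
        )

    def test_text_roundtrip(self, default_cube, tmp_path):
        path = tmp_path / "cube.csv"
        default_cube.to_text(path)
        loaded = sd.InheritanceCube.from_text(path)
        assert loaded.system.name == "split"
        np.testing.assert_allclose(loaded.tensor, default_cube.tensor, atol=1e-15)


class TestDeposition:
    def test_zero_rate_is_identity(self):
        base = sd.build_cube(sd.DriveParams(deposition_rate=0.0), "split")
        eps = sd.build_cube(sd.DriveParams(deposition_rate=1e-300), "split")
        np.testing.assert_allclose(base.tensor, eps.tensor, atol=1e-12)

    def test_only_machinery_mothers_affected(self, split_system):
        base = sd.build_cube(sd.DriveParams(), "split")
        dep = sd.build_cube(sd.DriveParams(deposition_rate=0.5), "split")
        deposits = split_system.deposits
        np.testing.assert_allclose(
            dep.tensor[~deposits], base.tensor[~deposits], atol=1e-12
        )
        assert not np.allclose(dep.tensor[deposits], base.tensor[deposits])

    def test_full_deposition_removes_w_offspring(self, split_system):
        dep = sd.build_cube(sd.DriveParams(deposition_rate=1.0), "split")
        w_pos = split_system.alleles.index("w")
        has_w = split_system.allele_count[:, w_pos] > 0
        rows = dep.tensor[split_system.deposits]
        assert rows[:, :, has_w].sum() == pytest.approx(0.0, abs=1e-12)


class TestFitness:
    def test_wild_type_neutral(self, split_system, default_drive):
        assert sd.fitness_modifiers(split_system, "+/+;w/w", default_drive) == (1.0, 1.0)

    def test_one_cas9_allele_fecundity(self, split_system, default_drive):
        fec, mort = sd.fitness_modifiers(split_system, "C/+;G/w", default_drive)
        assert fec == pytest.approx(0.922)
        assert mort == 1.0

    def test_double_homozygote(self, split_system, default_drive):
        fec, mort = sd.fitness_modifiers(split_system, "C/C;G/G", default_drive)
        assert fec == pytest.approx(0.922**2)  # 0.850084
        assert mort == pytest.approx(1.0 / 0.9)  # lifespan cut maps to rate inflation

    def test_r2_cost_class_flag(self, split_system):
        inclusive = sd.DriveParams()
        _, mort = sd.fitness_modifiers(split_system, "+/+;r2/r2", inclusive)
        assert mort == pytest.approx(1.0 / 0.9)
        exclusive = sd.DriveParams(r2_shares_cost_class=False)
        _, mort = sd.fitness_modifiers(split_system, "+/+;r2/r2", exclusive)
        assert mort == 1.0
        mask = cost_class_mask(split_system, exclusive)
        assert mask[split_system.genotype_index("C/C;G/G")]

    def test_invalid_parameters_raise(self):
        with pytest.raises(sd.ConfigurationError):
            sd.DriveParams(c_f=1.2)
        with pytest.raises(sd.ConfigurationError):
            sd.DriveParams(lifespan_cost_hom=1.0)


class TestGenotypeBookkeeping:
    def test_compact_and_slash_labels_agree(self, split_system):
        assert split_system.genotype_index("CC;GG") == split_system.genotype_index(
            "C/C;G/G"
        )
        assert split_system.genotype_index("+C;wG") == split_system.genotype_index(
            "C/+;G/w"
        )

    def test_genotype_space_sizes(self, split_system, linked_system, refractory_system):
        assert split_system.n == 30
        assert linked_system.n == 10
        assert refractory_system.n == 3

    def test_canonical_representation_unique(self, split_system):
        assert len(set(split_system.labels)) == split_system.n
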
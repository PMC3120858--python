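"""Nonbonded pair energies, switching, and LIE free-energy estimation."""

import numpy as np
import pytest

from flipsite.errors import ConfigurationError, StructureError
from flipsite.lie_energy import (
    COULOMB_CONSTANT,
    DNA_BACKBONE_ATOM_NAMES,
    NonbondedScheme,
    ddg,
    flipped_backbone_selection,
    interaction_series,
    last_window,
    lie_delta_g,
    nonbonded_interaction,
    pocket_selection,
    restraint_spec,
    switching_function,
)
from flipsite.structure_io import (
    Atom,
    EnergySeries,
    Frame,
    Topology,
    Trajectory,
)
from flipsite.synthetic_data import (
    ToyComplexSpec,
    make_energy_series,
    make_toy_complex,
)

from conftest import build_random_charged_system, naive_nonbonded


def _pair_topology(q1, q2, eps1=0.0, eps2=0.0, r1=1.0, r2=1.0):
    atoms = [
        Atom(index=0, name="A1", element="C", residue_name="XXX",
             residue_id=1, chain="A", charge=q1, lj_epsilon=eps1,
             lj_rmin_half=r1),
        Atom(index=1, name="A2", element="C", residue_name="XXX",
             residue_id=2, chain="A", charge=q2, lj_epsilon=eps2,
             lj_rmin_half=r2),
    ]
    return Topology(atoms)


class TestNonbonded:
    def test_unit_charges_give_coulomb_constant(self):
        """+1e/-1e at 1.0 A, eps=1, inside the switch region -> -332.0636."""
        top = _pair_topology(1.0, -1.0)
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        v_el, v_vdw = nonbonded_interaction(top, frame, [0], [1])
        assert v_el == pytest.approx(-COULOMB_CONSTANT, abs=1e-12)
        assert v_vdw == 0.0

    def test_lj_minimum_at_combined_rmin(self):
        """Neutral pair at r = Rmin_ij -> v_vdw = -eps_ij exactly."""
        eps1, eps2 = 0.12, 0.30
        r1, r2 = 1.6, 2.1
        top = _pair_topology(0.0, 0.0, eps1, eps2, r1, r2)
        frame = Frame(np.array([[0.0, 0, 0], [r1 + r2, 0, 0]]))
        _v_el, v_vdw = nonbonded_interaction(top, frame, [0], [1])
        assert v_vdw == pytest.approx(-np.sqrt(eps1 * eps2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        top, frame, ga, gb = build_random_charged_system(rng)
        scheme = NonbondedScheme()
        v_el, v_vdw = nonbonded_interaction(top, frame, ga, gb, scheme)
        ref_el, ref_vdw = naive_nonbonded(top, frame, ga, gb, scheme)
        assert v_el == pytest.approx(ref_el, abs=1e-10)
        assert v_vdw == pytest.approx(ref_vdw, abs=1e-10)

    def test_electrostatics_linear_in_single_charge(self):
        rng = np.random.default_rng(31)
        top, frame, ga, gb = build_random_charged_system(rng, n_a=5, n_b=5)
        v1, _ = nonbonded_interaction(top, frame, ga, gb)
        atoms = list(top.atoms)
        from dataclasses import replace

        atoms[0] = replace(atoms[0], charge=atoms[0].charge * 3.0)
        # contribution of atom 0 triples; others unchanged
        v_only0, _ = nonbonded_interaction(top, frame, [0], gb)
        top2 = Topology(atoms)
        v2, _ = nonbonded_interaction(top2, frame, ga, gb)
        assert v2 - v1 == pytest.approx(2.0 * v_only0, rel=1e-9)

    def test_symmetric_under_group_exchange(self):
        rng = np.random.default_rng(33)
        top, frame, ga, gb = build_random_charged_system(rng, n_a=20, n_b=20)
        ab = nonbonded_interaction(top, frame, ga, gb)
        ba = nonbonded_interaction(top, frame, gb, ga)
        assert ab[0] == pytest.approx(ba[0], abs=1e-12)
        assert ab[1] == pytest.approx(ba[1], abs=1e-12)

    def test_overlapping_groups_rejected(self):
        top = _pair_topology(0.1, -0.1)
        frame = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        with pytest.raises(StructureError, match="overlap"):
            nonbonded_interaction(top, frame, [0, 1], [1])

    def test_clash_below_cutoff_distance_rejected(self):
        top = _pair_topology(0.1, -0.1)
        frame = Frame(np.array([[0.0, 0, 0], [0.05, 0, 0]]))
        with pytest.raises(StructureError, match="clash"):
            nonbonded_interaction(top, frame, [0], [1])

    def test_switching_continuous_and_zero_beyond_cutoff(self):
        scheme = NonbondedScheme(cutoff=14.0, switch_start=12.0)
        r = np.arange(11.0, 15.0, 1e-3)
        s = switching_function(r, scheme)
        assert np.all(s[r <= 12.0] == 1.0)
        assert np.all(s[r >= 14.0] == 0.0)
        assert np.all(np.abs(np.diff(s)) < 5e-3)  # no jumps at 1e-3 A steps
        assert switching_function(12.0, scheme) == pytest.approx(1.0)
        assert switching_function(14.0, scheme) == pytest.approx(0.0)

    def test_bad_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            NonbondedScheme(cutoff=12.0, switch_start=14.0)


class TestInteractionSeries:
    def test_constant_geometry_gives_constant_series(self):
        top = _pair_topology(0.5, -0.5, 0.1, 0.1, 1.5, 1.5)
        frames = [
            Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]]), time=5.0 * (k + 1))
            for k in range(4)
        ]
        series = interaction_series(Trajectory(frames, dt=5.0), top, [0], [1])
        assert len(set(series.v_el.tolist())) == 1
        assert len(set(series.v_vdw.tolist())) == 1

    def test_series_mean_equals_framewise_oracle_mean(self):
        rng = np.random.default_rng(35)
        top, frame0, ga, gb = build_random_charged_system(rng, n_a=8, n_b=8)
        frames = [
            Frame(frame0.coordinates + rng.normal(scale=0.05, size=(16, 3)),
                  time=5.0 * (k + 1))
            for k in range(6)
        ]
        traj = Trajectory(frames, dt=5.0)
        scheme = NonbondedScheme()
        series = interaction_series(traj, top, ga, gb, scheme)
        ref = [naive_nonbonded(top, f, ga, gb, scheme) for f in frames]
        assert series.v_el.mean() == pytest.approx(
            np.mean([r[0] for r in ref]), abs=1e-10
        )

    def test_last_10ns_of_57ns_run_selects_2000_frames(self):
        """5 ps monitoring: the last 10 ns of a 57 ns series = 2000 frames."""
        n = int(57_000.0 / 5.0)  # 11400 frames at 5 ps
        series, _ = make_energy_series(-10.0, -4.0, 0.0, 0.0, n, seed=0)
        windowed = series.window(*last_window(series.times, 10_000.0))
        assert len(windowed) == 2000

    def test_empty_window_rejected(self):
        top = _pair_topology(0.1, -0.1)
        frames = [Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]]), time=5.0)]
        with pytest.raises(StructureError, match="window"):
            interaction_series(Trajectory(frames, dt=5.0), top, [0], [1],
                               window=(100.0, 200.0))


def _constant_series(v_el, v_vdw, n=10, label="bound"):
    return EnergySeries(label, 5.0 * np.arange(1, n + 1),
                        np.full(n, v_el), np.full(n, v_vdw))


class TestLIE:
    def test_identical_series_give_zero(self):
        bound = _constant_series(-7.0, -2.0)
        free = _constant_series(-7.0, -2.0, label="free")
        assert lie_delta_g(bound, free).delta_g == 0.0

    def test_closed_form_arithmetic(self):
        """bound (-10, -4), free (-2, -1), alpha 1, beta 0.5 -> -9.5."""
        bound = _constant_series(-10.0, -4.0)
        free = _constant_series(-2.0, -1.0, label="free")
        result = lie_delta_g(bound, free, alpha=1.0, beta=0.5)
        assert result.delta_g == pytest.approx(-9.5, abs=1e-12)

    def test_zero_weights_give_zero(self):
        rng = np.random.default_rng(37)
        bound, _ = make_energy_series(-50, -10, 5, 2, 100, seed=1)
        free, _ = make_energy_series(-20, -5, 5, 2, 100, seed=2,
                                     state_label="free")
        assert lie_delta_g(bound, free, alpha=0.0, beta=0.0).delta_g == 0.0

    def test_linear_in_alpha_and_beta(self):
        bound, _ = make_energy_series(-50, -10, 5, 2, 200, seed=3)
        free, _ = make_energy_series(-20, -5, 5, 2, 200, seed=4,
                                     state_label="free")
        base = lie_delta_g(bound, free, alpha=1.0, beta=0.5).delta_g
        d_alpha = lie_delta_g(bound, free, alpha=1.1, beta=0.5).delta_g - base
        d_beta = lie_delta_g(bound, free, alpha=1.0, beta=0.6).delta_g - base
        el_diff = bound.v_el.mean() - free.v_el.mean()
        vdw_diff = bound.v_vdw.mean() - free.v_vdw.mean()
        assert d_alpha == pytest.approx(0.1 * el_diff, rel=1e-9)
        assert d_beta == pytest.approx(0.1 * vdw_diff, rel=1e-9)

    def test_nan_error_names_frame(self):
        bound = _constant_series(-10.0, -4.0)
        bound.v_el[3] = np.nan
        free = _constant_series(-2.0, -1.0, label="free")
        with pytest.raises(StructureError, match="frame 3"):
            lie_delta_g(bound, free)

    def test_estimate_within_three_standard_errors(self):
        bound, tb = make_energy_series(-8.0, -3.0, 2.0, 1.0, 10_000, seed=5)
        free, tf = make_energy_series(-1.5, -0.5, 2.0, 1.0, 10_000, seed=6,
                                      state_label="free")
        result = lie_delta_g(bound, free, n_blocks=5)
        planted = (
            1.0 * (tb["mean_el"] - tf["mean_el"])
            + 0.5 * (tb["mean_vdw"] - tf["mean_vdw"])
        )
        assert abs(result.delta_g - planted) <= 3.0 * result.se_delta_g


class TestDeltaDeltaG:
    def _result(self, dg, alpha=1.0, beta=0.5):
        bound = _constant_series(dg, 0.0)
        free = _constant_series(0.0, 0.0, label="free")
        return lie_delta_g(bound, free, alpha=alpha, beta=beta)

    def test_identical_inputs_give_zero(self):
        assert ddg(self._result(-9.5), self._result(-9.5)).ddg == 0.0

    def test_subtraction(self):
        out = ddg(self._result(-9.5), self._result(-2.0))
        assert out.ddg == pytest.approx(-7.5, abs=1e-12)

    def test_region_label_propagated(self):
        out = ddg(self._result(-1.0), self._result(-2.0),
                  region_label="pocket")
        assert out.region_label == "pocket"

    def test_mismatched_weights_rejected(self):
        with pytest.raises(ConfigurationError, match="weights"):
            ddg(self._result(-1.0, alpha=1.0), self._result(-2.0, alpha=0.9))


class TestSelections:
    @pytest.fixture
    def shell_system(self):
        """Target residue at origin; neighbours at 10/14/16 A."""
        atoms = []
        coords = []
        for rid, (name, x) in enumerate(
            [("T", 0.0), ("R10", 10.0), ("R14", 14.0), ("R16", 16.0)], start=1
        ):
            atoms.append(
                Atom(index=rid - 1, name=name, element="C",
                     residue_name="RES", residue_id=rid, chain="A")
            )
            coords.append([x, 0.0, 0.0])
        return Topology(atoms), Frame(np.asarray(coords))

    def test_planted_shells_recovered_at_15A(self, shell_system):
        top, frame = shell_system
        sel = pocket_selection(top, frame, ("A", 1), cutoff=15.0)
        names = {top.atoms[i].name for i in sel}
        assert names == {"T", "R10", "R14"}

    def test_zero_cutoff_keeps_only_target(self, shell_system):
        top, frame = shell_system
        sel = pocket_selection(top, frame, ("A", 1), cutoff=0.0)
        assert {top.atoms[i].name for i in sel} == {"T"}

    def test_infinite_cutoff_keeps_all(self, shell_system):
        top, frame = shell_system
        sel = pocket_selection(top, frame, ("A", 1), cutoff=np.inf)
        assert len(sel) == top.n_atoms

    def test_absent_target_residue_rejected(self, shell_system):
        top, frame = shell_system
        with pytest.raises(StructureError, match="no residue"):
            pocket_selection(top, frame, ("A", 99))

    def test_complete_nucleotide_yields_all_8_backbone_atoms(self):
        top, _traj, truth = make_toy_complex(ToyComplexSpec(n_frames=1))
        sel = flipped_backbone_selection(top, "D")
        assert {top.atoms[i].name for i in sel} \
            == set(DNA_BACKBONE_ATOM_NAMES)
        assert len(sel) == 8
        np.testing.assert_array_equal(np.sort(sel),
                                      np.sort(truth.backbone_indices))

    def test_five_prime_terminal_nucleotide_yields_4_atoms(self):
        """A 5'-terminal residue lacks P, O1P, O2P and O5'."""
        kept = ("C4'", "C5'", "C3'", "O3'")
        atoms = [
            Atom(index=i, name=n, element=n[0], residue_name="DC",
                 residue_id=1, chain="D")
            for i, n in enumerate(kept)
        ]
        top = Topology(atoms)
        sel = flipped_backbone_selection(top, "D")
        assert {top.atoms[i].name for i in sel} == set(kept)

    def test_protein_chain_gives_empty_selection_and_warning(self):
        top, _traj, _truth = make_toy_complex(ToyComplexSpec(n_frames=1))
        with pytest.warns(UserWarning, match="no DNA backbone"):
            sel = flipped_backbone_selection(top, "P")
        assert len(sel) == 0

    def test_restraint_spec_lists_index_and_name(self):
        top, _traj, _truth = make_toy_complex(ToyComplexSpec(n_frames=1))
        sel = flipped_backbone_selection(top, "D")
        text = restraint_spec(top, sel)
        assert "C4'" in text and "FC_PLACEHOLDER" in text
        assert len(text.strip().splitlines()) == 9  # header + 8 atoms
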
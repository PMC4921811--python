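"""Rejection sampler: chain growth, clash detection, placement, ensembles."""

import numpy as np
import pytest

from trimerbody import (
    BeadModel,
    DomainLabel,
    LinkerSpec,
    SamplingExhaustedError,
    check_clash,
    grow_linker,
    make_architecture,
    make_ideal_core,
    make_sphere_payload,
    place_payload,
    sample_configuration,
    sample_ensemble,
)
from trimerbody.ensemble_sampler import InvalidArchitectureError


def beads_at(positions, radius):
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    return BeadModel.from_arrays(positions, radius, "A", DomainLabel.CORE)


class TestLinkerSpec:
    def test_contour_length_counts_junction_bond(self):
        assert LinkerSpec(7).contour_length == pytest.approx(8 * 3.8)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LinkerSpec(-1)
        with pytest.raises(ValueError):
            LinkerSpec(3, bond_length=0.0)


class TestGrowLinker:
    def test_zero_residues_gives_empty_chain(self, rng):
        chain = grow_linker(np.zeros(3), LinkerSpec(0), None, rng)
        assert chain.shape == (0, 3)

    def test_single_bead_one_bond_from_anchor(self, rng):
        anchor = np.array([1.0, -2.0, 3.0])
        chain = grow_linker(anchor, LinkerSpec(1), None, rng)
        assert chain.shape == (1, 3)
        assert np.isclose(np.linalg.norm(chain[0] - anchor), 3.8)

    def test_bond_lengths_exact_along_chain(self, rng):
        chain = grow_linker(np.zeros(3), LinkerSpec(12), None, rng,
                            check_clashes=False)
        steps = np.diff(np.vstack([np.zeros(3), chain]), axis=0)
        assert np.allclose(np.linalg.norm(steps, axis=1), 3.8, atol=1e-9)

    def test_freely_jointed_rms_end_to_end(self):
        # closed form <R^2> = n b^2 for the freely jointed chain
        rng = np.random.default_rng(2024)
        n_samples = 100_000
        spec = LinkerSpec(7)
        sq = np.empty(n_samples)
        anchor = np.zeros(3)
        for i in range(n_samples):
            chain = grow_linker(anchor, spec, None, rng, check_clashes=False)
            sq[i] = chain[-1] @ chain[-1]
        rms = np.sqrt(sq.mean())
        expected = 3.8 * np.sqrt(7)
        assert abs(rms - expected) / expected < 0.02

    def test_rejects_on_obstacle_clash(self, rng):
        # a wall of beads surrounding the anchor forces rejection
        wall = beads_at(
            3.8 * np.vstack([np.eye(3), -np.eye(3)]), radius=10.0
        )
        chain = grow_linker(np.zeros(3), LinkerSpec(3), wall, rng)
        assert chain is None


class TestCheckClash:
    def test_overlapping_and_separated_pairs(self):
        a = beads_at([[0.0, 0.0, 0.0]], 2.0)
        near = beads_at([[3.9, 0.0, 0.0]], 2.0)
        far = beads_at([[4.1, 0.0, 0.0]], 2.0)
        assert check_clash(a, near, scale=1.0) is True
        assert check_clash(a, far, scale=1.0) is False

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            pos_a = rng.uniform(-20, 20, size=(100, 3))
            pos_b = rng.uniform(-20, 20, size=(100, 3))
            rad_a = rng.uniform(0.5, 3.0, size=100)
            rad_b = rng.uniform(0.5, 3.0, size=100)
            a = BeadModel.from_arrays(pos_a, rad_a, "A", DomainLabel.CORE)
            b = BeadModel.from_arrays(pos_b, rad_b, "B", DomainLabel.CORE)
            expected = any(
                np.linalg.norm(pos_a[i] - pos_b[j]) < 0.9 * (rad_a[i] + rad_b[j])
                for i in range(100)
                for j in range(100)
            )
            assert check_clash(a, b, scale=0.9) == expected

    def test_symmetric(self, rng):
        a = beads_at(rng.normal(scale=5, size=(20, 3)), 1.5)
        b = beads_at(rng.normal(scale=5, size=(20, 3)), 1.5)
        assert check_clash(a, b) == check_clash(b, a)

    def test_invalid_scale_rejected(self):
        a = beads_at([[0.0, 0.0, 0.0]], 1.0)
        with pytest.raises(ValueError):
            check_clash(a, a, scale=0.0)


class TestPlacePayload:
    def test_point_payload_lands_on_target(self, point_payload, rng):
        target = np.array([3.0, 4.0, 5.0])
        posed, _ = place_payload(point_payload, target, rng)
        assert np.allclose(posed[0], target, atol=1e-9)

    def test_rigidity_preserves_internal_distances(self, sphere_payload, rng):
        posed, _ = place_payload(sphere_payload, np.array([10.0, 0.0, 0.0]), rng)
        orig = sphere_payload.model.positions
        d_orig = np.linalg.norm(orig[0] - orig[-1])
        assert np.isclose(np.linalg.norm(posed[0] - posed[-1]), d_orig, atol=1e-9)

    def test_orientations_average_to_zero(self):
        # uniform rotations: the mean posed unit orientation vector vanishes
        rng = np.random.default_rng(7)
        two_bead = make_sphere_payload(radius=1.0, n_beads=1, seed=0)
        template = BeadModel.from_arrays(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], 0.5, "P", DomainLabel.PAYLOAD_N
        )
        import dataclasses
        payload = dataclasses.replace(
            two_bead, model=template, n_anchor=np.zeros(3), c_anchor=np.zeros(3)
        )
        total = np.zeros(3)
        n = 100_000
        for _ in range(n):
            posed, _ = place_payload(payload, np.zeros(3), rng)
            total += posed[1] - posed[0]
        assert np.linalg.norm(total / n) < 0.02


class TestSampleConfiguration:
    def test_point_payloads_within_contour_ball(self, point_multi_arch, rng):
        # with clash checking off every attempt is accepted, and the payload
        # position never exceeds the linker contour from its N-anchor
        contour = 7 * 3.8
        anchors = point_multi_arch.core.n_anchor_points
        for _ in range(50):
            conf = sample_configuration(
                point_multi_arch, rng, check_clashes=False
            )
            assert conf is not None
            for k in range(3):
                d = np.linalg.norm(conf.payload_anchor_positions[k] - anchors[k])
                assert d <= contour + 1e-9

    def test_zero_residue_tether_pins_payload_to_donor(self, point_payload, rng):
        # compact core so that a linker end near the donor is actually
        # reachable; accepted payloads must sit within one bond of the donor
        compact = make_ideal_core(anchor_radius=2.0, axial_offset=2.0, seed=0)
        arch = make_architecture(
            "tandem", compact, [point_payload] * 3, [LinkerSpec(7)] * 3,
            [LinkerSpec(0), LinkerSpec(0)],
        )
        accepted = 0
        while accepted < 10:
            conf = sample_configuration(arch, rng, check_clashes=False,
                                        max_inner_attempts=2000)
            assert conf is not None, "degenerate-tether sampling failed"
            accepted += 1
            for k in (1, 2):
                d = np.linalg.norm(
                    conf.payload_anchor_positions[k] - compact.c_anchor_points[k - 1]
                )
                assert d <= 3.8 + 1e-9

    def test_tandem_payloads_in_contour_ball_intersection(
        self, point_tandem_arch, core, rng
    ):
        # primary linker ball around the N-anchor and extra-tether contour
        # ball around the donor C-anchor both contain every accepted position
        primary_ball = 7 * 3.8
        tether_ball = (17 + 1) * 3.8
        for _ in range(30):
            conf = sample_configuration(point_tandem_arch, rng, check_clashes=False,
                                        max_inner_attempts=500)
            assert conf is not None
            for k in (1, 2):
                p = conf.payload_anchor_positions[k]
                assert np.linalg.norm(p - core.n_anchor_points[k]) <= primary_ball + 1e-9
                assert np.linalg.norm(p - core.c_anchor_points[k - 1]) <= tether_ball + 1e-9

    def test_linker_bonds_and_tether_closure(self, point_tandem_arch, core, rng):
        conf = sample_configuration(point_tandem_arch, rng, check_clashes=False,
                                    max_inner_attempts=500)
        for cid, chain in conf.linker_chains.items():
            steps = np.diff(chain, axis=0)
            assert np.allclose(np.linalg.norm(steps, axis=1), 3.8, atol=1e-9)
        # tether final bead lands within one bond of the payload anchor
        for k, cid in ((1, "J"), (2, "K")):
            d = np.linalg.norm(
                conf.linker_chains[cid][-1] - conf.payload_anchor_positions[k]
            )
            assert d <= 3.8 * (1 + 1e-9)

    def test_invalid_architecture_rejected(self, core, point_payload, rng):
        with pytest.raises(InvalidArchitectureError):
            make_architecture(
                "tandem", core, [point_payload] * 3, [LinkerSpec(7)] * 3,
                [LinkerSpec(17)],  # tandem needs exactly two tethers
            )
        with pytest.raises(InvalidArchitectureError):
            make_architecture(
                "multi_chain", core, [point_payload] * 3, [LinkerSpec(7)] * 3,
                [LinkerSpec(17), LinkerSpec(17)],
            )


class TestSampleEnsemble:
    def test_requested_size_and_metadata(self, point_multi_arch):
        ens = sample_ensemble(point_multi_arch, n_accepted=10, seed=4,
                              check_clashes=False)
        assert ens.accepted == 10
        assert len(ens.configurations) == 10
        assert ens.attempts >= 10
        assert ens.architecture is point_multi_arch

    def test_same_seed_identical_different_seed_differs(self, multi_arch):
        a = sample_ensemble(multi_arch, n_accepted=3, seed=9, per_arm_retry=True)
        b = sample_ensemble(multi_arch, n_accepted=3, seed=9, per_arm_retry=True)
        c = sample_ensemble(multi_arch, n_accepted=3, seed=10, per_arm_retry=True)
        for ca, cb in zip(a.configurations, b.configurations):
            assert np.array_equal(ca.model.positions, cb.model.positions)
        assert not np.allclose(
            a.configurations[0].model.positions,
            c.configurations[0].model.positions,
        )

    def test_infeasible_architecture_exhausts(self, core):
        # a payload too large to place without clashing against the core
        huge = make_sphere_payload(radius=60.0, n_beads=400, seed=0)
        arch = make_architecture(
            "multi_chain", core, [huge] * 3, [LinkerSpec(1)] * 3
        )
        with pytest.raises(SamplingExhaustedError):
            sample_ensemble(arch, n_accepted=5, seed=0, max_total_attempts=50)

    def test_tandem_acceptance_not_above_multi_chain(
        self, point_multi_arch, point_tandem_arch
    ):
        # the double tether only removes configurations, so the tandem
        # acceptance rate cannot exceed the multi-chain rate in expectation;
        # both estimates are binomial, so allow 3 sigma of counting noise
        multi = sample_ensemble(point_multi_arch, n_accepted=50, seed=6)
        tandem = sample_ensemble(point_tandem_arch, n_accepted=50, seed=6)
        p_m, p_t = multi.acceptance_rate, tandem.acceptance_rate
        noise = 3.0 * np.sqrt(
            p_m * (1 - p_m) / multi.attempts + p_t * (1 - p_t) / tandem.attempts
        )
        assert p_t <= p_m + noise


class TestReachabilityInvariant:
    def test_all_payload_beads_within_reach(self, multi_arch):
        # every payload bead within linker contour + payload diameter of its
        # N-anchor (the payload attaches by a surface anchor)
        ens = sample_ensemble(multi_arch, n_accepted=5, seed=12, per_arm_retry=True)
        payload_diameter = 2.0 * multi_arch.arms[0].payload.bounding_radius()
        bound = 7 * 3.8 + payload_diameter + 1e-6
        labels = [DomainLabel.PAYLOAD_N, DomainLabel.PAYLOAD_I, DomainLabel.PAYLOAD_C]
        for conf in ens.configurations:
            for k, label in enumerate(labels):
                beads = conf.model.select_labels({label})
                d = np.linalg.norm(
                    beads.positions - multi_arch.core.n_anchor_points[k], axis=1
                )
                assert np.all(d <= bound)
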
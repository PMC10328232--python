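"""Expanding-cylinder probabilistic labelling."""

import numpy as np
import pytest

from ieegloc.core import Contact, Electrode, LabelEntry, LabelTable, VolumeImage
from ieegloc.ela import (
    ContactProbabilities,
    ElaParams,
    assign_region,
    bipolar_probabilities,
    contact_axis,
    ela_fractions,
    ela_probabilities,
    label_electrode,
)
from ieegloc.synthetic import WHITE_LABEL, make_depth_electrode, sample_cortical_points


def straight_electrode(n=8, spacing=5.0, direction=(0, 0, 1.0), origin=(0, 0, 0)):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    pts = np.asarray(origin, dtype=float) + np.arange(n)[:, None] * spacing * d
    return Electrode("E", [Contact(str(i), p) for i, p in enumerate(pts)])


class TestContactAxis:
    def test_straight_electrode_axis_constant(self):
        e = straight_electrode(direction=(0, 0, 1))
        for i in range(len(e)):
            assert np.allclose(contact_axis(e, i), (0, 0, 1), atol=1e-12)

    def test_single_contact_has_no_axis(self):
        e = Electrode("S", [Contact("1", (0, 0, 0))])
        assert contact_axis(e, 0) is None

    def test_arc_matches_finite_difference(self):
        theta = np.linspace(0, np.pi / 3, 6)
        pts = np.stack([30 * np.cos(theta), 30 * np.sin(theta), np.zeros(6)], axis=1)
        e = Electrode("A", [Contact(str(i), p) for i, p in enumerate(pts)])
        for i in range(6):
            lo, hi = max(i - 1, 0), min(i + 1, 5)
            expect = pts[hi] - pts[lo]
            expect /= np.linalg.norm(expect)
            assert np.allclose(contact_axis(e, i), expect, atol=1e-9)

    def test_coincident_neighbours_rejected(self):
        e = Electrode("B", [Contact("1", (0, 0, 0)), Contact("2", (0, 0, 0))])
        with pytest.raises(ValueError, match="coincide"):
            contact_axis(e, 0)


def halfspace_volume(offset=19.37, n=24):
    """Labels 7 / 8 fill the half-spaces x + y < offset and >= offset."""
    idx = np.arange(n)
    X, Y, _ = np.meshgrid(idx, idx, idx, indexing="ij")
    grid = np.where(X + Y < offset, 7, 8).astype(np.int32)
    return VolumeImage(grid, np.eye(4))


HALFSPACE_LUT = LabelTable(
    [
        LabelEntry(7, "ctx-region-A", "cortical_grey"),
        LabelEntry(8, "ctx-region-B", "cortical_grey"),
    ]
)


def brute_force_ela(position, axis, vol, params, half_length):
    """Independent oracle: enumerate the cubic lattice with plain loops and
    count nearest-voxel labels per radius."""
    s = params.sample_spacing
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    n_ax = int(np.floor(half_length / s + 1e-9))
    n_rad = int(np.floor(params.r_max / s + 1e-9))
    samples = []
    for a in range(-n_ax, n_ax + 1):
        for b in range(-n_rad, n_rad + 1):
            for c in range(-n_rad, n_rad + 1):
                radial = np.hypot(b * s, c * s)
                if radial > params.r_max + 1e-12:
                    continue
                p = position + a * s * u + b * s * v + c * s * w
                cont = np.linalg.solve(vol.affine[:3, :3], p - vol.affine[:3, 3])
                vox = np.sign(cont) * np.floor(np.abs(cont) + 0.5)
                if ((vox < 0) | (vox >= np.array(vol.shape))).any():
                    label = 0
                else:
                    label = int(vol.grid[tuple(vox.astype(int))])
                samples.append((radial, label))
    probs: dict = {}
    for r_k in params.radii:
        inside = [lab for rad, lab in samples if rad <= r_k + 1e-12]
        for lab in set(inside):
            probs[lab] = probs.get(lab, 0.0) + inside.count(lab) / len(inside)
    return {k: p / params.n_radii for k, p in probs.items()}


class TestElaProbabilities:
    def test_homogeneous_region_is_certain(self, head):
        probs = ela_probabilities(
            np.array([0.0, 10.0, 0.0]), np.array([0.0, 0.0, 1.0]),
            head.parcellation, head.labels, ElaParams(),
        )
        assert probs == {WHITE_LABEL: 1.0}

    def test_far_outside_is_background(self, head):
        probs = ela_probabilities(
            np.array([200.0, 0.0, 0.0]), None, head.parcellation, head.labels
        )
        assert probs == {0: 1.0}

    def test_planar_boundary_splits_evenly(self):
        vol = halfspace_volume()
        params = ElaParams()
        position = np.array([9.2, 10.17, 10.3])  # on the plane x+y = 19.37
        axis = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)  # parallel to the plane
        probs = ela_probabilities(position, axis, vol, HALFSPACE_LUT, params,
                                  half_length=2.0)
        assert set(probs) == {7, 8}
        assert abs(probs[7] - 0.5) <= 0.05
        assert abs(probs[8] - 0.5) <= 0.05
        oracle = brute_force_ela(position, axis, vol, params, half_length=2.0)
        for lab in oracle:
            assert probs.get(lab, 0.0) == pytest.approx(oracle[lab], abs=1e-12)

    def test_oblique_cylinder_matches_bruteforce(self, head):
        params = ElaParams()
        position = np.array([52.3, 11.7, 8.9])
        axis = np.array([0.3, 0.8, 0.52])
        probs = ela_probabilities(position, axis, head.parcellation, head.labels,
                                  params, half_length=2.5)
        oracle = brute_force_ela(position, axis, head.parcellation, params, 2.5)
        assert set(probs) == {k for k, p in oracle.items() if p > 0}
        for lab, p in oracle.items():
            assert probs.get(lab, 0.0) == pytest.approx(p, abs=1e-12)

    def test_probabilities_sum_to_one(self, head):
        pts, _ = sample_cortical_points(head, 25, margin_mm=0.0, seed=5)
        for p in pts:
            probs = ela_probabilities(p, None, head.parcellation, head.labels)
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-6)
            assert all(0.0 <= v <= 1.0 for v in probs.values())

    def test_support_grows_monotonically_with_radius(self, head):
        pts, _ = sample_cortical_points(head, 10, margin_mm=0.0, seed=6)
        for p in pts:
            uniq, frac = ela_fractions(p, np.array([0.0, 0.0, 1.0]),
                                       head.parcellation, ElaParams(), 2.5)
            support = [set(uniq[frac[k] > 0]) for k in range(frac.shape[0])]
            for a, b in zip(support, support[1:]):
                assert a <= b

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="sample_spacing"):
            ElaParams(r_max=1.0, sample_spacing=2.0)
        with pytest.raises(ValueError, match="r_max"):
            ElaParams(r_max=0.0)
        with pytest.raises(ValueError, match="n_radii"):
            ElaParams(n_radii=0)
        with pytest.raises(ValueError, match="mode"):
            ElaParams(mode="tripolar")


class TestBipolar:
    def test_interior_pair_is_certain(self, head):
        e, _ = make_depth_electrode(head, entry=(0, 0, 40.0), target=(0, 0, 5.0),
                                    n_contacts=4)
        probs = bipolar_probabilities(e, 0, head.parcellation, head.labels)
        assert probs == {WHITE_LABEL: 1.0}

    def test_pair_midpoint_on_boundary_splits(self):
        vol = halfspace_volume()
        mid = np.array([9.2, 10.17, 10.3])
        u = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        a, b = mid - 2.0 * u, mid + 2.0 * u
        e = Electrode("P", [Contact("1", a), Contact("2", b)])
        probs = bipolar_probabilities(e, 0, vol, HALFSPACE_LUT)
        assert abs(probs[7] - 0.5) <= 0.05

    def test_matches_monopolar_at_midpoint(self, head):
        e, _ = make_depth_electrode(head, entry=(70.0, 3.0, 1.0),
                                    target=(40.0, 3.0, 1.0), n_contacts=4)
        probs = bipolar_probabilities(e, 1, head.parcellation, head.labels)
        mid = (e.positions[1] + e.positions[2]) / 2
        axis = e.positions[2] - e.positions[1]
        direct = ela_probabilities(mid, axis / np.linalg.norm(axis),
                                   head.parcellation, head.labels,
                                   half_length=np.linalg.norm(axis) / 2)
        assert probs == direct

    def test_nonexistent_pair_rejected(self, head):
        e, _ = make_depth_electrode(head, entry=(0, 0, 40.0), target=(0, 0, 5.0),
                                    n_contacts=4)
        with pytest.raises(IndexError):
            bipolar_probabilities(e, 3, head.parcellation, head.labels)


class TestAssignRegion:
    def test_grey_beats_larger_white_probability(self, head):
        a = assign_region({7: 0.6, WHITE_LABEL: 0.4}, head.labels)
        assert (a.label, a.probability, a.fallback) == (7, 0.6, False)
        b = assign_region({7: 0.2, WHITE_LABEL: 0.8}, head.labels)
        assert (b.label, b.fallback) == (7, False)

    def test_pure_white_falls_back_flagged(self, head):
        a = assign_region({WHITE_LABEL: 1.0}, head.labels)
        assert (a.label, a.probability, a.fallback) == (WHITE_LABEL, 1.0, True)

    def test_tie_breaks_to_lower_id_and_flags(self, head):
        a = assign_region({3: 0.4, 5: 0.4, WHITE_LABEL: 0.2}, head.labels)
        assert (a.label, a.probability, a.tie) == (3, 0.4, True)
        # brute-force argmax confirmation over the grey labels
        grey = {k: v for k, v in {3: 0.4, 5: 0.4, WHITE_LABEL: 0.2}.items()
                if head.labels.is_grey(k)}
        assert a.probability == max(grey.values())
        assert a.label == min(k for k, v in grey.items() if v == max(grey.values()))

    def test_empty_rejected(self, head):
        with pytest.raises(ValueError):
            assign_region({}, head.labels)


class TestLabelElectrode:
    def test_near_boundary_contacts_flag_multiple_regions(self, head):
        # shaft running just inside the wedge-1/wedge-2 boundary plane
        az = np.pi / 4 - 0.01
        u = np.array([np.cos(az), np.sin(az), 0.0])
        e = Electrode("NB", [Contact(str(i), (52 + 2 * i) * u) for i in range(4)])
        records = label_electrode(e, head.parcellation, head.labels)
        for r in records:
            assert r.multi_region
            assert len([p for p in r.probabilities.values() if p > 0]) >= 2

    def test_bipolar_mode_yields_pair_records(self, head):
        e, _ = make_depth_electrode(head, entry=(70.0, 3.0, 1.0),
                                    target=(40.0, 3.0, 1.0), n_contacts=4)
        records = label_electrode(e, head.parcellation, head.labels,
                                  ElaParams(mode="bipolar"))
        assert [r.contact for r in records] == ["1-2", "2-3", "3-4"]
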
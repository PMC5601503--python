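"""Synthetic cohort generator: sampling, voxel heads, 10-5 layout, arcs."""

import math
from dataclasses import replace

import numpy as np
import pytest

import nirspath as nn
from nirspath.errors import ConfigurationError, ResolutionError

from conftest import median_geometry_params, sphere_params


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def test_default_cohort_median_skull_thickness(default_cohort):
    med = np.median([s.skull_thickness_base_mm for s in default_cohort])
    assert 2.3 <= med <= 2.9


def test_default_cohort_median_csf_and_depth(default_cohort):
    csf = np.median([s.csf_thickness_base_mm for s in default_cohort])
    depth = np.median([s.cortical_depth_base_mm for s in default_cohort])
    assert abs(csf - 5.1) < 0.5
    assert abs(depth - 10.2) < 0.6


def test_cohort_fields_respect_stated_ranges(default_cohort):
    for s in default_cohort:
        assert 58.0 <= s.age_months <= 131.4
        assert 33.7 <= s.head_circumference_cm <= 44.5
        assert 1.1 <= s.skull_thickness_base_mm <= 9.6
        assert 3.0 <= s.csf_thickness_base_mm <= 9.0
        assert s.cortical_depth_base_mm >= (
            s.skull_thickness_base_mm + s.csf_thickness_base_mm)
        if s.sex == "male":
            assert s.frontal_depth_offset_mm == 0.0


def test_cohort_determinism_same_seed():
    a = nn.sample_cohort(nn.CohortSpec(n_subjects=20), seed=42)
    b = nn.sample_cohort(nn.CohortSpec(n_subjects=20), seed=42)
    assert a == b
    c = nn.sample_cohort(nn.CohortSpec(n_subjects=20), seed=43)
    assert a != c


def test_zero_spread_cohort_equals_means_exactly():
    spec = nn.CohortSpec(
        n_subjects=1, sex_ratio=1.0,
        age_months=nn.FieldDist(94.2, 0.0, 58.0, 131.4),
        head_circumference_cm=nn.FieldDist(38.8, 0.0, 33.7, 44.5),
        skull_thickness_base_mm=nn.FieldDist(2.585, 0.0, 1.1, 9.6, log=True),
        csf_thickness_base_mm=nn.FieldDist(5.1, 0.0, 3.0, 9.0),
        cortical_depth_base_mm=nn.FieldDist(10.17, 0.0, 6.2, 14.7),
    )
    s = nn.sample_cohort(spec, seed=0)[0]
    assert s.age_months == 94.2
    assert s.head_circumference_cm == 38.8
    assert s.skull_thickness_base_mm == 2.585
    assert s.csf_thickness_base_mm == 5.1
    assert s.cortical_depth_base_mm == pytest.approx(10.17)


def test_age_circumference_coupling_r_squared():
    """Large-sample R^2 of circumference ~ age near the weak printed coupling."""
    cohort = nn.sample_cohort(nn.CohortSpec(n_subjects=2000), seed=7)
    age = np.array([s.age_months for s in cohort])
    circ = np.array([s.head_circumference_cm for s in cohort])
    r2 = np.corrcoef(age, circ)[0, 1] ** 2
    assert 0.12 <= r2 <= 0.24


def test_invalid_spec_names_offending_field():
    bad = nn.CohortSpec(csf_thickness_base_mm=nn.FieldDist(5.0, 1.0, 9.0, 3.0))
    with pytest.raises(ConfigurationError, match="csf_thickness_base_mm"):
        nn.sample_cohort(bad, seed=0)
    with pytest.raises(ConfigurationError, match="n_subjects"):
        nn.sample_cohort(nn.CohortSpec(n_subjects=0), seed=0)


# ---------------------------------------------------------------------------
# Head voxelization
# ---------------------------------------------------------------------------

def test_sphere_shell_volumes_match_analytic():
    """Layer voxel counts agree with closed-form concentric-shell volumes."""
    head = nn.build_head(sphere_params(radius_mm=70.0, skull=2.6, csf=5.1,
                                       depth=10.2), 1.0)
    r0 = 70.0
    r1 = r0 - head.params.scalp_thickness_mm
    r2 = r1 - 2.6
    r3 = r2 - 5.1
    vol = lambda a, b: 4.0 / 3.0 * math.pi * (a**3 - b**3)
    expected = {
        nn.SCALP: vol(r0, r1),
        nn.SKULL: vol(r1, r2),
        nn.CSF: vol(r2, r3),
        nn.BRAIN: 4.0 / 3.0 * math.pi * r3**3,
    }
    for label, v in expected.items():
        count = float((head.labels == label).sum())  # voxel = 1 mm^3
        assert abs(count - v) / v < 0.03


def test_nested_shell_ordering_by_radial_rays():
    """From any brain voxel outward the labels run 4,3,2,1,0 (with repeats)."""
    head = nn.build_head(median_geometry_params(), 1.0)
    rng = np.random.default_rng(0)
    brain_idx = np.argwhere(head.labels == nn.BRAIN)
    center = head.world_to_index(head.center_mm)
    for row in brain_idx[rng.choice(len(brain_idx), 50, replace=False)]:
        d = row - center
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        seq = []
        for t in np.arange(0.0, 120.0, 0.4):
            idx = np.rint(center + d * (norm + t)).astype(int)
            if np.any(idx < 0) or np.any(idx >= head.labels.shape):
                break
            seq.append(int(head.labels[tuple(idx)]))
        # walking outward, labels must be non-increasing 4 -> 0
        assert seq[0] == nn.BRAIN
        assert all(b <= a for a, b in zip(seq, seq[1:]))
        assert seq[-1] == nn.AIR


def test_zero_frontal_offset_makes_sexes_voxel_identical():
    f = median_geometry_params(sex="female", frontal_depth_offset_mm=0.0,
                               subject_id="f")
    m = median_geometry_params(sex="male", subject_id="m")
    assert np.array_equal(nn.build_head(f, 1.0).labels,
                          nn.build_head(m, 1.0).labels)


def test_female_frontal_patch_deepens_cortex_by_offset():
    from nirspath.topographic_projection import surface_layer_maps

    f = median_geometry_params(sex="female", frontal_depth_offset_mm=2.5,
                               subject_id="f")
    m = median_geometry_params(sex="male", subject_id="m")
    hf, hm = nn.build_head(f, 1.0), nn.build_head(m, 1.0)
    optodes = nn.place_optodes_10_5(hf)
    lf = surface_layer_maps(hf, optodes)
    lm = surface_layer_maps(hm, optodes)
    # frontal midline positions inside the patch
    idx = [optodes.index(p) for p in ("Fpz", "AFpz")]
    diffs = [lf["cortical_depth"][i] - lm["cortical_depth"][i] for i in idx]
    assert all(2.0 <= d <= 3.5 for d in diffs)


def test_build_head_determinism(default_cohort):
    p = default_cohort[0]
    assert np.array_equal(nn.build_head(p, 1.0).labels,
                          nn.build_head(p, 1.0).labels)


def test_resolution_error_when_layer_below_one_voxel():
    thin = sphere_params(skull=1.2)
    with pytest.raises(ResolutionError):
        nn.build_head(thin, 1.5)
    with pytest.raises(ConfigurationError):
        nn.build_head(thin, 0.25)


# ---------------------------------------------------------------------------
# 10-5 optode layout
# ---------------------------------------------------------------------------

def test_full_layout_has_346_named_positions(median_head):
    head, optodes = median_head
    assert len(optodes) == 346
    assert len(set(optodes.labels)) == 346
    for name in ("Fpz", "Cz", "C3", "C4", "C3h", "T7", "Fz", "Oz", "Nz"):
        assert name in optodes.labels


def test_positions_lie_on_scalp_surface(median_head):
    head, optodes = median_head
    for pos in optodes.positions_mm:
        idx = head.world_to_index(pos)
        assert head.labels[tuple(idx)] == nn.SCALP


def test_cz_equidistant_from_fiducials_on_sphere():
    head = nn.build_head(sphere_params(), 1.0)
    optodes = nn.place_optodes_10_5(head)
    cz = optodes.position("Cz")
    arcs = [nn.scalp_arc_distance(head, cz, f) for f in head.fiducials.values()]
    assert max(arcs) - min(arcs) <= 2 * head.voxel_size_mm


def test_left_right_mirror_symmetry(median_head):
    """Reflecting the head in the midsagittal plane maps C3 onto C4 etc."""
    head, optodes = median_head
    for left, right in (("C3", "C4"), ("F3", "F4"), ("P7", "P8"), ("T7", "T8")):
        pl = optodes.position(left) - head.center_mm
        pr = optodes.position(right) - head.center_mm
        mirrored = pl * np.array([-1.0, 1.0, 1.0])
        assert np.linalg.norm(mirrored - pr) <= math.sqrt(3) * head.voxel_size_mm


def test_layout_invariant_to_voxel_size():
    p = sphere_params()
    names_1 = nn.place_optodes_10_5(nn.build_head(p, 1.0)).labels
    names_2 = nn.place_optodes_10_5(nn.build_head(p, 2.0)).labels
    assert names_1 == names_2
    assert len(names_1) == 346


# ---------------------------------------------------------------------------
# Arc measurements
# ---------------------------------------------------------------------------

def test_sphere_circumference_matches_closed_form():
    """On a sphere the 10%-up ring is a circle of analytic length."""
    head = nn.build_head(sphere_params(radius_mm=70.0), 1.0)
    arcs = nn.measure_arcs(head)
    # 10% up the coronal arc = 18 deg elevation on a sphere
    expected = 2 * math.pi * 70.0 * math.cos(math.radians(18.0)) / 10.0
    assert abs(arcs["circumference_cm"] - expected) / expected < 0.02
    assert arcs["arc_AP_cm"] == pytest.approx(math.pi * 7.0, rel=0.01)
    assert arcs["arc_RL_cm"] == pytest.approx(math.pi * 7.0, rel=0.01)


def test_default_cohort_mean_circumference(default_cohort):
    vals = [nn.measure_arcs(nn.build_head(s, 1.0))["circumference_cm"]
            for s in default_cohort[:20]]
    assert 37.5 <= np.mean(vals) <= 40.0


def test_arcs_scale_linearly_with_radius():
    small = nn.measure_arcs(nn.build_head(sphere_params(radius_mm=60.0), 1.0))
    big = nn.measure_arcs(nn.build_head(sphere_params(radius_mm=120.0), 1.0))
    for key in small:
        assert big[key] == pytest.approx(2 * small[key], rel=1e-6)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_nifti_round_trip(tmp_path):
    from nirspath.synthetic_head import load_head_nifti, save_head_nifti

    head = nn.build_head(sphere_params(radius_mm=50.0, depth=9.0), 1.0)
    path = tmp_path / "head.nii"
    save_head_nifti(head, path)
    loaded = load_head_nifti(path)
    assert np.array_equal(loaded.labels, head.labels)
    assert loaded.params.scalp_radius_mm == head.params.scalp_radius_mm
    for k in head.fiducials:
        np.testing.assert_allclose(loaded.fiducials[k], head.fiducials[k])


def test_optode_text_round_trip(tmp_path):
    from nirspath.synthetic_head import load_optodes_text, save_optodes_text

    head = nn.build_head(sphere_params(radius_mm=50.0, depth=9.0), 1.0)
    optodes = nn.place_optodes_10_5(head)
    path = tmp_path / "optodes.txt"
    save_optodes_text(optodes, path)
    labels, pos = load_optodes_text(path)
    assert labels == optodes.labels
    np.testing.assert_allclose(pos, optodes.positions_mm, atol=1e-3)
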
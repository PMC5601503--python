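"""Monte Carlo transport: conservation, sampling, symmetry, monotonicity."""

import numpy as np
import pytest

import nirspath as nn
from nirspath.errors import ConfigurationError, DomainError, GeometryError

from conftest import sphere_params, tabulated_optics


def matched_optics(mu_a=0.01, mu_s_prime=1.0, g=0.89, n=1.0):
    return {t: nn.TissueOptics(mu_a=mu_a, mu_s_prime=mu_s_prime, g=g, n=n)
            for t in ("scalp", "skull", "csf", "brain")}


def test_energy_conservation_every_run(matched_slab_sim):
    _, res = matched_slab_sim
    assert res.conservation_residual < 1e-6


def test_zero_absorption_matched_index_exits_with_unit_weight():
    slab = nn.homogeneous_slab(size_mm=60.0, depth_mm=30.0)
    cfg = nn.SimulationConfig(n_photons=3000, seed=2, max_total_path_mm=400.0)
    res = nn.run_simulation(slab, matched_optics(mu_a=0.0),
                            np.array([0.0, 0.0, 0.0]),
                            np.array([0.0, 0.0, -1.0]), cfg)
    assert res.n_detected > 0
    np.testing.assert_allclose(res.exit_weights, 1.0)
    assert res.conservation_residual < 1e-6


def test_per_photon_path_tallies_sum_to_total(matched_slab_sim):
    _, res = matched_slab_sim
    np.testing.assert_allclose(res.paths_by_tissue_mm.sum(axis=1),
                               res.total_paths_mm, rtol=1e-12)
    assert np.all(res.exit_weights > 0)
    assert np.all(res.exit_weights <= 1.0)


def test_same_seed_reproduces_tallies():
    slab = nn.homogeneous_slab(size_mm=60.0, depth_mm=30.0)
    cfg = nn.SimulationConfig(n_photons=5000, seed=11)
    a = nn.run_simulation(slab, matched_optics(), np.array([0.0, 0.0, 0.0]),
                          np.array([0.0, 0.0, -1.0]), cfg)
    b = nn.run_simulation(slab, matched_optics(), np.array([0.0, 0.0, 0.0]),
                          np.array([0.0, 0.0, -1.0]), cfg)
    np.testing.assert_array_equal(a.exit_positions_mm, b.exit_positions_mm)
    np.testing.assert_array_equal(a.exit_weights, b.exit_weights)
    c = nn.run_simulation(slab, matched_optics(), np.array([0.0, 0.0, 0.0]),
                          np.array([0.0, 0.0, -1.0]),
                          nn.SimulationConfig(n_photons=5000, seed=12))
    assert not np.array_equal(a.exit_weights, c.exit_weights)


def test_henyey_greenstein_mean_cosine():
    """Empirical mean deflection cosine within 3 sigma of g."""
    g = 0.89
    n = 1_000_000
    draws = nn.hg_sample_cos(g, n, seed=5)
    var = (1 + g**2) - 0.0  # loose bound: Var(cos) <= E[cos^2] <= 1
    se = np.sqrt((np.var(draws)) / n)
    assert abs(draws.mean() - g) < 3 * se
    # isotropic limit
    iso = nn.hg_sample_cos(0.0, 200_000, seed=6)
    assert abs(iso.mean()) < 3 * np.sqrt(np.var(iso) / iso.size)


def test_diffusion_theory_dpf_oracle(matched_slab_sim):
    """Semi-infinite homogeneous MC vs the diffusion closed form, <10%."""
    _, res = matched_slab_sim
    mu_a, mu_sp = 0.01, 1.0

    def ln_reflectance(mua):
        D = 1.0 / (3.0 * (mua + mu_sp))
        z0 = 1.0 / (mua + mu_sp)
        zb = 2.0 * D  # index-matched boundary (A = 1)
        meff = np.sqrt(mua / D)
        r1 = np.sqrt(rho**2 + z0**2)
        r2 = np.sqrt(rho**2 + (z0 + 2 * zb) ** 2)
        R = (z0 * (meff + 1 / r1) * np.exp(-meff * r1) / r1**2
             + (z0 + 2 * zb) * (meff + 1 / r2) * np.exp(-meff * r2) / r2**2)
        return np.log(R)

    r_exit = np.linalg.norm(res.exit_positions_mm[:, :2], axis=1)
    on_top = res.exit_positions_mm[:, 2] > -0.6
    for rho in (20.0, 30.0, 40.0):
        h = 1e-6
        L_theory = -(ln_reflectance(mu_a + h) - ln_reflectance(mu_a - h)) / (2 * h)
        sel = on_top & (np.abs(r_exit - rho) < 1.5)
        assert sel.sum() > 100
        L_mc = np.average(res.total_paths_mm[sel], weights=res.exit_weights[sel])
        assert abs(L_mc - L_theory) / L_theory < 0.10


def test_symmetric_detectors_receive_equal_intensity():
    """Mirror-symmetric detectors about the source agree within 3 sigma."""
    slab = nn.homogeneous_slab(size_mm=120.0, depth_mm=50.0)
    cfg = nn.SimulationConfig(n_photons=150_000, seed=4, detector_aperture_mm=3.0)
    res = nn.run_simulation(slab, matched_optics(), np.array([0.0, 0.0, 0.0]),
                            np.array([0.0, 0.0, -1.0]), cfg)
    r = np.linalg.norm(res.exit_positions_mm[:, :2], axis=1)
    on_top = res.exit_positions_mm[:, 2] > -0.6
    left = on_top & (np.abs(res.exit_positions_mm[:, 0] + 20) < 3) \
        & (np.abs(res.exit_positions_mm[:, 1]) < 3)
    right = on_top & (np.abs(res.exit_positions_mm[:, 0] - 20) < 3) \
        & (np.abs(res.exit_positions_mm[:, 1]) < 3)
    n1, n2 = left.sum(), right.sum()
    assert n1 > 50 and n2 > 50
    # counting statistics: difference within 3 sigma of Poisson
    assert abs(n1 - n2) < 3 * np.sqrt(n1 + n2)


def test_reciprocity_source_detector_swap():
    """Swapping source and detector changes intensity by < 3 MC sigma."""
    head = nn.build_head(sphere_params(radius_mm=60.0), 1.0)
    optodes = nn.place_optodes_10_5(head)
    optics = tabulated_optics(690.0)
    cfg = nn.SimulationConfig(n_photons=120_000, seed=9,
                              detector_aperture_mm=3.0)

    def intensity(src, det):
        res = nn.run_simulation(head, optics, optodes.position(src),
                                -optodes.normal(src), cfg)
        ch = nn.detect_channels(res, optodes, src, head)
        row = ch[ch.detector == det].iloc[0]
        return row.intensity, row.n_detected

    i_ab, n_ab = intensity("C3", "C3h")
    i_ba, n_ba = intensity("C3h", "C3")
    sigma = np.sqrt(max(n_ab, 1)) / n_ab * i_ab + np.sqrt(max(n_ba, 1)) / n_ba * i_ba
    assert n_ab > 30 and n_ba > 30
    assert abs(i_ab - i_ba) < 3 * sigma


def test_intensity_decreases_with_brain_absorption():
    """Raising brain mu_a (others fixed) lowers brain-traversing intensity."""
    head = nn.build_head(sphere_params(radius_mm=60.0, skull=2.0, csf=3.0,
                                       depth=8.0), 1.0)
    optodes = nn.place_optodes_10_5(head)
    cfg = nn.SimulationConfig(n_photons=80_000, seed=13)
    base = tabulated_optics(690.0)
    out = []
    for mua_brain in (0.005, 0.02, 0.08):
        optics = dict(base)
        optics["brain"] = nn.TissueOptics(mua_brain, 1.44, 0.89, 1.45)
        res = nn.run_simulation(head, optics, optodes.position("C3"),
                                -optodes.normal("C3"), cfg)
        sel = res.paths_by_tissue_mm[:, 3] > 0
        out.append(float(res.exit_weights[sel].sum()))
    assert out[0] > out[1] > out[2]


def test_nearest_mode_partitions_all_detected_weight(median_sim_690, median_head):
    """Nearest-detector assignment partitions the full detected weight."""
    from scipy.spatial import cKDTree

    head, optodes = median_head
    res, _ = median_sim_690
    ch = nn.detect_channels(res, optodes, "C3", head, mode="nearest")
    assigned = ch.intensity.sum() * res.totals["launched"]
    # exits whose nearest optode is the source itself are not channel rows
    nearest = cKDTree(optodes.positions_mm).query(res.exit_positions_mm)[1]
    src_weight = res.exit_weights[nearest == optodes.index("C3")].sum()
    assert assigned + src_weight == pytest.approx(res.totals["detected"],
                                                 rel=1e-9)


def test_brain_path_fraction_grows_with_separation(median_sim_690):
    """Longer channels interrogate proportionally more brain tissue."""
    _, ch = median_sim_690
    short = ch[(ch.rho_mm >= 10) & (ch.rho_mm <= 18) & (ch.n_detected >= 50)]
    far = ch[(ch.rho_mm >= 32) & (ch.rho_mm <= 40) & (ch.n_detected >= 50)]
    assert len(short) >= 3 and len(far) >= 3
    frac_short = (short.mean_brain_path_mm / short.mean_total_path_mm).mean()
    frac_far = (far.mean_brain_path_mm / far.mean_total_path_mm).mean()
    assert frac_short < frac_far
    assert (short.mean_brain_path_mm.mean() <= far.mean_brain_path_mm.mean())


def test_sensitivity_db_deep_region_below_shallow():
    """A deep brain shell is less fNIRS-visible than a shallow one, in dB."""
    head = nn.build_head(sphere_params(radius_mm=60.0, skull=2.0, csf=3.0,
                                       depth=8.0), 1.0)
    optodes = nn.place_optodes_10_5(head)
    center = head.center_mm
    vs = head.voxel_size_mm
    idx = np.indices(head.labels.shape).reshape(3, -1).T
    world = head.origin_mm + idx * vs
    r = np.linalg.norm(world - center, axis=1).reshape(head.labels.shape)
    brain = head.labels == nn.BRAIN
    shallow = brain & (r > 60.0 - 8.0 - 6.0)
    deep = brain & (r < 60.0 - 25.0) & (r > 60.0 - 33.0)
    cfg = nn.SimulationConfig(n_photons=60_000, seed=17)
    optics = tabulated_optics(690.0)
    vals = {}
    for name, mask in (("shallow", shallow), ("deep", deep)):
        res = nn.run_simulation(head, optics, optodes.position("C3"),
                                -optodes.normal("C3"), cfg, region_mask=mask)
        ch = nn.detect_channels(res, optodes, "C3", head)
        vals[name], _ = nn.sensitivity_db(ch, rho_range_mm=(20.0, 40.0))
    assert vals["shallow"] <= 0.0
    assert vals["deep"] < vals["shallow"]


def test_sensitivity_requires_channels_in_range(median_sim_690):
    _, channels = median_sim_690
    with pytest.raises(DomainError):
        nn.sensitivity_db(channels, rho_range_mm=(500.0, 600.0))


def test_run_simulation_validates_inputs():
    head = nn.build_head(sphere_params(radius_mm=50.0, depth=9.0), 1.0)
    optics = matched_optics()
    cfg = nn.SimulationConfig(n_photons=10, seed=0)
    with pytest.raises(GeometryError):
        nn.run_simulation(head, optics, head.center_mm + 500.0,
                          np.array([0.0, 0.0, -1.0]), cfg)
    incomplete = {k: v for k, v in optics.items() if k != "csf"}
    with pytest.raises(ConfigurationError, match="csf"):
        nn.run_simulation(head, incomplete,
                          head.center_mm + np.array([0.0, 0.0, 50.0]),
                          np.array([0.0, 0.0, -1.0]), cfg)
    with pytest.raises(ConfigurationError):
        nn.SimulationConfig(n_photons=0, seed=0)
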
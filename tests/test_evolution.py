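"""Circular initialization and the level-set gradient flow."""

import numpy as np
import pytest

from symseg import evolution, metrics, symmetry
from symseg.evolution import (
    EvolutionParams,
    drlse_rhs,
    evolve,
    extract_mask,
    init_circular_sdf,
    sct_rhs,
)
from symseg.exceptions import ParameterError
from symseg.raster_core import gradient
from symseg.symmetry import sct_energy


class TestInitCircularSdf:
    def test_values_and_slope(self):
        phi = init_circular_sdf((128, 128), (63.5, 63.5), 20.0)
        assert phi[63, 63] == pytest.approx(-20.0, abs=0.8)  # centre pixel ~O
        assert phi[63, 84] == pytest.approx(0.0, abs=0.6)  # ~R to the right
        gx, gy = gradient(phi)
        s = np.hypot(gx, gy)
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(xx - 63.5, yy - 63.5)
        interior = np.zeros((128, 128), dtype=bool)
        interior[1:-1, 1:-1] = True
        # the cone tip dominates the central-difference error: O(1/r²)
        assert np.abs(s[(r > 2.0) & interior] - 1.0).max() < 0.07
        assert np.abs(s[(r > 8.0) & interior] - 1.0).max() < 0.01

    def test_exact_center_value(self):
        phi = init_circular_sdf((65, 65), (32.0, 32.0), 15.0)
        assert phi[32, 32] == -15.0

    def test_center_outside_rejected(self):
        with pytest.raises(ParameterError):
            init_circular_sdf((32, 32), (40.0, 10.0), 5.0)
        with pytest.raises(ParameterError):
            init_circular_sdf((32, 32), (10.0, 10.0), 0.0)


class TestDrlseRhs:
    def test_sdf_regularization_residual_small(self):
        """d_p(1) = 0: an exact SDF is a fixed point of the μ term."""
        phi = init_circular_sdf((128, 128), (63.5, 63.5), 30.0)
        p = EvolutionParams(lam=0.0, alpha=0.0)
        rhs = drlse_rhs(phi, np.ones((128, 128)), p)
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(xx - 63.5, yy - 63.5)
        assert np.abs(rhs[(r > 5) & (r < 55)]).max() < 5e-3

    def test_negative_alpha_expands_interface(self):
        phi = init_circular_sdf((64, 64), (31.5, 31.5), 12.0)
        p = EvolutionParams(mu=0.0, lam=0.0, alpha=-2.0)
        rhs = drlse_rhs(phi, np.ones((64, 64)), p)
        on_zero = np.abs(phi) < 0.5
        # rhs < 0 on the interface: φ decreases, the inside region grows
        assert np.all(rhs[on_zero] < 0)

    def test_band_limited_support(self):
        phi = init_circular_sdf((64, 64), (31.5, 31.5), 12.0)
        p = EvolutionParams(mu=0.0)  # only λ and α terms remain
        rhs = drlse_rhs(phi, np.ones((64, 64)), p)
        assert np.all(rhs[np.abs(phi) > p.epsilon] == 0.0)


class TestSctRhs:
    def test_symmetric_inputs_zero(self, notched_circle):
        phi, _, m, g = notched_circle
        rhs = sct_rhs(phi, g, m, EvolutionParams())
        assert np.abs(rhs).max() < 1e-6

    def test_eta_zero_identically_zero(self, notched_circle):
        _, phi_notched, m, g = notched_circle
        rhs = sct_rhs(phi_notched, g, m, EvolutionParams(eta=0.0))
        assert np.all(rhs == 0.0)

    def test_euler_step_decreases_energy(self, notched_circle):
        _, phi_notched, m, g = notched_circle
        p = EvolutionParams()
        e0 = sct_energy(phi_notched, g, m, p.eta, p.epsilon)
        phi1 = phi_notched + 0.1 * sct_rhs(phi_notched, g, m, p)
        e1 = sct_energy(phi1, g, m, p.eta, p.epsilon)
        assert e1 < e0


class TestEvolve:
    def test_disk_drlse_reaches_target(self, disk):
        p = EvolutionParams(mode="drlse")
        phi, trace = evolve(image=disk.image, edges=disk.edges, params=p)
        iou = metrics.segmentation_metrics(extract_mask(phi), disk.mask).iou
        assert iou >= 0.95
        assert trace.iterations_used <= p.max_iters

    def test_symmetry_term_inert_on_symmetric_target(self, disk):
        pd = EvolutionParams(mode="drlse")
        ps = EvolutionParams(mode="lsm-sec")
        phid, _ = evolve(image=disk.image, edges=disk.edges, params=pd, axis=disk.axis)
        phis, _ = evolve(image=disk.image, edges=disk.edges, params=ps, axis=disk.axis)
        ioud = metrics.segmentation_metrics(extract_mask(phid), disk.mask).iou
        ious = metrics.segmentation_metrics(extract_mask(phis), disk.mask).iou
        assert abs(ious - ioud) <= 0.02

    def test_eta_zero_equals_drlse_bitwise(self, clean_phantom):
        ph = clean_phantom
        ax = symmetry.detect_axis(ph.image, ph.edges)
        pl = EvolutionParams(mode="lsm-sec", eta=0.0, max_iters=40)
        pd = EvolutionParams(mode="drlse", max_iters=40)
        phil, _ = evolve(image=ph.image, edges=ph.edges, params=pl, axis=ax)
        phid, _ = evolve(image=ph.image, edges=ph.edges, params=pd, axis=ax)
        assert np.array_equal(phil, phid)

    def test_deterministic(self, clean_phantom):
        ph = clean_phantom
        p = EvolutionParams(max_iters=30)
        a, _ = evolve(image=ph.image, edges=ph.edges, params=p)
        b, _ = evolve(image=ph.image, edges=ph.edges, params=p)
        assert np.array_equal(a, b)

    def test_drlse_trace_has_no_sct_entry(self, disk):
        p = EvolutionParams(mode="drlse", max_iters=20)
        _, trace = evolve(image=disk.image, edges=disk.edges, params=p)
        assert all("sct" not in e for e in trace.energies)
        assert trace.iterations == sorted(trace.iterations)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ParameterError):
            evolve(params=EvolutionParams())


class TestParams:
    def test_stability_bound_enforced(self):
        with pytest.raises(ParameterError):
            EvolutionParams(mu=0.3, dt=1.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            EvolutionParams(mode="geodesic")


class TestExtractMask:
    def test_disk_area(self):
        phi = init_circular_sdf((128, 128), (63.5, 63.5), 20.0)
        area = extract_mask(phi).sum()
        assert area == pytest.approx(np.pi * 400, rel=0.05)

    def test_all_positive_empty(self):
        assert extract_mask(np.ones((16, 16))).sum() == 0

    def test_largest_component_filter(self):
        phi = np.ones((32, 32))
        phi[4:20, 4:20] = -1.0
        phi[28:30, 28:30] = -1.0
        mask = extract_mask(phi, largest_component=True)
        assert mask.sum() == 16 * 16
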
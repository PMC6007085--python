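"""Head coordinate frames: construction, equivariance, unit conversion."""
import numpy as np
import pytest

from megbids import (
    Fiducials,
    FrameConvention,
    RigidTransform,
    between_frames,
    convert_units,
    frame_from_fiducials,
)
from megbids.errors import GeometryError, MegBidsError


def _random_fiducials(rng, units="m"):
    scale = {"m": 1.0, "cm": 100.0, "mm": 1000.0}[units]
    return Fiducials(
        nas=(np.array([0.10, 0.0, 0.0]) + rng.normal(0, 0.01, 3)) * scale,
        lpa=(np.array([0.0, 0.075, 0.0]) + rng.normal(0, 0.01, 3)) * scale,
        rpa=(np.array([0.0, -0.075, 0.0]) + rng.normal(0, 0.01, 3)) * scale,
        units=units,
    )


def _random_rigid_motion(rng):
    theta = rng.uniform(0, 2 * np.pi)
    ax = rng.normal(0, 1, 3)
    ax /= np.linalg.norm(ax)
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    return R, rng.normal(0, 0.05, 3)


class TestFrameConstruction:
    def test_als_self_application_canonical(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            fid = _random_fiducials(rng)
            T = frame_from_fiducials(fid, "CTF")
            nas = T.apply(fid.nas)
            origin = T.apply((fid.lpa + fid.rpa) / 2)
            lpa, rpa = T.apply(fid.lpa), T.apply(fid.rpa)
            assert nas[0] > 0 and abs(nas[1]) < 1e-12 and abs(nas[2]) < 1e-12
            assert np.allclose(origin, 0, atol=1e-12)
            assert abs(lpa[2]) < 1e-12 and abs(rpa[2]) < 1e-12
            assert np.allclose(lpa, -rpa, atol=1e-12)
            assert lpa[1] > 0  # left is +y in ALS

    def test_ras_self_application_canonical(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            fid = _random_fiducials(rng)
            T = frame_from_fiducials(fid, "ElektaNeuromag")
            lpa, rpa, nas = T.apply(fid.lpa), T.apply(fid.rpa), T.apply(fid.nas)
            assert lpa[0] < 0 and abs(lpa[1]) < 1e-9 and abs(lpa[2]) < 1e-12
            assert rpa[0] > 0 and abs(rpa[1]) < 1e-9 and abs(rpa[2]) < 1e-12
            assert nas[1] > 0 and abs(nas[0]) < 1e-9 and abs(nas[2]) < 1e-12

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(7)
        for conv in ("CTF", "ElektaNeuromag"):
            T = frame_from_fiducials(_random_fiducials(rng), conv)
            R = T.rotation
            assert np.max(np.abs(R.T @ R - np.eye(3))) < 1e-9
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_fiducials_rejected(self):
        fid = Fiducials(nas=[0.1, 0, 0], lpa=[0.05, 0, 0], rpa=[-0.05, 0, 0], units="m")
        with pytest.raises(GeometryError):
            frame_from_fiducials(fid, "CTF")

    def test_unknown_convention_rejected(self):
        fid = Fiducials(nas=[0.1, 0, 0], lpa=[0, 0.07, 0], rpa=[0, -0.07, 0])
        with pytest.raises(MegBidsError):
            frame_from_fiducials(fid, "MagicSpace")

    def test_other_convention_via_explicit_object(self):
        fid = Fiducials(nas=[0.1, 0, 0], lpa=[0, 0.07, 0], rpa=[0, -0.07, 0])
        conv = FrameConvention("Other", "ALS", "bespoke ALS variant")
        T = frame_from_fiducials(fid, conv)
        assert T.apply(fid.nas)[0] > 0


class TestTransformAlgebra:
    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            fid = _random_fiducials(rng)
            R, t = _random_rigid_motion(rng)
            moved = Fiducials(R @ fid.nas + t, R @ fid.lpa + t, R @ fid.rpa + t, "m")
            T1 = frame_from_fiducials(fid, "CTF")
            T2 = frame_from_fiducials(moved, "CTF")
            pts = rng.normal(0, 0.1, (4, 3))
            delta = T2.apply(pts @ R.T + t) - T1.apply(pts)
            worst = max(worst, float(np.max(np.abs(delta))))
        assert worst < 1e-9

    def test_between_frames_round_trip(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            fid = _random_fiducials(rng, units="cm")
            fwd = between_frames(fid, "CTF", "ElektaNeuromag")
            back = between_frames(fid, "ElektaNeuromag", "CTF")
            pts = rng.normal(0, 0.1, (5, 3))
            assert np.max(np.abs(back.apply(fwd.apply(pts)) - pts)) < 1e-9

    def test_between_same_convention_is_identity(self):
        fid = _random_fiducials(np.random.default_rng(13))
        T = between_frames(fid, "CTF", "KIT")  # both ALS
        pts = np.eye(3) * 0.1
        assert np.allclose(T.apply(pts), pts, atol=1e-12)

    def test_als_to_ras_nasion_moves_to_plus_y(self):
        fid = _random_fiducials(np.random.default_rng(14))
        A = frame_from_fiducials(fid, "CTF")
        T = between_frames(fid, "CTF", "ElektaNeuromag")
        nas_ras = T.apply(A.apply(fid.nas))
        assert abs(nas_ras[0]) < 1e-9 and nas_ras[1] > 0

    def test_distances_preserved(self):
        rng = np.random.default_rng(15)
        fid = _random_fiducials(rng)
        T = frame_from_fiducials(fid, "ElektaNeuromag")
        p, q = rng.normal(0, 0.1, 3), rng.normal(0, 0.1, 3)
        assert np.linalg.norm(T.apply(p) - T.apply(q)) == pytest.approx(
            np.linalg.norm(p - q), abs=1e-12
        )

    def test_compose_inverse_is_identity(self):
        rng = np.random.default_rng(16)
        T = frame_from_fiducials(_random_fiducials(rng, "mm"), "CTF")
        I = T.compose(T.inverse())
        assert np.allclose(I.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(I.translation, 0, atol=1e-12)
        assert I.scale_factor == pytest.approx(1.0)


class TestUnits:
    def test_m_to_mm(self):
        assert np.allclose(convert_units([0.1, 0, 0], "m", "mm"), [100, 0, 0])

    def test_identity_conversion(self):
        pts = np.array([[1.0, 2.0, 3.0]])
        assert np.array_equal(convert_units(pts, "cm", "cm"), pts)

    def test_conversion_composes_exactly(self):
        pts = np.array([0.123, -4.56, 7.89])
        via = convert_units(convert_units(pts, "m", "cm"), "cm", "mm")
        assert np.array_equal(via, convert_units(pts, "m", "mm"))

    def test_unknown_unit_rejected(self):
        with pytest.raises(MegBidsError):
            convert_units([1, 2, 3], "m", "furlong")
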
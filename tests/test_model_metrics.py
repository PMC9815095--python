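import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from daqrefine import (DegenerateGeometryError, ca_rmsd, detect_misaligned,
                       evaluate, gdt_ha, kabsch)
from daqrefine.model_metrics import GDT_HA_THRESHOLDS, gdt_fractions
from daqrefine.synthetic import (SyntheticSpec, cyclic_sequence,
                                 inject_conformational_error,
                                 inject_trace_shift, make_backbone)
from test_daq_scoring import ca_model


def helix_model(n, seed_seq=None):
    spec = SyntheticSpec(n_residues=n, sequence=seed_seq or cyclic_sequence(n))
    return make_backbone(spec)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def svd_kabsch(P, Q):
    """Textbook SVD Kabsch, written independently of the library path."""
    pc, qc = P.mean(0), Q.mean(0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (P - pc) @ R.T + qc
    return R, np.sqrt(((moved - Q) ** 2).sum(1).mean())


def grid_search_rmsd(P, Q, n_steps=40):
    """Brute-force search over a rotation grid; translation solved exactly."""
    best = np.inf
    angles = np.linspace(0, 2 * np.pi, n_steps, endpoint=False)
    betas = np.linspace(0, np.pi, n_steps // 2 + 1)
    P0 = P - P.mean(0)
    Q0 = Q - Q.mean(0)
    for a, b, c in itertools.product(angles, betas, angles):
        R = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
        r = np.sqrt(((P0 @ R.T - Q0) ** 2).sum(1).mean())
        best = min(best, r)
    return best


def exhaustive_gdt_fractions(X, Y, thresholds=GDT_HA_THRESHOLDS, max_iter=20):
    """Seed enumeration over *every* window length >= 3, with SVD refits."""
    n = len(X)

    def fit(idx):
        P, Q = X[idx], Y[idx]
        if len(idx) < 3 or np.linalg.matrix_rank(P - P.mean(0), tol=1e-8) < 2:
            return None
        R, _ = svd_kabsch(P, Q)
        t = Q.mean(0) - P.mean(0) @ R.T
        return R, t

    transforms = []
    seeds = [np.arange(n)] + [np.arange(s, s + L)
                              for L in range(3, n + 1)
                              for s in range(n - L + 1)]
    for seed in seeds:
        base = fit(seed)
        if base is None:
            continue
        transforms.append(base)
        for t in thresholds:
            R, tr = base
            prev = None
            for _ in range(max_iter):
                d = np.linalg.norm(X @ R.T + tr - Y, axis=1)
                inl = np.nonzero(d <= t)[0]
                if len(inl) < 3 or (prev is not None and np.array_equal(inl, prev)):
                    break
                nxt = fit(inl)
                if nxt is None:
                    break
                (R, tr), prev = nxt, inl
            transforms.append((R, tr))
    out = {}
    for t in thresholds:
        out[t] = max(float((np.linalg.norm(X @ R.T + tr - Y, axis=1) <= t).mean())
                     for R, tr in transforms)
    return out


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_identical_sets_identity_transform(self):
        X = helix_model(8).ca_coords()
        res = kabsch(X, X)
        assert res.rmsd < 1e-9
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_constructed_rigid_motion_recovered(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 3)) * 5
        R = Rotation.from_euler("xyz", rng.uniform(0, 2 * np.pi, 3)).as_matrix()
        Y = X @ R.T + rng.normal(size=3) * 10
        res = kabsch(X, Y)
        assert res.rmsd < 1e-9
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)

    def test_agrees_with_independent_svd_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(7, 3))
        Y = rng.normal(size=(7, 3))
        _, oracle = svd_kabsch(X, Y)
        assert kabsch(X, Y).rmsd == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 3))
        Y = rng.normal(size=(4, 3))
        r_opt = kabsch(X, Y).rmsd
        r_grid = grid_search_rmsd(X, Y)
        # optimality: the grid can never beat the closed form, and the grid
        # spacing (9 deg) bounds how far above it can land
        max_radius = max(np.linalg.norm(X - X.mean(0), axis=1).max(),
                         np.linalg.norm(Y - Y.mean(0), axis=1).max())
        assert r_opt <= r_grid + 1e-12
        assert r_grid - r_opt <= 2 * np.sin(np.deg2rad(9)) * max_radius

    def test_collinear_points_rejected(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch(X, X + 1.0)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.ones((2, 3)))


class TestCaRmsd:
    def test_self_comparison_is_zero(self):
        m = helix_model(10)
        assert ca_rmsd(m, m).rmsd < 1e-12

    def test_rigid_shift_removed_by_superposition(self):
        m = helix_model(10)
        shifted = ca_model(m.ca_coords() + np.array([1.0, 0, 0]), m.sequence)
        res = ca_rmsd(shifted, m)
        assert res.rmsd < 1e-9
        assert res.n_pairs == 10

    def test_frame_fixed_mode_sees_the_shift(self):
        m = helix_model(10)
        shifted = ca_model(m.ca_coords() + np.array([1.0, 0, 0]), m.sequence)
        assert ca_rmsd(shifted, m, superpose=False).rmsd == pytest.approx(1.0)

    def test_displaced_residue_matches_full_kabsch_oracle(self):
        m = helix_model(10)
        X = m.ca_coords().copy()
        X[4] += np.array([0.0, 0.0, 3.0])
        moved = ca_model(X, m.sequence)
        _, oracle = svd_kabsch(X, m.ca_coords())
        assert ca_rmsd(moved, m).rmsd == pytest.approx(oracle, abs=1e-12)

    def test_symmetry(self):
        a = helix_model(12)
        X = a.ca_coords() + np.random.default_rng(2).normal(size=(12, 3)) * 0.4
        b = ca_model(X, a.sequence)
        assert ca_rmsd(a, b).rmsd == pytest.approx(ca_rmsd(b, a).rmsd, abs=1e-9)


# ---------------------------------------------------------------------------
# GDT-HA
# ---------------------------------------------------------------------------

class TestGdtHa:
    def test_identical_structures_score_one(self):
        m = helix_model(10)
        res = gdt_ha(m, m)
        assert res.gdt_ha == 1.0
        assert all(v == 1.0 for v in res.per_threshold.values())

    def test_two_of_ten_displaced_gives_point_eight(self):
        m = helix_model(10)
        bad = inject_conformational_error(m, (9, 10), displacement=10.0)
        res = gdt_ha(bad, m)
        assert res.per_threshold == {t: 0.8 for t in GDT_HA_THRESHOLDS}
        assert res.gdt_ha == pytest.approx(0.8)

    def test_rigid_rotation_invariance(self):
        m = helix_model(10)
        bad = inject_conformational_error(m, (9, 10), displacement=10.0)
        R = Rotation.from_euler("xyz", [0.4, 1.1, -0.6]).as_matrix()
        rotated = ca_model(bad.ca_coords() @ R.T + np.array([3, 4, 5.0]),
                           bad.sequence)
        assert gdt_ha(rotated, m).gdt_ha == pytest.approx(gdt_ha(bad, m).gdt_ha)

    def test_fractions_monotone_in_threshold(self):
        m = helix_model(15)
        X = m.ca_coords() + np.random.default_rng(8).normal(size=(15, 3)) * 1.5
        noisy = ca_model(X, m.sequence)
        f = gdt_ha(noisy, m).per_threshold
        vals = [f[t] for t in sorted(f)]
        assert vals == sorted(vals)

    def test_search_never_below_global_fit(self):
        m = helix_model(12)
        X = m.ca_coords().copy()
        X[3:7] += np.array([0.0, 6.0, 0.0])
        noisy = ca_model(X, m.sequence)
        frac = gdt_ha(noisy, m).per_threshold
        from daqrefine.model_metrics import kabsch as lib_kabsch
        T = lib_kabsch(X, m.ca_coords()).transform
        d = np.linalg.norm(T.apply(X) - m.ca_coords(), axis=1)
        for t in GDT_HA_THRESHOLDS:
            assert frac[t] >= float((d <= t).mean())

    @pytest.mark.parametrize("case", ["plant", "register", "jitter"])
    def test_matches_exhaustive_seed_oracle_on_small_structures(self, case):
        m = helix_model(10)
        if case == "plant":
            other = inject_conformational_error(m, (9, 10), displacement=10.0)
        elif case == "register":
            other = inject_trace_shift(helix_model(12), (5, 8), 2)
            m = helix_model(12)
        else:
            X = m.ca_coords() + np.random.default_rng(3).normal(size=(10, 3))
            other = ca_model(X, m.sequence)
        X, Y = other.ca_coords(), m.ca_coords()
        assert gdt_fractions(X, Y) == exhaustive_gdt_fractions(X, Y)


# ---------------------------------------------------------------------------
# Misaligned-segment detection
# ---------------------------------------------------------------------------

class TestDetectMisaligned:
    def test_identical_models_give_no_segments(self):
        m = helix_model(40)
        assert detect_misaligned(m, m) == []

    def test_register_shifted_helix_detected_as_one_segment(self):
        m = helix_model(40)
        shifted = inject_trace_shift(m, (11, 20), 3)
        segs = detect_misaligned(shifted, m)
        assert len(segs) == 1
        covered = set(range(segs[0].start.number, segs[0].end.number + 1))
        assert covered >= set(range(11, 21))

    def test_isolated_outlier_below_min_run_ignored(self):
        m = helix_model(40)
        bad = inject_conformational_error(m, (20, 20), displacement=3.0)
        assert detect_misaligned(bad, m) == []

    def test_displaced_but_not_near_other_residues_is_not_misaligned(self):
        # conformational error far from everything: > 2 A but no capture
        m = helix_model(40)
        bad = inject_conformational_error(m, (15, 22), displacement=30.0,
                                          direction=(1.0, 0.0, 0.0))
        assert detect_misaligned(bad, m) == []

    def test_chain_relabel_invariance(self):
        m = helix_model(40)
        shifted = inject_trace_shift(m, (11, 20), 3)
        relabeled = ca_model(shifted.ca_coords(), shifted.sequence)
        relabeled.chain_id = "Z"
        for r, src in zip(relabeled.residues, shifted.residues):
            assert r.number == src.number

        mapping = {r.key("Z"): r.key("A") for r in relabeled.residues}
        segs_a = detect_misaligned(shifted, m)
        segs_z = detect_misaligned(relabeled, m, mapping=mapping)
        assert [(s.start.number, s.end.number) for s in segs_z] == \
               [(s.start.number, s.end.number) for s in segs_a]


def test_evaluate_report_roundtrip(tmp_path):
    from daqrefine import read_report, write_report
    m = helix_model(12)
    bad = inject_conformational_error(m, (11, 12), displacement=10.0)
    rep = evaluate(bad, m)
    p = tmp_path / "report.json"
    write_report(rep, p)
    rep2 = read_report(p)
    assert rep2.gdt_ha == rep.gdt_ha
    assert abs(rep2.ca_rmsd - rep.ca_rmsd) < 1e-12
    assert rep2.per_threshold == rep.per_threshold
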
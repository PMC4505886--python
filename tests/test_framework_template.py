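import numpy as np
import pytest
from sklearn.base import clone

from vdomgeom import errors
from vdomgeom.framework_template import (
    FrameworkTemplate,
    FrameworkTemplateBuilder,
    RigidTransform,
    align_complex_on_alpha,
    derive_framework_subset,
    kabsch,
    remove_loops_and_turns,
    superpose_on_template,
)
from vdomgeom.structure_io import Atom, Residue, VariableDomain
from vdomgeom.synthetic_fixtures import synth_complex, toy_domain
from vdomgeom.cuboid_geometry import EulerTriple


def svd_kabsch_oracle(P, Q):
    """Independent closed-form least-squares superposition (direct SVD)."""
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    U, _, Vt = np.linalg.svd(Pc.T @ Qc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Q.mean(0) - R @ P.mean(0)
    rmsd = np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1)))
    return R, t, rmsd


def make_domain(coords, chain_type="alpha", chain_id="A"):
    residues = [
        Residue("ALA", i + 1, atoms=[Atom("CA", "C", c)]) for i, c in enumerate(coords)
    ]
    return VariableDomain(chain_type, residues, chain_id)


def random_transform(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.normal(0, 10, 3))


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse(self):
        rng = np.random.default_rng(0)
        a, b = random_transform(rng), random_transform(rng)
        x = rng.normal(size=(5, 3))
        np.testing.assert_allclose(a.compose(b).apply(x), a.apply(b.apply(x)), atol=1e-9)
        np.testing.assert_allclose(a.inverse().apply(a.apply(x)), x, atol=1e-9)


class TestKabsch:
    def test_self_superposition_is_identity(self, toy_alpha):
        xyz = toy_alpha.ca_coords()
        tr, rmsd = kabsch(xyz, xyz)
        assert rmsd <= 1e-9
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, 0, atol=1e-8)

    def test_recovers_known_transform(self, toy_alpha):
        rng = np.random.default_rng(1)
        xyz = toy_alpha.ca_coords()
        tr = random_transform(rng)
        back, rmsd = kabsch(tr.apply(xyz), xyz)
        assert rmsd <= 1e-6
        np.testing.assert_allclose(back.rotation, tr.inverse().rotation, atol=1e-6)
        np.testing.assert_allclose(back.translation, tr.inverse().translation, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_closed_form_oracle_under_noise(self, toy_alpha, seed):
        rng = np.random.default_rng(seed)
        xyz = toy_alpha.ca_coords()
        noisy = random_transform(rng).apply(xyz) + rng.normal(0, 0.1, xyz.shape)
        tr, rmsd = kabsch(noisy, xyz)
        R, t, rmsd_oracle = svd_kabsch_oracle(noisy, xyz)
        np.testing.assert_allclose(tr.rotation, R, atol=1e-8)
        np.testing.assert_allclose(tr.translation, t, atol=1e-7)
        assert rmsd == pytest.approx(rmsd_oracle, abs=1e-9)
        # residual scale set by the planted noise
        assert 0.05 < rmsd < 0.2

    def test_underdetermined_rejected(self):
        with pytest.raises(errors.SuperpositionError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLoopRemoval:
    def test_all_extended_trace_fully_kept(self):
        coords = np.column_stack([np.arange(30) * 3.4, np.zeros(30), np.zeros(30)])
        mask = remove_loops_and_turns(make_domain(coords))
        assert mask.all()

    def test_inserted_coil_segment_excluded(self):
        # hand-labelled fixture: 12 extended + 8 compact coil + 12 extended
        ext1 = np.column_stack([np.arange(12) * 3.4, np.zeros(12), np.zeros(12)])
        rng = np.random.default_rng(0)
        coil = ext1[-1] + np.cumsum(rng.normal(0, 0.8, (8, 3)), axis=0)
        ext2 = coil[-1] + np.column_stack(
            [np.zeros(12), np.arange(1, 13) * 3.4, np.zeros(12)]
        )
        mask = remove_loops_and_turns(make_domain(np.vstack([ext1, coil, ext2])))
        assert not mask[13:19].any()  # coil interior rejected
        assert mask[:11].all() and mask[-11:].all()

    def test_short_fragment_rejected(self):
        coords = np.column_stack([np.arange(5) * 3.4, np.zeros(5), np.zeros(5)])
        with pytest.raises(errors.DegenerateGeometryError):
            remove_loops_and_turns(make_domain(coords))


class TestDeriveFrameworkSubset:
    def test_exact_copies_converge_immediately(self, toy_alpha):
        domains = [toy_alpha, toy_alpha, toy_alpha]
        template = derive_framework_subset(domains, "alpha")
        initial = remove_loops_and_turns(toy_alpha)
        assert len(template) == int(initial.sum())
        assert template.n_iterations == 1
        assert template.rmsd_variance <= 1e-18

    def test_perturbed_region_is_excluded(self, toy_alpha):
        rng = np.random.default_rng(3)
        perturbed_numbers = toy_alpha.residue_numbers()[40:50]
        residues = []
        for r in toy_alpha.residues:
            shift = rng.normal(0, 5.0, 3) if r.number in perturbed_numbers else 0.0
            residues.append(
                Residue(r.name, r.number, r.icode,
                        [Atom("CA", "C", r.ca.position + shift)])
            )
        noisy = VariableDomain("alpha", residues, "A")
        template = derive_framework_subset([toy_alpha, noisy, toy_alpha], "alpha")
        assert not set(perturbed_numbers) & set(template.anchor_positions)

    def test_idempotent_on_converged_subset(self, toy_alpha):
        domains = [toy_alpha, toy_alpha]
        t1 = derive_framework_subset(domains, "alpha")
        mask = np.array([n in set(t1.anchor_positions) for n in toy_alpha.residue_numbers()])
        t2 = derive_framework_subset(domains, "alpha", initial_mask=mask)
        assert t1.anchor_positions == t2.anchor_positions

    def test_random_clouds_do_not_converge(self):
        rng = np.random.default_rng(4)
        a = make_domain(rng.normal(0, 10, (40, 3)))
        b = make_domain(rng.normal(0, 10, (40, 3)))
        with pytest.raises((errors.ConvergenceError, errors.DegenerateGeometryError)):
            derive_framework_subset([a, b], "alpha", initial_mask=np.ones(40, bool))


class TestSuperposeOnTemplate:
    def test_reference_self_superposition(self, small_pipeline):
        complexes, templates, _, _ = small_pipeline
        res = superpose_on_template(complexes[0].alpha, templates.alpha)
        assert res.rmsd <= 1e-9
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_mutual_inverse(self, toy_alpha):
        rng = np.random.default_rng(5)
        tr = random_transform(rng)
        moved = toy_alpha.transformed(tr.rotation, tr.translation)
        mask = remove_loops_and_turns(toy_alpha)
        template_a = derive_framework_subset([toy_alpha, toy_alpha], "alpha", initial_mask=mask)
        template_b = FrameworkTemplate(
            "alpha",
            template_a.anchor_positions,
            np.array([moved.ca_by_number()[n] for n in template_a.anchor_positions]),
        )
        ab = superpose_on_template(moved, template_a).transform
        ba = superpose_on_template(toy_alpha, template_b).transform
        np.testing.assert_allclose(ab.rotation, ba.inverse().rotation, atol=1e-6)
        np.testing.assert_allclose(ab.translation, ba.inverse().translation, atol=1e-5)

    def test_too_few_matches_rejected(self, small_pipeline, toy_alpha):
        _, templates, _, _ = small_pipeline
        stub = make_domain(toy_alpha.ca_coords()[:2])  # numbers 1..2 only
        keep = [n for n in templates.alpha.anchor_positions if n <= 2]
        assert len(keep) < 3
        with pytest.raises(errors.SuperpositionError):
            superpose_on_template(stub, templates.alpha)


class TestAlignComplex:
    def test_reference_complex_unchanged(self, small_pipeline):
        complexes, templates, _, _ = small_pipeline
        aligned, res = align_complex_on_alpha(complexes[0], templates.alpha)
        np.testing.assert_allclose(
            aligned.beta.ca_coords(), complexes[0].beta.ca_coords(), atol=1e-8
        )

    def test_translated_complex_restored(self, small_pipeline):
        complexes, templates, _, _ = small_pipeline
        moved = complexes[0].transformed(np.eye(3), np.array([10.0, 0.0, 0.0]))
        aligned, _ = align_complex_on_alpha(moved, templates.alpha)
        np.testing.assert_allclose(
            aligned.alpha.ca_coords(), complexes[0].alpha.ca_coords(), atol=1e-6
        )
        np.testing.assert_allclose(
            aligned.beta.ca_coords(), complexes[0].beta.ca_coords(), atol=1e-6
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_beta_placement_invariant_to_global_motion(self, small_pipeline, seed):
        complexes, templates, _, _ = small_pipeline
        rng = np.random.default_rng(seed)
        tr = random_transform(rng)
        moved = complexes[1].transformed(tr.rotation, tr.translation)
        a1, _ = align_complex_on_alpha(complexes[1], templates.alpha)
        a2, _ = align_complex_on_alpha(moved, templates.alpha)
        np.testing.assert_allclose(a1.beta.ca_coords(), a2.beta.ca_coords(), atol=1e-6)


class TestEstimator:
    def test_fit_exposes_sklearn_surface(self, toy_alpha):
        est = FrameworkTemplateBuilder(deviation_cutoff=1.5)
        assert clone(est).get_params()["deviation_cutoff"] == 1.5
        est.fit([toy_alpha, toy_alpha])
        assert est.n_iter_ == 1
        assert len(est.anchor_positions_) >= 3
        aligned = est.transform([toy_alpha])
        np.testing.assert_allclose(aligned[0].ca_coords(), toy_alpha.ca_coords(), atol=1e-8)

    def test_template_file_round_trip(self, tmp_path, small_pipeline):
        _, templates, _, _ = small_pipeline
        p = tmp_path / "template.tsv"
        templates.alpha.to_file(p)
        back = FrameworkTemplate.from_file(p)
        assert back.anchor_positions == templates.alpha.anchor_positions
        assert back.chain_type == "alpha"
        np.testing.assert_allclose(
            back.anchor_coordinates, templates.alpha.anchor_coordinates, atol=1e-6
        )
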
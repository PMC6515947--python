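"""PDB parsing, face-plane fitting, and L/J residue classification."""

import numpy as np
import pandas as pd
import pytest

from pepzone.errors import (
    AnchorsOnPlane,
    DegenerateGeometry,
    EmptyZone,
    InsertionCodesUnsupported,
    NoSuchChain,
)
from pepzone.structure_map import (
    StructureModel,
    classify_faces,
    fit_face_plane,
    read_structure,
    write_face_overlay,
    zone_face_fraction,
)
from pepzone.synth import gen_structure, structure_to_pdb


def pdb_atom(serial, resseq, x, y, z, altloc=" ", icode=" ", chain="A"):
    return (
        f"ATOM  {serial:5d}  CA {altloc}GLY {chain}{resseq:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


class TestReadStructure:
    def test_minimal_three_residues(self):
        text = "\n".join(
            [pdb_atom(1, 1, 0, 0, 0), pdb_atom(2, 2, 3.8, 0, 0), pdb_atom(3, 3, 7.6, 0, 0), "END"]
        )
        model = read_structure(text, chain="A")
        assert sorted(model.coords) == [1, 2, 3]
        assert model.coords[2] == pytest.approx([3.8, 0, 0])

    def test_missing_residue_excluded(self):
        text = "\n".join([pdb_atom(1, 1, 0, 0, 0), pdb_atom(2, 5, 1, 1, 1), "END"])
        model = read_structure(text, chain="A")
        assert model.resolved == {1, 5}

    def test_first_altloc_wins(self):
        text = "\n".join(
            [
                pdb_atom(1, 1, 0.0, 0.0, 0.0, altloc="A"),
                pdb_atom(2, 1, 9.0, 9.0, 9.0, altloc="B"),
                "END",
            ]
        )
        model = read_structure(text, chain="A")
        assert model.coords[1] == pytest.approx([0.0, 0.0, 0.0])

    def test_insertion_code_rejected(self):
        text = "\n".join([pdb_atom(1, 1, 0, 0, 0, icode="A"), "END"])
        with pytest.raises(InsertionCodesUnsupported):
            read_structure(text, chain="A")

    def test_missing_chain_raises(self):
        with pytest.raises(NoSuchChain):
            read_structure(pdb_atom(1, 1, 0, 0, 0) + "\nEND", chain="B")

    def test_synthetic_model_roundtrip(self):
        model, _ = gen_structure(n_res=30, shape="plane", l_side_spans=[(5, 10)], seed=2)
        back = read_structure(structure_to_pdb(model), chain="A")
        assert back.resolved == model.resolved
        for res in model.coords:
            # PDB format keeps 3 decimals
            assert back.coords[res] == pytest.approx(model.coords[res], abs=1e-3)


def grid_model(z_anchor=5.0, n=6):
    """n x n grid on z = 0 with anchor residues 101-105 lifted to z_anchor."""
    coords = {}
    idx = 1
    for i in range(n):
        for j in range(n):
            coords[idx] = np.array([4.0 * i, 4.0 * j, 0.0])
            idx += 1
    for a in range(101, 106):
        coords[a] = np.array([2.0 * (a - 100), 3.0, z_anchor])
    return StructureModel(chain_id="A", coords=coords)


class TestFitFacePlane:
    def test_exact_plane_with_raised_anchors(self):
        model = grid_model()
        plane = fit_face_plane(model, anchors=range(101, 106))
        assert abs(plane.normal[2]) == pytest.approx(1.0, abs=0.05)
        assert plane.normal[2] > 0  # oriented toward the anchors

    def test_rigid_rotation_preserves_signed_distances(self):
        model = grid_model()
        plane = fit_face_plane(model, anchors=range(101, 106))
        d_before = plane.signed_distance(model.coord_array())
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0],
            ]
        )
        tilt = np.array([[1, 0, 0], [0, np.cos(0.4), -np.sin(0.4)], [0, np.sin(0.4), np.cos(0.4)]])
        R = tilt @ rot
        rotated = StructureModel(
            chain_id="A",
            coords={k: R @ v + np.array([10.0, -3.0, 7.0]) for k, v in model.coords.items()},
        )
        plane2 = fit_face_plane(rotated, anchors=range(101, 106))
        d_after = plane2.signed_distance(rotated.coord_array())
        assert d_after == pytest.approx(d_before, abs=1e-6)

    def test_collinear_raises(self):
        coords = {i: np.array([float(i), 2.0 * i, -i / 2]) for i in range(1, 10)}
        with pytest.raises(DegenerateGeometry):
            fit_face_plane(StructureModel("A", coords), anchors=[1])

    def test_anchors_on_plane_raise(self):
        model = grid_model(z_anchor=0.5)
        with pytest.raises(AnchorsOnPlane):
            fit_face_plane(model, anchors=range(101, 106))


class TestClassifyFaces:
    def test_sides_and_edge_band(self):
        model = grid_model()
        extra = dict(model.coords)
        extra[200] = np.array([8.0, 8.0, -5.0])
        extra[201] = np.array([8.0, 12.0, 1.0])
        model = StructureModel("A", extra)
        plane = fit_face_plane(model, anchors=range(101, 106))
        labels = classify_faces(model, plane)
        assert labels.loc[101] == "L"
        assert labels.loc[200] == "J"
        assert labels.loc[201] == "edge"

    def test_anchor_flip_swaps_faces(self):
        model = grid_model()
        extra = dict(model.coords)
        extra[200] = np.array([8.0, 8.0, -5.0])
        model = StructureModel("A", extra)
        plane_l = fit_face_plane(model, anchors=range(101, 106))
        plane_j = fit_face_plane(model, anchors=[200])
        la, lb = classify_faces(model, plane_l), classify_faces(model, plane_j)
        swap = {"L": "J", "J": "L", "edge": "edge"}
        assert lb.tolist() == [swap[v] for v in la.tolist()]

    def test_fishhook_generator_truth(self):
        model, truth = gen_structure(
            n_res=120,
            shape="fishhook",
            l_side_spans=[(10, 20), (50, 60)],
            j_side_spans=[(90, 100)],
            seed=5,
        )
        plane = fit_face_plane(model, anchors=range(10, 21))
        labels = classify_faces(model, plane)
        non_edge = truth[truth != "edge"].index
        assert (labels.loc[non_edge] == truth.loc[non_edge]).all()

    def test_whole_pipeline_rigid_motion_invariance(self):
        model, _ = gen_structure(
            n_res=80, shape="helix", l_side_spans=[(20, 30)], seed=7
        )
        plane = fit_face_plane(model, anchors=range(20, 31))
        labels = classify_faces(model, plane)
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = StructureModel(
            "A", {k: q @ v + np.array([5.0, 6.0, -2.0]) for k, v in model.coords.items()}
        )
        plane2 = fit_face_plane(moved, anchors=range(20, 31))
        labels2 = classify_faces(moved, plane2)
        assert labels2.tolist() == labels.tolist()


class TestZoneFaceFraction:
    def test_pure_l_zone(self):
        model, _ = gen_structure(n_res=50, shape="plane", l_side_spans=[(10, 20)], seed=1)
        plane = fit_face_plane(model, anchors=range(10, 21))
        labels = classify_faces(model, plane)
        df = zone_face_fraction({"z1": (10, 20)}, labels)
        assert df.loc[0, "frac_L"] == pytest.approx(1.0)
        assert df.loc[0, "frac_J"] == 0.0

    def test_mirrored_control_zone_majority_j(self):
        model, _ = gen_structure(
            n_res=100,
            shape="fishhook",
            l_side_spans=[(10, 20), (40, 50), (70, 80)],
            j_side_spans=[(85, 95)],
            seed=3,
        )
        plane = fit_face_plane(model, anchors=range(10, 21))
        labels = classify_faces(model, plane)
        df = zone_face_fraction(
            {"z1": (10, 20), "z2": (40, 50), "z3": (70, 80), "ctrl": (85, 95)}, labels
        ).set_index("zone")
        assert (df.loc[["z1", "z2", "z3"], "frac_L"] > 0.5).all()
        assert df.loc["ctrl", "frac_J"] > 0.5

    def test_unresolved_residues_reported(self):
        model, _ = gen_structure(n_res=40, shape="plane", l_side_spans=[(5, 15)], seed=4)
        pruned = StructureModel(
            "A", {k: v for k, v in model.coords.items() if k != 10}
        )
        plane = fit_face_plane(pruned, anchors=[5, 6, 7, 8, 9])
        labels = classify_faces(pruned, plane)
        df = zone_face_fraction({"z": (5, 15)}, labels)
        assert df.loc[0, "n_unresolved"] == 1
        assert df.loc[0, "n_resolved"] == 10

    def test_empty_zone_raises(self):
        model, _ = gen_structure(n_res=50, shape="plane", l_side_spans=[(3, 6)], seed=6)
        plane = fit_face_plane(model, anchors=[3, 4, 5, 6])
        labels = classify_faces(model, plane)
        with pytest.raises(EmptyZone):
            zone_face_fraction({"z": (200, 210)}, labels)


def test_face_overlay_written(tmp_path):
    model, _ = gen_structure(n_res=60, shape="plane", l_side_spans=[(5, 10)], seed=9)
    plane = fit_face_plane(model, anchors=range(5, 11))
    labels = classify_faces(model, plane)
    out = tmp_path / "overlay.pdb"
    write_face_overlay(model, labels, out)
    back = read_structure(out.read_text(), chain="A")
    assert back.resolved == model.resolved
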
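"""Structure mapping: loading, distances vs brute force, interfaces."""

import numpy as np
import pytest

from titrascreen import structure_map as sm
from titrascreen import synthetic_data as syn


def brute_min_dist(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive all-pairs heavy-atom minimum distance (the oracle)."""
    return min(float(np.linalg.norm(x - y)) for x in a for y in b)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def test_load_toy_two_chain_pdb(tmp_path):
    model = syn.generate_structure(
        {
            "NAS": [(i, "A", [[float(i), 0, 0]]) for i in (1, 2, 3)],
            "NBS": [(i, "A", [[float(i), 10, 0]]) for i in (1, 2, 3)],
        }
    )
    path = tmp_path / "toy.pdb"
    syn.write_structure_pdb(model, path)
    loaded = sm.load_structure(path, {"A": "NAS", "B": "NBS"})
    assert len(loaded.residues) == 6
    assert loaded.subunits() == ["NAS", "NBS"]
    np.testing.assert_allclose(
        loaded.residues[("NBS", 2)].coords, [[2.0, 10.0, 0.0]], atol=1e-3
    )


def test_absent_chain_error_lists_available(tmp_path):
    model = syn.generate_structure({"NAS": [(1, "A", [[0.0, 0, 0]])]})
    path = tmp_path / "one.pdb"
    syn.write_structure_pdb(model, path)
    with pytest.raises(KeyError, match="available"):
        sm.load_structure(path, {"Z": "NAS"})


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    pdb = (
        "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.30 10.00"
        "           C\n"
        "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.70 10.00"
        "           C\n"
        "END\n"
    )
    path = tmp_path / "alt.pdb"
    path.write_text(pdb)
    model = sm.load_structure(path, {"A": "NAS"})
    res = model.residues[("NAS", 1)]
    assert len(res.coords) == 1
    np.testing.assert_allclose(res.coords[0], [5.0, 0.0, 0.0], atol=1e-3)


def test_hydrogens_dropped(tmp_path):
    pdb = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00 10.00"
        "           C\n"
        "ATOM      2  H   GLY A   1       1.000   0.000   0.000  1.00 10.00"
        "           H\n"
        "END\n"
    )
    path = tmp_path / "h.pdb"
    path.write_text(pdb)
    model = sm.load_structure(path, {"A": "NAS"})
    assert len(model.residues[("NAS", 1)].coords) == 1


# ---------------------------------------------------------------------------
# proximity
# ---------------------------------------------------------------------------

def test_his_proximity_euclidean():
    model = syn.generate_structure(
        {
            "NAS": [(1, "H", [[0.0, 0, 0]]), (2, "A", [[5.0, 0, 0]]),
                    (3, "A", [[9.0, 0, 0]])],
            "NBS": [(1, "A", [[0.0, 50, 0]])],
        }
    )
    reports = {r.key: r for r in sm.his_proximity(model, cutoff=8.0)}
    assert reports[("NAS", 2)].min_dist_to_his == pytest.approx(5.0)
    assert reports[("NAS", 2)].near_his
    assert reports[("NAS", 3)].min_dist_to_his == pytest.approx(9.0)
    assert not reports[("NAS", 3)].near_his
    assert reports[("NAS", 2)].nearest_his == ("NAS", 1)


def test_interface_residues_cutoff():
    near = syn.generate_structure(
        {
            "NAS": [(1, "A", [[0.0, 0, 0]])],
            "NBS": [(1, "A", [[4.9, 0, 0]]), (2, "A", [[30.0, 0, 0]])],
        }
    )
    assert sm.interface_residues(near, cutoff=5.0) == {("NAS", 1), ("NBS", 1)}
    far = syn.generate_structure(
        {
            "NAS": [(1, "A", [[0.0, 0, 0]])],
            "NBS": [(1, "A", [[20.0, 0, 0]])],
        }
    )
    assert sm.interface_residues(far, cutoff=5.0) == set()


def test_single_chain_interface_error():
    model = syn.generate_structure({"NAS": [(1, "A", [[0.0, 0, 0]])]})
    with pytest.raises(ValueError, match="two subunits"):
        sm.interface_residues(model)


def test_random_structures_match_brute_force_oracle(rng):
    """KD-tree implementation == exhaustive scan on 30 random structures."""
    for trial in range(30):
        model = syn.random_structure(rng, n_per_chain=6, separation=-12.0)
        his = model.his_keys()
        if his:
            for rep in sm.his_proximity(model, cutoff=8.0):
                expected = min(
                    brute_min_dist(
                        model.residues[rep.key].coords, model.residues[h].coords
                    )
                    for h in his
                )
                assert rep.min_dist_to_his == pytest.approx(expected, abs=1e-9)
                assert rep.near_his == (expected <= 8.0)
        cutoff = float(rng.uniform(3.0, 15.0))
        subs = model.subunits()
        expected_iface = set()
        for ka in model.keys_of(subs[0]):
            for kb in model.keys_of(subs[1]):
                if (
                    brute_min_dist(
                        model.residues[ka].coords, model.residues[kb].coords
                    )
                    <= cutoff
                ):
                    expected_iface.update({ka, kb})
        assert sm.interface_residues(model, cutoff=cutoff) == expected_iface


def test_distances_invariant_under_rigid_motion(rng):
    model = syn.random_structure(rng, n_per_chain=5, separation=-10.0)
    # random rotation via QR decomposition
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = model.transformed(q, rng.normal(size=3) * 50)
    orig = {r.key: r.min_dist_to_his for r in sm.his_proximity(model)} if model.his_keys() else {}
    if orig:
        new = {r.key: r.min_dist_to_his for r in sm.his_proximity(moved)}
        for k in orig:
            assert new[k] == pytest.approx(orig[k], abs=1e-8)
    assert sm.interface_residues(moved, 6.0) == sm.interface_residues(model, 6.0)


# ---------------------------------------------------------------------------
# functional partition
# ---------------------------------------------------------------------------

def test_interface_partition_two_sets_and_separation():
    model, extra = syn.reference_screen_structure()
    prox = sm.his_proximity(model)
    part = sm.interface_partition([], prox, extra["functional_labels"], model)
    assert len(part["activation_interface"]) == 4
    assert len(part["affinity_interface"]) == 3
    assert part["spatially_separated"] is True
    assert part["min_inter_set_distance"] > part["max_intra_set_distance"]
    assert set(part["activation_near_his"]) == set(part["activation_interface"])


def test_interface_partition_empty_labels():
    part = sm.interface_partition([], [], {})
    assert part["activation_interface"] == []
    assert part["affinity_interface"] == []


def test_interface_partition_rejects_unknown_label():
    with pytest.raises(ValueError, match="unknown effect labels"):
        sm.interface_partition([], [], {("NBS", 48): "both"})
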
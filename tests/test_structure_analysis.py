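"""SASA, interfaces, symmetry, superposition, site detection, orientation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cadherlink.structure_analysis import (
    PROBE_RADIUS,
    ChainOverlap,
    DegenerateGeometry,
    NoSymmetry,
    PairingMismatch,
    UnknownChain,
    compute_sasa,
    detect_disulfides,
    detect_metal_sites,
    expand_symmetry,
    interface_area,
    kabsch,
    orientation_projection,
    read_structure,
    sasa_from_arrays,
    superpose_rmsd,
    two_sphere_interface_area,
    two_sphere_sasa,
)
from cadherlink.synthetic_data import (
    ToyStructureConfig,
    generate_toy_structure,
    toy_calcium_model,
    toy_disulfide_model,
    toy_rod_domains,
    toy_two_sphere_model,
    write_pdb,
)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_single_carbon_atom_matches_analytic_sphere():
    area = sasa_from_arrays(np.zeros((1, 3)), np.array([1.7]))
    assert area[0] == pytest.approx(4 * np.pi * (1.7 + PROBE_RADIUS) ** 2, rel=1e-9)
    assert area[0] == pytest.approx(120.76, abs=0.05)


def test_distant_spheres_keep_isolated_area():
    coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    radii = np.array([1.7, 1.7])
    areas = sasa_from_arrays(coords, radii)
    iso = 4 * np.pi * (1.7 + PROBE_RADIUS) ** 2
    assert np.allclose(areas, iso)


@pytest.mark.parametrize("r1,r2,d", [(3.0, 3.0, 4.0), (3.0, 2.0, 3.5),
                                     (2.0, 2.0, 2.0), (4.0, 1.5, 4.2)])
def test_two_sphere_sasa_matches_cap_formula_within_1pct(r1, r2, d):
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    areas = sasa_from_arrays(coords, np.array([r1, r2]), n_points=960)
    exact = two_sphere_sasa(r1, r2, d)
    for got, want in zip(areas, exact):
        assert got == pytest.approx(want, rel=0.01)


def test_sasa_rigid_motion_invariance(rng):
    coords = rng.normal(size=(12, 3)) * 3.0
    radii = np.full(12, 1.7)
    base = sasa_from_arrays(coords, radii)
    R = Rotation.from_euler("zyx", [0.7, -0.2, 1.4]).as_matrix()
    moved = coords @ R.T + np.array([10.0, -4.0, 2.0])
    assert np.allclose(sasa_from_arrays(moved, radii), base, rtol=0.01, atol=0.3)


def test_sasa_cross_checked_against_biotite(rng):
    """Independent route: biotite's Shrake-Rupley agrees per atom on a
    random carbon cluster (same probe, point count and radii)."""
    import biotite.structure as struc

    n = 15
    coords = rng.normal(size=(n, 3)) * 4.0
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.element = np.array(["C"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["GLY"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.chain_id = np.array(["A"] * n)
    theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                        vdw_radii="Single")
    mine = sasa_from_arrays(coords, np.full(n, 1.7), n_points=960)
    assert np.allclose(mine, theirs, rtol=0.02, atol=0.5)


def test_doubling_point_count_changes_sasa_below_half_pct():
    model, _ = toy_two_sphere_model(3.0, 2.5, 4.0)
    coords, radii, _ = model.atom_table()
    a1 = sasa_from_arrays(coords, radii, n_points=960).sum()
    a2 = sasa_from_arrays(coords, radii, n_points=1920).sum()
    assert abs(a1 - a2) / a2 < 0.005


# ---------------------------------------------------------------------------
# interfaces
# ---------------------------------------------------------------------------

def test_disjoint_chains_have_zero_interface():
    model, _ = toy_two_sphere_model(3.0, 3.0, 100.0)
    rep = interface_area(model, ["A"], ["B"])
    assert rep.area == pytest.approx(0.0, abs=1e-6)
    assert not rep.relevant
    assert rep.residues == []


def test_toy_interface_matches_analytic_half_loss():
    model, oracle = toy_two_sphere_model(3.0, 2.5, 4.0)
    rep = interface_area(model, ["A"], ["B"])
    assert rep.area == pytest.approx(oracle["interface_area"], rel=0.01)


def test_interface_symmetric_in_chain_order():
    model, _ = toy_two_sphere_model(3.0, 2.5, 4.0)
    ab = interface_area(model, ["A"], ["B"]).area
    ba = interface_area(model, ["B"], ["A"]).area
    assert ab == pytest.approx(ba)


def test_relevance_threshold_classifies_large_interfaces():
    # giant spheres bury far more than the 856 A^2 empirical threshold
    model, oracle = toy_two_sphere_model(20.0, 20.0, 12.0)
    rep = interface_area(model, ["A"], ["B"])
    assert oracle["interface_area"] > 856
    assert rep.relevant
    # the single sphere-residues lose >30% of isolated SASA
    assert len(rep.residues) == 2


def test_interface_chain_errors():
    model, _ = toy_two_sphere_model()
    with pytest.raises(ChainOverlap):
        interface_area(model, ["A"], ["A"])
    with pytest.raises(UnknownChain):
        interface_area(model, ["A"], ["Z"])


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

MINIMAL_PDB = (
    "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00"
    "           C\nEND\n"
)

TWO_MODEL_PDB = (
    "MODEL        1\n"
    "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00"
    "           C\n"
    "ENDMDL\n"
    "MODEL        2\n"
    "ATOM      1  CA  GLY A   1       5.000   0.000   0.000  1.00  0.00"
    "           C\n"
    "ATOM      2  CA  GLY A   2       9.000   0.000   0.000  1.00  0.00"
    "           C\n"
    "ENDMDL\nEND\n"
)


def test_read_minimal_pdb(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(MINIMAL_PDB)
    model = read_structure(p)
    assert model.chain_ids() == ["A"]
    assert len(model.chains[0].residues[0].atoms) == 1


def test_read_uses_first_model_only(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_MODEL_PDB)
    model = read_structure(p)
    atoms = [a for ch in model.chains for r in ch.residues for a in r.atoms]
    assert len(atoms) == 1
    assert np.allclose(atoms[0].coord, [0, 0, 0])


def test_pdb_round_trip_of_toy_structure(tmp_path):
    model, _ = toy_two_sphere_model(3.0, 2.5, 4.0)
    p = tmp_path / "toy.pdb"
    p.write_text(write_pdb(model))
    back = read_structure(p)
    assert back.chain_ids() == ["A", "B"]
    c0 = back.chains[0].residues[0].atoms[0].coord
    assert np.allclose(c0, [0, 0, 0], atol=1e-3)


# ---------------------------------------------------------------------------
# symmetry expansion
# ---------------------------------------------------------------------------

def test_large_p1_cell_has_no_mates():
    model, _ = toy_two_sphere_model()
    model.spacegroup = "P 1"
    model.cell = (500.0, 500.0, 500.0, 90.0, 90.0, 90.0)
    expanded = expand_symmetry(model)
    # identity operator excluded; distant lattice translations out of range
    assert expanded.chain_ids() == model.chain_ids()


def test_symmetry_mates_found_in_small_cell():
    cfg = ToyStructureConfig(
        chains={"A": [((1.0, 1.0, 1.0), 2.0, "C")]},
        spacegroup="P 21 21 21",
        cell=(10.0, 10.0, 10.0, 90.0, 90.0, 90.0),
    )
    model = generate_toy_structure(cfg)
    expanded = expand_symmetry(model, contact_cutoff=8.0)
    mates = [c for c in expanded.chain_ids() if "~" in c]
    assert mates  # screw-axis mates within contact range
    # every mate has at least one atom within the cutoff of the original
    orig = expanded.chain("A").residues[0].atoms[0].coord
    for mid in mates:
        d = np.linalg.norm(expanded.chain(mid).residues[0].atoms[0].coord - orig)
        assert d <= 8.0 + 1e-6


def test_missing_symmetry_raises():
    model, _ = toy_two_sphere_model()
    with pytest.raises(NoSymmetry):
        expand_symmetry(model)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_kabsch_identical_and_rotated_copies(rng):
    X = rng.normal(size=(40, 3)) * 8
    assert kabsch(X, X).rmsd == pytest.approx(0.0, abs=1e-9)
    R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
    Y = X @ R.T + np.array([3.0, -7.0, 1.0])
    res = kabsch(X, Y)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_kabsch_rmsd_never_exceeds_raw_rmsd(rng):
    for _ in range(5):
        X = rng.normal(size=(30, 3)) * 5
        Y = X + rng.normal(size=(30, 3)) * 0.8
        raw = np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1)))
        assert kabsch(X, Y).rmsd <= raw + 1e-12


def test_superpose_chains_paired_by_residue_and_atom(tmp_path, rng):
    # chain B = rigidly moved copy of chain A with small coordinate noise
    n = 25
    coords = rng.normal(size=(n, 3)) * 6
    R = Rotation.from_euler("xyz", [0.2, 0.5, -0.3]).as_matrix()
    moved = coords @ R.T + 30.0 + rng.normal(size=(n, 3)) * 0.2
    lines = []
    for k, (xyz_a, xyz_b) in enumerate(zip(coords, moved), start=1):
        for ch, xyz in (("A", xyz_a), ("B", xyz_b)):
            lines.append(
                f"ATOM  {k:5d}  CA  GLY {ch}{k:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           C"
            )
    p = tmp_path / "pair.pdb"
    p.write_text("\n".join(lines) + "\nEND\n")
    model = read_structure(p)
    res = superpose_rmsd(model, "A", "B", atom_names=("CA",))
    assert res.atom_count == n
    assert res.rmsd < 0.5  # noise-limited, far below the raw offset
    with pytest.raises(PairingMismatch):
        superpose_rmsd(model, "A", "B", atom_names=("OXT",))


# ---------------------------------------------------------------------------
# metal sites & disulfides
# ---------------------------------------------------------------------------

def test_no_metals_gives_empty_sites():
    model, _ = toy_two_sphere_model()
    assert detect_metal_sites(model) == []


def test_placed_calcium_sites_recovered_with_coordinators():
    model, truth = toy_calcium_model(3, seed=4)
    sites = detect_metal_sites(model, "CA", coordination_cutoff=3.0)
    assert len(sites) == 3
    for (_, _, coordinators), (_, site_ox) in zip(sites, truth):
        assert len(coordinators) == len(site_ox) == 3
        assert all(d <= 3.0 for *_, d in coordinators)


def test_disulfide_detection():
    model, _ = toy_two_sphere_model()
    assert detect_disulfides(model) == []
    pair = detect_disulfides(toy_disulfide_model(2.05))
    assert len(pair) == 1
    assert pair[0][2] == pytest.approx(2.05)
    assert detect_disulfides(toy_disulfide_model(3.2)) == []


# ---------------------------------------------------------------------------
# orientation projections
# ---------------------------------------------------------------------------

def test_collinear_partner_projects_to_origin():
    ref, _ = toy_rod_domains(0.0)
    proj = orientation_projection(ref, ref + np.array([50.0, 0, 0]))
    assert np.allclose(proj.partner_projection, (0.0, 0.0), atol=1e-9)
    assert proj.tilt_degrees == pytest.approx(0.0, abs=1e-6)


def test_partner_at_30_degrees_projects_to_half():
    ref, par = toy_rod_domains(30.0)
    proj = orientation_projection(ref, par)
    assert proj.partner_projection[0] == pytest.approx(0.5, abs=1e-9)
    assert proj.partner_projection[1] == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("tilt", [5.0, 17.0, 44.0, 71.0])
def test_generator_tilt_recovered_within_one_degree(tilt):
    ref, par = toy_rod_domains(tilt)
    proj = orientation_projection(ref, par)
    assert proj.tilt_degrees == pytest.approx(tilt, abs=1.0)


def test_degenerate_geometry_raises():
    with pytest.raises(DegenerateGeometry):
        orientation_projection(np.zeros((2, 3)), np.eye(3))
    with pytest.raises(DegenerateGeometry):
        orientation_projection(np.zeros((5, 3)), np.eye(3))


def test_interface_area_of_symmetry_contact():
    """End-to-end: expand a tight crystal cell and measure a mate contact."""
    cfg = ToyStructureConfig(
        chains={"A": [((1.0, 1.0, 1.0), 2.5, "C")]},
        spacegroup="P 21 21 21",
        cell=(9.0, 9.0, 9.0, 90.0, 90.0, 90.0),
    )
    model = generate_toy_structure(cfg)
    expanded = expand_symmetry(model, contact_cutoff=8.0)
    mates = [c for c in expanded.chain_ids() if "~" in c]
    areas = [interface_area(expanded, ["A"], [m]).area for m in mates]
    assert max(areas) > 0.0
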
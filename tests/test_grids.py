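"""Occupancy grid and PDM projection around a query protein."""

import numpy as np
import pytest

from pdmsite.atom_types import N_TYPES
from pdmsite.grids import GridSpec, compute_occupancy, grid_for_structure, project_pdms
from pdmsite.kb import PairObservation, accumulate_histograms, build_knowledge_base
from pdmsite.structure import AtomSite, Structure
from conftest import random_rotation


def single_atom_structure(type_id=8, radius=1.87, xyz=(0.0, 0.0, 0.0)):
    """One typed surface atom plus two scaffold atoms giving it a frame."""
    atoms = [
        AtomSite("A", "LEU", 1, "CD1", np.asarray(xyz, float), type_id=type_id,
                 radius=radius, sasa_u=10.0),
        AtomSite("A", "LEU", 1, "CG", np.asarray(xyz, float) + [1.4, 0.4, 0.0],
                 type_id=6, radius=1.87, sasa_u=0.0),
        AtomSite("A", "LEU", 1, "CB", np.asarray(xyz, float) + [1.8, 1.8, 0.5],
                 type_id=7, radius=1.87, sasa_u=0.0),
    ]
    return Structure(atoms)


class TestOccupancy:
    def test_cell_at_atom_center_occupied_far_cell_free(self):
        st = single_atom_structure()
        spec = grid_for_structure(st, spacing=1.0, margin=8.0)
        occ = compute_occupancy(st, spec)
        centers = spec.cell_centers()
        d = np.linalg.norm(centers - st.atoms[0].xyz, axis=1)
        flat = occ.occupied.ravel()
        assert flat[np.argmin(d)]
        assert not flat[np.argmax(d)]

    def test_occupied_fraction_matches_monte_carlo_volume(self):
        """Fraction of occupied cells inside a sphere vs a 1e5-point MC
        estimate of the vdW volume fraction."""
        rng = np.random.default_rng(0)
        atoms = [AtomSite("A", "ALA", i + 1, "CB", rng.uniform(-4, 4, 3),
                          type_id=8, radius=1.87, sasa_u=1.0) for i in range(8)]
        st = Structure(atoms)
        spec = GridSpec(origin=(-12.0, -12.0, -12.0), spacing=0.5, dims=(48, 48, 48))
        occ = compute_occupancy(st, spec)
        centers = spec.cell_centers()
        sphere = np.linalg.norm(centers, axis=1) <= 10.0
        frac_grid = occ.occupied.ravel()[sphere].mean()
        pts = rng.uniform(-10, 10, size=(300_000, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= 10.0][:100_000]
        xyz = st.coords()
        inside = np.zeros(len(pts), dtype=bool)
        for x in xyz:
            inside |= np.linalg.norm(pts - x, axis=1) <= 1.87
        np.testing.assert_allclose(frac_grid, inside.mean(), atol=0.03 * max(inside.mean(), 0.01) + 0.002)

    def test_grid_not_covering_structure_is_error(self):
        st = single_atom_structure(xyz=(50.0, 0.0, 0.0))
        spec = GridSpec(origin=(-5.0, -5.0, -5.0), spacing=1.0, dims=(10, 10, 10))
        with pytest.raises(ValueError, match="cover"):
            compute_occupancy(st, spec)


def toy_kb(seed=0, n_obs=300):
    rng = np.random.default_rng(seed)
    obs = []
    for _ in range(n_obs):
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * rng.uniform(3.0, 6.0)
        obs.append(PairObservation(8, int(rng.integers(1, 32)), tuple(v)))
    return accumulate_histograms(obs)


class TestProjection:
    def test_no_surface_atoms_gives_zero_grids(self):
        st = single_atom_structure()
        for a in st.atoms:
            a.sasa_u = 0.0
        grid = project_pdms(st, toy_kb())
        assert grid.n_contributors == 0
        assert np.all(grid.values == 0)

    def test_single_atom_nearest_mode_reproduces_histogram(self):
        """With one contributing atom the global grid is the rigidly placed
        canonical histogram (nearest-cell transfer, occupancy masking off
        away from the protein)."""
        kb = toy_kb()
        st = single_atom_structure()
        spec = grid_for_structure(st, spacing=1.0, margin=10.0)
        grid = project_pdms(st, kb, spec, mode="nearest")
        # total mass: one contributor, histograms normalised per type, some
        # cells masked under the protein spheres
        norm = kb.normalized(8).reshape(N_TYPES, -1).sum(axis=1)
        got = grid.values.reshape(N_TYPES, -1).sum(axis=1)
        assert np.all(got <= norm + 1e-9)
        assert got.sum() > 0.8 * norm.sum()

    def test_projection_is_linear_in_atoms(self):
        """Grids from atoms A+B equal grids from A plus grids from B
        (before averaging)."""
        kb = toy_kb()
        st1 = single_atom_structure(xyz=(0.0, 0.0, 0.0))
        atoms2 = [AtomSite("A", a.res_name, a.res_seq + 1, a.atom_name,
                           a.xyz + [14.0, 0, 0], type_id=a.type_id,
                           radius=a.radius, sasa_u=a.sasa_u) for a in st1.atoms]
        st2 = Structure(atoms2)
        both = Structure([a for a in st1.atoms] + atoms2)
        spec = grid_for_structure(both, margin=10.0)
        g1 = project_pdms(st1, kb, spec, average=False)
        g2 = project_pdms(st2, kb, spec, average=False)
        g12 = project_pdms(both, kb, spec, average=False)
        # mask differs under each sub-structure's spheres; compare off-mask
        occ = (g1.values == 0) | (g2.values == 0) | (g12.values == 0)
        np.testing.assert_allclose(np.where(occ, 0, g12.values),
                                   np.where(occ, 0, g1.values + g2.values),
                                   atol=1e-10)

    def test_trilinear_splat_conserves_mass(self):
        kb = toy_kb()
        st = single_atom_structure()
        spec = grid_for_structure(st, spacing=1.0, margin=12.0)
        grid = project_pdms(st, kb, spec, occupancy=None, mode="trilinear")
        norm_mass = kb.normalized(8).reshape(N_TYPES, -1).sum(axis=1)
        got = grid.values.reshape(N_TYPES, -1).sum(axis=1)
        # occupancy masking removes a little; unmasked mass within 1%+mask
        populated = norm_mass > 0
        assert np.all(got[populated] > 0.5 * norm_mass[populated])
        assert np.all(got <= norm_mass * 1.01 + 1e-12)

    def test_no_density_inside_vdw_spheres(self, typed_reference_set):
        st = typed_reference_set[0]
        kb = build_knowledge_base([st])
        grid = project_pdms(st, kb)
        spec = grid.spec
        centers = spec.cell_centers()
        vals = grid.values.reshape(N_TYPES, -1)
        xyz, radii = st.coords(), st.radii()
        from scipy.spatial import cKDTree

        tree = cKDTree(centers)
        for x, r in zip(xyz[:40], radii[:40]):
            inside = tree.query_ball_point(x, r * 0.999)
            assert np.all(vals[:, inside] == 0)

    def test_rigid_motion_equivariance(self):
        """PDMs of a rotated query equal rotated PDMs (nearest-mode compare
        on matching cells)."""
        kb = toy_kb()
        st = single_atom_structure()
        rng = np.random.default_rng(3)
        rot = random_rotation(rng)
        moved = Structure([AtomSite(a.chain, a.res_name, a.res_seq, a.atom_name,
                                    rot @ a.xyz, type_id=a.type_id,
                                    radius=a.radius, sasa_u=a.sasa_u)
                           for a in st.atoms])
        g_base = project_pdms(st, kb, grid_for_structure(st, margin=10.0))
        g_rot = project_pdms(moved, kb, grid_for_structure(moved, margin=10.0))
        # compare by sampling the rotated grid at rotated base-cell centres
        from scipy.interpolate import RegularGridInterpolator

        spec_r = g_rot.spec
        axes = [np.asarray(spec_r.origin)[k] + (np.arange(spec_r.dims[k]) + 0.5)
                * spec_r.spacing for k in range(3)]
        base_centers = g_base.spec.cell_centers()
        pts = base_centers @ rot.T
        tol = 1e-6 * max(g_base.values.max(), 1e-30)
        sel = np.linalg.norm(base_centers - st.atoms[0].xyz, axis=1) < 7.0
        for j in (6, 7, 14, 30):
            interp = RegularGridInterpolator(axes, g_rot.values[j],
                                             bounds_error=False, fill_value=0.0)
            want = interp(pts[sel])
            got = g_base.values[j].ravel()[sel]
            # trilinear resampling smooths; demand strong correlation and
            # matching total mass instead of cell-wise identity
            if got.sum() > 0:
                assert abs(want.sum() - got.sum()) / got.sum() < 0.25
                c = np.corrcoef(want, got)[0, 1]
                assert c > 0.7
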
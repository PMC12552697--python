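"""Linear-elastic finite elements on voxel grids, with contact and fracture.

Every solid voxel of a label volume becomes one trilinear (8-node)
hexahedral element; materials are isotropic and linear elastic (an explicit
per-voxel 6x6 elasticity field may override, which the macroscale growth
model uses for homogenized cells). The assembled system K u = f is solved
with a sparse direct factorization for small problems and Jacobi-
preconditioned conjugate gradients (relative residual 1e-8) otherwise;
ordering is deterministic.

Interfaces between material pairs may be bonded (shared nodes — the voxel
default), excluded (the material is removed), or frictional: interface
nodes are duplicated and coupled by penalty springs that act only in
compression along the interface normal, with tangential traction capped at
mu times the normal pressure (active-set iteration).

Fracture uses the maximum-principal-stress initiation criterion
f = sigma_1 / sigma_max with strict exceedance, and a sequential
element-erosion surrogate for crack propagation: at each load level the
element with the largest ratio above 1 is removed and the system re-solved
until the crack arrests or fails to arrest (percolates or leaves the
system singular).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .image import ImageVolume
from .materials import MaterialModel, isotropic_stiffness

VOID = 0

# VTK hexahedron local node order (offsets within a voxel).
OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
])
_XI = 2.0 * OFFSETS - 1.0  # local corner coordinates in [-1, 1]^3


class SolverError(RuntimeError):
    pass


class FloatingIslandError(SolverError):
    """A connected blob of material carries no constraint (rigid-body mode)."""


def _shape_gradients(xi: np.ndarray, h: np.ndarray) -> np.ndarray:
    """dN/dx for the 8 trilinear shape functions at local point xi. (8, 3)"""
    g = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        g[a, 0] = 0.125 * xa * (1 + ya * xi[1]) * (1 + za * xi[2]) * (2.0 / h[0])
        g[a, 1] = 0.125 * ya * (1 + xa * xi[0]) * (1 + za * xi[2]) * (2.0 / h[1])
        g[a, 2] = 0.125 * za * (1 + xa * xi[0]) * (1 + ya * xi[1]) * (2.0 / h[2])
    return g


def _b_matrix(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24), Voigt order xx,yy,zz,yz,xz,xy."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz
        B[3, c + 2] = gy
        B[4, c] = gz
        B[4, c + 2] = gx
        B[5, c] = gy
        B[5, c + 1] = gx
    return B


def hex_quadrature(h) -> tuple[np.ndarray, float, np.ndarray]:
    """(B at 8 Gauss points (8,6,24), weight*detJ per point, B at centroid)."""
    h = np.asarray(h, dtype=float)
    gp = 1.0 / np.sqrt(3.0)
    Bs = np.stack([
        _b_matrix(_shape_gradients(gp * _XI[a], h)) for a in range(8)
    ])
    detJw = float(np.prod(h)) / 8.0
    B0 = _b_matrix(_shape_gradients(np.zeros(3), h))
    return Bs, detJw, B0


def element_stiffness(C: np.ndarray, h) -> np.ndarray:
    """24x24 stiffness of a voxel element with elasticity C (6x6)."""
    Bs, detJw, _ = hex_quadrature(h)
    return sum(B.T @ C @ B for B in Bs) * detJw


def element_stiffness_batch(C: np.ndarray, h) -> np.ndarray:
    """Stiffness for a batch of per-element C matrices. C: (n, 6, 6)."""
    Bs, detJw, _ = hex_quadrature(h)
    return np.einsum("gai,nab,gbj->nij", Bs, C, Bs, optimize=True) * detJw


# ---------------------------------------------------------------------------
# Load case definition
# ---------------------------------------------------------------------------

@dataclass
class DirichletBC:
    """Fixed displacement components on the corner nodes of a voxel patch.

    ``value`` may be a scalar, a length-3 vector, or a callable mapping an
    (n, 3) array of node coordinates (mm) to an (n, 3) displacement array.
    ``components`` selects which of (0, 1, 2) = (x, y, z) are constrained.
    """

    patch: np.ndarray
    components: tuple[int, ...] = (0, 1, 2)
    value: object = 0.0
    face: str | None = None  # restrict to one node plane, e.g. '-x'


@dataclass
class Load:
    """Total force (N) distributed over a voxel patch.

    With ``face`` one of '+x','-x','+y','-y','+z','-z' the force is applied
    with trilinear-consistent weights on that face of the patch voxels
    (uniform traction); otherwise it is spread equally over all patch
    corner nodes.
    """

    patch: np.ndarray
    force: tuple[float, float, float]
    face: str | None = None


BONDED = "bonded"
EXCLUDED = "excluded"


def frictional(mu: float):
    return ("frictional", float(mu))


@dataclass
class LoadCase:
    dirichlet: list = dc_field(default_factory=list)
    loads: list = dc_field(default_factory=list)
    interface_mode: dict = dc_field(default_factory=dict)
    """Map frozenset({label_a, label_b}) -> BONDED | EXCLUDED-label | frictional(mu).

    A single label key with value EXCLUDED removes that material entirely.
    """

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(
            dirichlet=self.dirichlet,
            loads=[Load(l.patch, tuple(factor * f for f in l.force), l.face)
                   for l in self.loads],
            interface_mode=self.interface_mode,
        )


# ---------------------------------------------------------------------------
# Stress field result
# ---------------------------------------------------------------------------

def von_mises(stress: np.ndarray) -> np.ndarray:
    s = np.asarray(stress)
    sxx, syy, szz, syz, sxz, sxy = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy ** 2 + syz ** 2 + sxz ** 2)
    )


def principal_stresses(stress: np.ndarray) -> np.ndarray:
    """Sorted principal stresses (ascending) per row of Voigt stresses."""
    s = np.asarray(stress)
    T = np.zeros(s.shape[:-1] + (3, 3))
    T[..., 0, 0] = s[..., 0]
    T[..., 1, 1] = s[..., 1]
    T[..., 2, 2] = s[..., 2]
    T[..., 1, 2] = T[..., 2, 1] = s[..., 3]
    T[..., 0, 2] = T[..., 2, 0] = s[..., 4]
    T[..., 0, 1] = T[..., 1, 0] = s[..., 5]
    return np.linalg.eigvalsh(T)


@dataclass
class StressField:
    """Element-wise stress state and nodal displacements of one solve."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    elems: np.ndarray          # (n, 3) voxel indices of the solid elements
    elem_labels: np.ndarray    # (n,) material label per element
    stress: np.ndarray         # (n, 6) Voigt, MPa
    displacement: np.ndarray   # (nx+1, ny+1, nz+1, 3), mm
    external_work: float       # 0.5 * f.u, N*mm
    strain_energy: float       # 0.5 * u.K.u, N*mm

    @property
    def von_mises(self) -> np.ndarray:
        return von_mises(self.stress)

    @property
    def max_principal(self) -> np.ndarray:
        return principal_stresses(self.stress)[:, 2]

    def volume(self, per_elem: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.shape, fill, dtype=float)
        out[tuple(self.elems.T)] = per_elem
        return out


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

def _resolve_active_labels(labels: np.ndarray, materials: dict, case: LoadCase):
    """Labels kept in the system after applying EXCLUDED interface modes."""
    excluded = set()
    pairs = []
    for key, mode in case.interface_mode.items():
        if mode == EXCLUDED:
            for lab in (key if isinstance(key, frozenset) else [key]):
                excluded.add(int(lab))
        elif isinstance(mode, tuple) and mode[0] == "frictional":
            la, lb = sorted(key)
            pairs.append((int(la), int(lb), float(mode[1])))
        elif mode == BONDED:
            pass
        else:
            raise ValueError(f"unknown interface mode {mode!r}")
    active = sorted(set(np.unique(labels)) - {VOID} - excluded)
    active = [lab for lab in active if lab in materials]
    return active, pairs


class VoxelSystem:
    """Assembled FE system for one label volume and load case."""

    def __init__(self, labels: ImageVolume, materials: dict, case: LoadCase,
                 C_field: np.ndarray | None = None):
        vol = labels.values
        self.shape = vol.shape
        self.spacing = labels.spacing
        self.origin = labels.origin
        self.case = case
        self.materials = materials

        active_labels, self.contact_pairs_spec = _resolve_active_labels(
            vol, materials, case)
        solid = np.isin(vol, active_labels)
        if not solid.any():
            raise SolverError("no solid elements in the system")
        self.elems = np.argwhere(solid)
        self.elem_labels = vol[tuple(self.elems.T)].astype(int)

        nx, ny, nz = self.shape
        self.node_shape = (nx + 1, ny + 1, nz + 1)
        self.n_base_nodes = int(np.prod(self.node_shape))

        def node_id(i, j, k):
            return (i * self.node_shape[1] + j) * self.node_shape[2] + k

        self._node_id = node_id
        e = self.elems
        conn = np.empty((len(e), 8), dtype=np.int64)
        for a, (oi, oj, ok) in enumerate(OFFSETS):
            conn[:, a] = node_id(e[:, 0] + oi, e[:, 1] + oj, e[:, 2] + ok)
        self.conn = conn

        # --- frictional interfaces: duplicate shared nodes for the B side
        self.contact_pairs = []  # (orig_node, dup_node, normal, mu, kp)
        self.n_nodes = self.n_base_nodes
        for la, lb, mu in self.contact_pairs_spec:
            self._duplicate_interface(vol, la, lb, mu)

        self.ndof = 3 * self.n_nodes
        self._assemble(C_field)
        self._apply_loads()
        self._collect_dirichlet()
        self._check_islands()

    # -- interface node duplication ------------------------------------
    def _duplicate_interface(self, vol, la, lb, mu):
        mask_a = vol == la
        mask_b = vol == lb
        if not (mask_a.any() and mask_b.any()):
            return
        normals = {}
        for axis in range(3):
            for sign in (+1, -1):
                shifted = np.roll(mask_b, -sign, axis=axis)
                if sign > 0:
                    shifted[tuple(slice(None) if a != axis else -1
                                  for a in range(3))] = False
                else:
                    shifted[tuple(slice(None) if a != axis else 0
                                  for a in range(3))] = False
                faces = np.argwhere(mask_a & shifted)
                for (i, j, k) in faces:
                    # shared face nodes: the 4 corners of the A voxel face
                    # pointing towards B
                    for off in OFFSETS:
                        proj = off[axis]
                        if (sign > 0 and proj == 1) or (sign < 0 and proj == 0):
                            nid = self._node_id(i + off[0], j + off[1], k + off[2])
                            n = normals.setdefault(nid, np.zeros(3))
                            n[axis] += sign
        if not normals:
            return
        is_b_elem = self.elem_labels == lb
        b_nodes = set(np.unique(self.conn[is_b_elem]))
        kp = self._penalty_stiffness(la, lb)
        remap = {}
        for nid, nvec in sorted(normals.items()):
            if nid not in b_nodes:
                continue
            norm = np.linalg.norm(nvec)
            if norm < 1e-12:
                continue
            dup = self.n_nodes
            self.n_nodes += 1
            remap[nid] = dup
            self.contact_pairs.append((nid, dup, nvec / norm, mu, kp))
        if remap:
            lut = np.arange(self.n_nodes, dtype=np.int64)
            for k_, v_ in remap.items():
                lut[k_] = v_
            self.conn[is_b_elem] = lut[self.conn[is_b_elem]]

    def _penalty_stiffness(self, la, lb) -> float:
        # 100x the axial stiffness of the stiffer neighbouring element
        E = max(self.materials[la].E, self.materials[lb].E)
        h = float(np.mean(self.spacing))
        return 100.0 * E * h

    # -- assembly -------------------------------------------------------
    def _assemble(self, C_field):
        h = self.spacing
        n_el = len(self.elems)
        edof = np.empty((n_el, 24), dtype=np.int64)
        edof[:, 0::3] = 3 * self.conn
        edof[:, 1::3] = 3 * self.conn + 1
        edof[:, 2::3] = 3 * self.conn + 2
        self.edof = edof

        if C_field is not None:
            C_e = C_field[tuple(self.elems.T)]
            ke_all = element_stiffness_batch(C_e, h)
            self.elem_C = C_e
        else:
            labs = np.unique(self.elem_labels)
            ke_by_label = {}
            C_by_label = {}
            for lab in labs:
                C = self.materials[int(lab)].stiffness_matrix()
                ke_by_label[int(lab)] = element_stiffness(C, h)
                C_by_label[int(lab)] = C
            ke_all = np.stack([ke_by_label[int(l)] for l in self.elem_labels])
            self.elem_C = np.stack([C_by_label[int(l)] for l in self.elem_labels])

        rows = np.repeat(edof, 24, axis=1).ravel()
        cols = np.tile(edof, (1, 24)).ravel()
        K = sp.coo_matrix((ke_all.ravel(), (rows, cols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        self.K_bulk = K

    def contact_stiffness(self, active: np.ndarray, t_scale: np.ndarray) -> sp.csr_matrix:
        """Penalty-spring stiffness for the current contact state."""
        if not self.contact_pairs:
            return sp.csr_matrix((self.ndof, self.ndof))
        rows, cols, data = [], [], []
        eps_open = 1e-8
        for idx, (a, b, n, mu, kp) in enumerate(self.contact_pairs):
            if active[idx]:
                Kn = kp * np.outer(n, n)
                Kt = kp * float(t_scale[idx]) * (np.eye(3) - np.outer(n, n))
                Kp = Kn + Kt
            else:
                Kp = eps_open * kp * np.eye(3)
            for (na, nb, s) in ((a, a, 1.0), (b, b, 1.0), (a, b, -1.0), (b, a, -1.0)):
                for ci in range(3):
                    for cj in range(3):
                        rows.append(3 * na + ci)
                        cols.append(3 * nb + cj)
                        data.append(s * Kp[ci, cj])
        return sp.coo_matrix((data, (rows, cols)),
                             shape=(self.ndof, self.ndof)).tocsr()

    # -- loads and constraints ------------------------------------------
    def _patch_nodes(self, patch, face=None) -> tuple[np.ndarray, np.ndarray]:
        """Node ids and weights (sum 1) over a voxel patch."""
        vox = np.argwhere(np.asarray(patch, dtype=bool))
        if len(vox) == 0:
            raise ValueError("empty load/constraint patch")
        counts = {}
        if face is None:
            sel = range(8)
        else:
            axis = {"x": 0, "y": 1, "z": 2}[face[1]]
            want = 1 if face[0] == "+" else 0
            sel = [a for a in range(8) if OFFSETS[a][axis] == want]
        for (i, j, k) in vox:
            for a in sel:
                oi, oj, ok = OFFSETS[a]
                nid = self._node_id(i + oi, j + oj, k + ok)
                counts[nid] = counts.get(nid, 0) + 1
        nodes = np.array(sorted(counts))
        w = np.array([counts[n] for n in nodes], dtype=float)
        w /= w.sum()
        return nodes, w

    def _apply_loads(self):
        f = np.zeros(self.ndof)
        for load in self.case.loads:
            nodes, w = self._patch_nodes(load.patch, load.face)
            F = np.asarray(load.force, dtype=float)
            for c in range(3):
                f[3 * nodes + c] += w * F[c]
        self.f = f

    def node_coords(self, nodes: np.ndarray) -> np.ndarray:
        k = nodes % self.node_shape[2]
        j = (nodes // self.node_shape[2]) % self.node_shape[1]
        i = nodes // (self.node_shape[1] * self.node_shape[2])
        return np.stack([i, j, k], axis=1) * np.asarray(self.spacing) + \
            np.asarray(self.origin)

    def _collect_dirichlet(self):
        fixed = {}
        for bc in self.case.dirichlet:
            nodes, _ = self._patch_nodes(bc.patch, bc.face)
            coords = self.node_coords(nodes)
            if callable(bc.value):
                vals = np.asarray(bc.value(coords), dtype=float)
            else:
                v = np.asarray(bc.value, dtype=float)
                vals = np.broadcast_to(
                    v if v.ndim else np.array([float(v)] * 3), (len(nodes), 3)
                )
            for c in bc.components:
                for n_, val in zip(nodes, vals[:, c]):
                    fixed[3 * n_ + c] = float(val)
        if not fixed:
            raise SolverError("load case has no Dirichlet constraints")
        self.fixed_dofs = np.array(sorted(fixed))
        self.fixed_vals = np.array([fixed[d] for d in self.fixed_dofs])

    def _check_islands(self):
        solid = np.zeros(self.shape, dtype=bool)
        solid[tuple(self.elems.T)] = True
        lbl, n = ndimage.label(solid, structure=np.ones((3, 3, 3)))
        fixed_by_node: dict[int, set] = {}
        for d in self.fixed_dofs:
            fixed_by_node.setdefault(int(d) // 3, set()).add(int(d) % 3)
        comp_of_elem = lbl[tuple(self.elems.T)]
        for comp in range(1, n + 1):
            members = comp_of_elem == comp
            nodes = np.unique(self.conn[members])
            dirs: set = set()
            for nd in nodes:
                dirs |= fixed_by_node.get(int(nd), set())
                if len(dirs) == 3:
                    break
            if len(dirs) < 3:
                size = int(members.sum())
                raise FloatingIslandError(
                    f"material island (component {comp}, {size} elements) is "
                    f"unconstrained along axes {sorted({0, 1, 2} - dirs)}; "
                    "rigid-body mode"
                )

    # -- solution ---------------------------------------------------------
    def _solve_linear(self, K: sp.csr_matrix, f: np.ndarray) -> np.ndarray:
        free = np.setdiff1d(np.arange(self.ndof), self.fixed_dofs,
                            assume_unique=False)
        # move known values to the rhs
        u = np.zeros(self.ndof)
        u[self.fixed_dofs] = self.fixed_vals
        rhs = f - K @ u
        Kff = K[free][:, free]
        # drop fully unused dofs (nodes not touched by any element/spring)
        diag = Kff.diagonal()
        used = diag != 0
        if not used.all():
            Kff = Kff[used][:, used]
        rhs_f = rhs[free][used] if not used.all() else rhs[free]
        nfree = Kff.shape[0]
        if nfree == 0:
            return u
        if nfree <= 80_000:
            lu = spla.splu(Kff.tocsc(), permc_spec="MMD_AT_PLUS_A")
            sol = lu.solve(rhs_f)
        else:
            d = Kff.diagonal()
            M = sp.diags(1.0 / np.where(d > 0, d, 1.0))
            sol, info = spla.cg(Kff, rhs_f, M=M, rtol=1e-8, maxiter=20_000)
            if info != 0:
                raise SolverError(f"CG failed to converge (info={info})")
        if not np.all(np.isfinite(sol)):
            raise SolverError("singular system (non-finite solution)")
        full = np.zeros(len(free))
        if not used.all():
            full[used] = sol
        else:
            full = sol
        u[free] = full
        return u

    def solve(self, max_contact_iter: int = 12) -> StressField:
        if not self.contact_pairs:
            u = self._solve_linear(self.K_bulk, self.f)
        else:
            npair = len(self.contact_pairs)
            active = np.ones(npair, dtype=bool)
            t_scale = np.ones(npair)
            u = None
            for _ in range(max_contact_iter):
                K = self.K_bulk + self.contact_stiffness(active, t_scale)
                u = self._solve_linear(K, self.f)
                new_active = active.copy()
                new_scale = t_scale.copy()
                for idx, (a, b, n, mu, kp) in enumerate(self.contact_pairs):
                    d = u[3 * b:3 * b + 3] - u[3 * a:3 * a + 3]
                    gap = float(d @ n)
                    new_active[idx] = gap < 0  # penetration => compression
                    if new_active[idx]:
                        p = kp * (-gap)
                        dt = d - gap * n
                        tmag = kp * t_scale[idx] * float(np.linalg.norm(dt))
                        if tmag > mu * p and tmag > 0:
                            new_scale[idx] = max(t_scale[idx] * mu * p / tmag,
                                                 1e-6)
                        else:
                            new_scale[idx] = min(1.0, t_scale[idx] * 1.5)
                changed = (new_active != active).any() or \
                    np.max(np.abs(new_scale - t_scale)) > 0.05
                active, t_scale = new_active, new_scale
                if not changed:
                    break
            K = self.K_bulk + self.contact_stiffness(active, t_scale)

        K_used = self.K_bulk if not self.contact_pairs else K
        # element stresses at centroids
        _, _, B0 = hex_quadrature(self.spacing)
        u_e = u[self.edof]  # (n, 24)
        eps = u_e @ B0.T
        stress = np.einsum("nab,nb->na", self.elem_C, eps)

        ext = 0.5 * float(self.f @ u)
        strain = 0.5 * float(u @ (K_used @ u))

        disp = np.zeros(self.node_shape + (3,))
        base = u[: 3 * self.n_base_nodes].reshape(self.n_base_nodes, 3)
        disp[...] = base.reshape(self.node_shape + (3,))
        return StressField(
            shape=self.shape, spacing=self.spacing, elems=self.elems,
            elem_labels=self.elem_labels, stress=stress, displacement=disp,
            external_work=ext, strain_energy=strain,
        )


def assemble_and_solve(labels: ImageVolume, materials: dict, case: LoadCase,
                       C_field: np.ndarray | None = None) -> StressField:
    """Assemble and solve one voxel FE problem; see :class:`VoxelSystem`."""
    return VoxelSystem(labels, materials, case, C_field=C_field).solve()


# ---------------------------------------------------------------------------
# Fracture: MPS initiation and element-erosion propagation
# ---------------------------------------------------------------------------

def failure_ratios(field: StressField, materials: dict,
                   tip_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-element stress ratio f = sigma_1 / sigma_max.

    Compressive maximum principal stress never initiates (ratio 0); materials
    without a tensile strength are excluded (ratio 0). Elements flagged in
    ``tip_mask`` (crack-tip neighbourhood) use a toughness-limited allowable
    stress min(sigma_max, K_Ic / sqrt(pi * h/2)).
    """
    s1 = field.max_principal
    f = np.zeros(len(s1))
    h_m = float(np.mean(field.spacing)) * 1e-3  # element size in metres
    for lab in np.unique(field.elem_labels):
        mat = materials[int(lab)]
        if mat.sigma_max is None:
            continue
        sel = field.elem_labels == lab
        allow = np.full(sel.sum(), mat.sigma_max)
        if tip_mask is not None and mat.K_Ic is not None:
            at_tip = tip_mask[tuple(field.elems[sel].T)]
            allow_tip = mat.K_Ic / np.sqrt(np.pi * h_m / 2.0)
            allow[at_tip] = min(mat.sigma_max, allow_tip)
        f[sel] = np.maximum(s1[sel], 0.0) / allow
    return f


def crack_initiation(field: StressField, materials: dict) -> tuple[np.ndarray, np.ndarray]:
    """(flags, ratios): element fails iff f > 1 strictly."""
    f = failure_ratios(field, materials)
    return f > 1.0, f


def _patches_connected(labels_vals: np.ndarray, case: LoadCase) -> bool:
    solid = labels_vals != VOID
    lbl, _ = ndimage.label(solid, structure=np.ones((3, 3, 3)))

    def comp_set(patch):
        # patch voxels may themselves be eroded; look at surviving ones
        sel = np.asarray(patch, dtype=bool) & solid
        return set(np.unique(lbl[sel]).tolist()) - {0}

    loaded = set()
    for l in case.loads:
        loaded |= comp_set(l.patch)
    constrained = set()
    for bc in case.dirichlet:
        constrained |= comp_set(bc.patch)
    return bool(loaded & constrained)


@dataclass
class CrackResult:
    path: list                  # ordered (i, j, k) eroded elements
    failure_load: float | None  # first non-arresting load level (N scale)
    arrested_levels: list       # load levels that arrested
    history: list               # (level, n_eroded_cumulative)


def propagate_crack(labels: ImageVolume, materials: dict, case: LoadCase,
                    load_schedule, use_toughness_arrest: bool = True,
                    max_eroded_frac: float = 0.3,
                    refine_to: float = 0.01) -> CrackResult:
    """Element-erosion crack propagation over a monotone load schedule.

    At each level the worst element with f > 1 is eroded and the system
    re-solved until arrest. Failure is declared at the first level where
    erosion does not arrest: the crack disconnects the loaded patch from
    the constraints, the system goes singular, or the erosion budget
    (``max_eroded_frac`` of the initial solid) is exhausted. The failure
    load is then bisection-refined to ``refine_to`` of the schedule span.
    """
    schedule = list(load_schedule)
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("load schedule must be strictly increasing")

    work = labels.with_values(labels.values.copy())
    n_solid0 = int(np.count_nonzero(work.values))
    budget = max(1, int(max_eroded_frac * n_solid0))
    path: list = []
    tip = np.zeros(work.shape, dtype=bool)

    def erode_at(level, state_vals, tip_state, path_state):
        """Run erosion at one load level; returns (arrested, vals, tip, path)."""
        vals = state_vals.copy()
        tip_l = tip_state.copy()
        path_l = list(path_state)
        scaled = case.scaled(level)
        while True:
            try:
                fldvol = labels.with_values(vals)
                sfield = assemble_and_solve(fldvol, materials, scaled)
            except SolverError:
                return False, vals, tip_l, path_l
            f = failure_ratios(sfield, materials,
                               tip_l if use_toughness_arrest else None)
            if f.max() <= 1.0:
                return True, vals, tip_l, path_l
            worst = int(np.argmax(f))
            ijk = tuple(sfield.elems[worst])
            vals[ijk] = VOID
            path_l.append(ijk)
            # crack-tip neighbourhood: 6-neighbours of every eroded element
            m = np.zeros_like(tip_l)
            m[ijk] = True
            tip_l |= ndimage.binary_dilation(m)
            tip_l[vals == VOID] = False
            if len(path_l) > budget or not _patches_connected(vals, scaled):
                return False, vals, tip_l, path_l

    arrested_levels = []
    history = []
    failure = None
    last_safe_state = (work.values.copy(), tip.copy(), list(path))
    last_safe_level = 0.0
    for level in schedule:
        ok, vals, tip, path = erode_at(level, *last_safe_state)
        history.append((level, len(path)))
        if ok:
            arrested_levels.append(level)
            last_safe_state = (vals, tip, list(path))
            last_safe_level = level
        else:
            failure = level
            break

    if failure is not None and arrested_levels:
        lo, hi = last_safe_level, failure
        span = schedule[-1] - schedule[0]
        while hi - lo > refine_to * span:
            mid = 0.5 * (lo + hi)
            ok, vals, tip_m, path_m = erode_at(mid, *last_safe_state)
            if ok:
                lo = mid
                last_safe_state = (vals, tip_m, list(path_m))
            else:
                hi = mid
        failure = hi
        path = last_safe_state[2] if not path else path

    return CrackResult(path=path, failure_load=failure,
                       arrested_levels=arrested_levels, history=history)


# ---------------------------------------------------------------------------
# Force-displacement utilities
# ---------------------------------------------------------------------------

def stiffness_from_curve(force: np.ndarray, displacement: np.ndarray,
                         window: tuple[int, int] | None = None) -> float:
    """Least-squares slope (N/mm) of a force-displacement curve.

    ``window`` selects the linear regime as an index slice (start, stop);
    the default is the full range.
    """
    f = np.asarray(force, dtype=float)
    d = np.asarray(displacement, dtype=float)
    if f.shape != d.shape or f.size < 2:
        raise ValueError("need >= 2 matching force/displacement samples")
    if np.any(np.diff(d) < 0):
        raise ValueError("displacement must be non-decreasing")
    if window is not None:
        f = f[window[0]:window[1]]
        d = d[window[0]:window[1]]
    if np.ptp(d) == 0:
        raise ValueError("constant displacement: stiffness fit degenerate")
    slope, _ = np.polyfit(d, f, 1)
    return float(slope)
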
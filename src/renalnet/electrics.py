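"""Electrotonic conduction through the endothelial syncytium of a tree.

Each vessel wall is discretized into units of one endothelial-cell length;
a unit lumps the N cells of the cross-section, giving unit leak conductance
G_u = N*G_c, capacitance C_u = N*C_c and longitudinal gap-junction
conductance G_g = N*G_gj. Branch points couple the three adjoining vessel
ends through a triangle of pairwise conductances obtained by splitting each
vessel's cells toward the two others in proportion to their diameters and
averaging the two directed counts.

Because membrane dynamics are taken as instantaneous and linear, the
voltage response to macula-densa current injections is a quasi-static
linear problem: one sparse factorization yields the full nephron-to-nephron
coupling matrix (voltage-transfer coefficients between arteriole tips).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .tree import VascularTree

__all__ = [
    "ElectricalParams",
    "ElectricalNetwork",
    "discretize_vessel",
    "branch_conductances",
    "root_conductance",
    "build_network",
    "steady_state_voltages",
    "coupling_strength",
    "coupling_matrix",
]


@dataclass(frozen=True)
class ElectricalParams:
    """Endothelial-cell constants.

    Conductances in 1/MOhm, capacitance pF, potentials mV, sizes um. With
    these units (1/MOhm)*(mV) = nA, so injected currents are in nA.
    ``eq6_literal`` switches the longitudinal coupling coefficient of inner
    units from the gap-junction conductance to the unit leak conductance,
    reproducing the alternative (likely mistyped) published form.
    """

    w_c: float = 5.0      # endothelial cell width (cross-section pitch)
    l_c: float = 50.0     # effective endothelial cell length (unit length)
    g_gj: float = 1.0 / 3.0  # per-cell gap junction conductance
    g_c: float = 1.0 / 8.0   # per-cell membrane conductance
    c_c: float = 20.0     # per-cell capacitance
    v_rest: float = -40.0
    eq6_literal: bool = False


def _round_half_away(x) -> int:
    return int(np.floor(x + 0.5))


def discretize_vessel(diam, length, params: ElectricalParams = ElectricalParams()):
    """Cell counts and lumped unit parameters for one vessel.

    N = round(pi*D/W_c) cells per cross-section, M = round(L/L_c) units
    along the vessel; both floored at 1.
    """
    n = max(1, _round_half_away(np.pi * diam / params.w_c))
    m = max(1, _round_half_away(length / params.l_c))
    return n, m, n * params.g_c, n * params.c_c, n * params.g_gj


def _split_largest_remainder(n, w1, w2):
    """Split n cells into two parts proportional to weights w1:w2 by
    largest-remainder apportionment (parts always sum to n exactly).

    An exact remainder tie (equal weights, odd n) is split evenly rather
    than favoring either side, so the rule is symmetric under swapping the
    two targets; only in that degenerate case can a count be half-integer.
    """
    q1 = n * w1 / (w1 + w2)
    q2 = n * w2 / (w1 + w2)
    f1, f2 = np.floor(q1), np.floor(q2)
    rem = n - f1 - f2
    if rem:
        r1, r2 = q1 - f1, q2 - f2
        if abs(r1 - r2) < 1e-12:
            f1 += rem / 2.0
            f2 += rem / 2.0
        elif r1 > r2:
            f1 += rem
        else:
            f2 += rem
    return f1, f2


def branch_conductances(d_i, d_j, d_k, params: ElectricalParams = ElectricalParams()):
    """Triangle conductances (G_ij, G_ik, G_jk) at a three-vessel branch.

    Vessel i's cross-section cells split toward j and k in proportion to
    D_j:D_k (and cyclically); the gap-junction count between two vessels is
    the arithmetic mean of the two directed cell counts, which makes the
    coupling symmetric by construction.
    """
    n_i, *_ = discretize_vessel(d_i, params.l_c, params)
    n_j, *_ = discretize_vessel(d_j, params.l_c, params)
    n_k, *_ = discretize_vessel(d_k, params.l_c, params)
    i_to_j, i_to_k = _split_largest_remainder(n_i, d_j, d_k)
    j_to_i, j_to_k = _split_largest_remainder(n_j, d_i, d_k)
    k_to_i, k_to_j = _split_largest_remainder(n_k, d_i, d_j)
    g_ij = 0.5 * (i_to_j + j_to_i) * params.g_gj
    g_ik = 0.5 * (i_to_k + k_to_i) * params.g_gj
    g_jk = 0.5 * (j_to_k + k_to_j) * params.g_gj
    return g_ij, g_ik, g_jk


def root_conductance(n_root, params: ElectricalParams = ElectricalParams()):
    """Boundary conductance tying the root segment to resting upstream
    tissue: every root cross-section cell couples to two downstream cells."""
    if n_root < 1:
        raise ValueError("cell count must be >= 1")
    return 2 * n_root * params.g_gj


@dataclass
class ElectricalNetwork:
    """Assembled unit graph of one tree.

    Voltages are stored as deflections u = V - V_rest, so the quasi-static
    balance reads (G_u + sum G_nb) u - sum G_nb u_nb = I with the root
    clamp entering the diagonal only.
    """

    params: ElectricalParams
    n_units: int
    unit_leak: np.ndarray          # G_u per unit, incl. boundary clamp
    matrix: sp.csr_matrix          # symmetric system matrix
    first_unit: dict               # vessel id -> index of its upstream unit
    n_vessel_units: dict           # vessel id -> M
    _solver: object = field(default=None, repr=False)

    def distal_unit(self, vessel_id) -> int:
        return self.first_unit[vessel_id] + self.n_vessel_units[vessel_id] - 1

    def solve(self, injections: np.ndarray) -> np.ndarray:
        """Deflections u (mV) for per-unit current injections (nA)."""
        if self._solver is None:
            self._solver = spla.factorized(self.matrix.tocsc())
        b = np.asarray(injections, float)
        if b.shape[0] != self.n_units:
            raise ValueError("injection vector has wrong length")
        return self._solver(b)


def build_network(tree: VascularTree,
                  params: ElectricalParams = ElectricalParams()) -> ElectricalNetwork:
    """Discretize every vessel (arteries and arterioles) and assemble the
    quasi-static conductance matrix."""
    first_unit = {}
    n_units_of = {}
    g_u = []
    g_long = []  # per vessel: longitudinal coupling conductance
    total = 0
    for v in tree.vessels:
        n, m, gu, _, gg = discretize_vessel(v.diameter, v.length, params)
        first_unit[v.id] = total
        n_units_of[v.id] = m
        total += m
        g_u.append(gu)
        g_long.append(gu if params.eq6_literal else gg)
    leak = np.zeros(total)
    rows, cols, vals = [], [], []

    def couple(a, b, g):
        rows.extend((a, b, a, b))
        cols.extend((b, a, a, b))
        vals.extend((-g, -g, g, g))

    for v in tree.vessels:
        f, m = first_unit[v.id], n_units_of[v.id]
        leak[f:f + m] += g_u[v.id]
        for u in range(f, f + m - 1):
            couple(u, u + 1, g_long[v.id])
    # branch points: connect end units of the vessels meeting at each node
    children = tree.children_map()
    inbound = tree.inbound_map()
    for node, kids in children.items():
        up = inbound.get(node)
        if up is None:
            continue  # root inlet handled below
        members = [up] + list(kids)
        ends = {}
        for v in members:
            ends[v.id] = (first_unit[v.id] + n_units_of[v.id] - 1
                          if v is up else first_unit[v.id])
        if len(members) == 2:
            a, b = members
            n_a, *_ = discretize_vessel(a.diameter, params.l_c, params)
            n_b, *_ = discretize_vessel(b.diameter, params.l_c, params)
            couple(ends[a.id], ends[b.id], 0.5 * (n_a + n_b) * params.g_gj)
        else:
            # triangle (or clique of triangles when >2 daughters share a node)
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    for z in range(y + 1, len(members)):
                        a, b, c = members[x], members[y], members[z]
                        g_ab, g_ac, g_bc = branch_conductances(
                            a.diameter, b.diameter, c.diameter, params)
                        couple(ends[a.id], ends[b.id], g_ab)
                        couple(ends[a.id], ends[c.id], g_ac)
                        couple(ends[b.id], ends[c.id], g_bc)
    # root boundary: upstream end of the root vessel clamped toward rest
    root = tree.root_vessel
    n_root, *_ = discretize_vessel(root.diameter, params.l_c, params)
    leak[first_unit[root.id]] += root_conductance(n_root, params)
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(total, total))
    matrix = lap + sp.diags(leak)
    return ElectricalNetwork(params=params, n_units=total, unit_leak=leak,
                             matrix=matrix.tocsr(), first_unit=first_unit,
                             n_vessel_units=n_units_of)


def steady_state_voltages(network: ElectricalNetwork, injections) -> np.ndarray:
    """Absolute membrane potentials (mV) at quasi-static balance."""
    u = network.solve(injections)
    return network.params.v_rest + u


def coupling_strength(tree_or_network, source_aa: int, target_aa: int,
                      params: ElectricalParams = ElectricalParams()) -> float:
    """Voltage-transfer coefficient from one arteriole tip to another.

    Unit test current is injected at the most distal unit of the source
    arteriole (the macula-densa contact end); the returned ratio
    (V_target - V_rest)/(V_source - V_rest) is independent of the injected
    amplitude by linearity.
    """
    net = (tree_or_network if isinstance(tree_or_network, ElectricalNetwork)
           else build_network(tree_or_network, params))
    if source_aa == target_aa:
        return 1.0
    inj = np.zeros(net.n_units)
    inj[net.distal_unit(source_aa)] = 1.0
    u = net.solve(inj)
    return float(u[net.distal_unit(target_aa)] / u[net.distal_unit(source_aa)])


def coupling_matrix(tree: VascularTree,
                    params: ElectricalParams = ElectricalParams()):
    """K[m, n]: transfer coefficient from source arteriole n to target m.

    One factorization, one solve per source. Returns (K, arteriole vessel
    ids in row/column order). The diagonal is 1; off-diagonal entries lie in
    (0, 1) and need not be symmetric (the branch geometry is anisotropic).
    """
    net = build_network(tree, params)
    aas = tree.arterioles()
    if not aas:
        raise ValueError("tree has no arterioles")
    ids = [v.id for v in aas]
    tips = np.array([net.distal_unit(i) for i in ids])
    k = np.empty((len(ids), len(ids)))
    for col, tip in enumerate(tips):
        inj = np.zeros(net.n_units)
        inj[tip] = 1.0
        u = net.solve(inj)
        k[:, col] = u[tips] / u[tip]
        k[col, col] = 1.0
    return k, ids
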
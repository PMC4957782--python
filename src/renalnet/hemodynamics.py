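"""Poiseuille pressure network on a vascular tree.

Each artery is a pure hydraulic resistance; pressure states live on the
junction nodes, with a single lumped compliance per node. Blood viscosity
follows the diameter-dependent in-vivo law for a fixed hematocrit of 0.45,
so narrow vessels are markedly more resistive than plain Poiseuille flow
with bulk viscosity would predict.

Afferent arterioles are excluded from the resistive network: their
resistance is the actively controlled R_a of the nephron model, and each
nephron appears here only as an outflow F_neph at the node its arteriole
originates from.

Units: pressures kPa, flows nL/s, resistances kPa*s/nL, diameters and
lengths um, viscosity cP. With these units R = 128*eta*L/(pi*D^4) needs no
additional conversion factor (1 kPa*s/nL = 1e15 Pa*s/m^3 absorbs the SI
powers exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .tree import VascularTree

__all__ = [
    "HemodynamicsError",
    "blood_viscosity",
    "vessel_resistance",
    "nephron_inflow",
    "HemodynamicNetwork",
    "pressure_derivatives",
    "steady_state_pressures",
]

#: Table-value compliance of blood vessels, nL/kPa (stable over 0.3-5)
C_HDR_DEFAULT = 3.0
_C_HDR_RANGE = (0.3, 5.0)


class HemodynamicsError(ValueError):
    pass


def blood_viscosity(diam):
    """In-vivo relative blood viscosity (cP) at hematocrit 0.45.

    eta = [1 + 6 e^(-0.085 D) + 2.2 - 2.44 e^(-0.06 D^0.645)] * (D/(D-1.12))^2
    with D in um; tends to 3.2 cP for wide vessels.
    """
    d = np.asarray(diam, dtype=float)
    if np.any(d <= 1.12):
        raise HemodynamicsError("viscosity law requires D > 1.12 um")
    eta45 = 1.0 + 6.0 * np.exp(-0.085 * d) + 2.2 - 2.44 * np.exp(-0.06 * d ** 0.645)
    out = eta45 * (d / (d - 1.12)) ** 2
    return out if out.ndim else float(out)


def vessel_resistance(diam, length):
    """Poiseuille resistance (kPa*s/nL) of a cylindrical vessel."""
    d = np.asarray(diam, dtype=float)
    l = np.asarray(length, dtype=float)
    if np.any(d <= 0) or np.any(l <= 0):
        raise HemodynamicsError("diameter and length must be > 0")
    out = 128.0 * blood_viscosity(d) * l / (np.pi * d ** 4)
    return out if out.ndim else float(out)


def nephron_inflow(p_node, p_g, r_a):
    """Afferent flow (nL/s): feed-node pressure minus glomerular capillary
    pressure over the arteriolar resistance. May be negative when the feed
    pressure cannot sustain filtration (reversed gradient)."""
    if np.any(np.asarray(r_a) <= 0):
        raise HemodynamicsError("R_a must be > 0")
    return (np.asarray(p_node, float) - p_g) / r_a


@dataclass
class HemodynamicNetwork:
    """Precompiled arrays for the nodal pressure balance on one tree.

    Free nodes are every junction except the root inlet (node 0), whose
    pressure is the boundary condition. Arteriole-origin nodes additionally
    receive the per-nephron outflows.
    """

    tree: VascularTree
    c_hdr: float
    # per (non-arteriole) vessel:
    v_parent: np.ndarray     # free-node index of upstream node (-1 = root inlet)
    v_child: np.ndarray      # free-node index of downstream node
    conductance: np.ndarray  # 1/R, nL/(kPa*s)
    resistance: np.ndarray
    # nephron bookkeeping
    aa_vessel_ids: np.ndarray
    aa_node_index: np.ndarray  # free-node index each arteriole hangs off
    n_free: int
    node_of_free: np.ndarray   # free index -> original node id

    @classmethod
    def from_tree(cls, tree: VascularTree, c_hdr: float = C_HDR_DEFAULT):
        if not (_C_HDR_RANGE[0] <= c_hdr <= _C_HDR_RANGE[1]):
            raise HemodynamicsError(
                f"C_hdr={c_hdr} outside the stable range {_C_HDR_RANGE} nL/kPa")
        arteries = tree.arteries()
        root_inlet = tree.root_vessel.parent_node
        free_nodes = sorted({v.child_node for v in arteries})
        if root_inlet in free_nodes:
            raise HemodynamicsError("root inlet cannot be a vessel endpoint")
        index = {n: i for i, n in enumerate(free_nodes)}
        v_parent = np.array([index.get(v.parent_node, -1) for v in arteries])
        v_child = np.array([index[v.child_node] for v in arteries])
        res = np.array([vessel_resistance(v.diameter, v.length) for v in arteries])
        aas = tree.arterioles()
        missing = [v.id for v in aas if v.parent_node not in index]
        if missing:
            raise HemodynamicsError(
                f"arterioles {missing} attach to nodes outside the artery network")
        return cls(tree=tree, c_hdr=float(c_hdr), v_parent=v_parent,
                   v_child=v_child, conductance=1.0 / res, resistance=res,
                   aa_vessel_ids=np.array([v.id for v in aas]),
                   aa_node_index=np.array([index[v.parent_node] for v in aas]),
                   n_free=len(free_nodes),
                   node_of_free=np.array(free_nodes))

    # -- dynamics ----------------------------------------------------------

    def flows(self, pressures, p_root):
        """Per-artery flow (nL/s), positive downstream."""
        p_up = np.where(self.v_parent >= 0, pressures[self.v_parent], p_root)
        return (p_up - pressures[self.v_child]) * self.conductance

    def derivatives(self, pressures, p_root, nephron_outflows):
        """dP/dt (kPa/s) on the free nodes from conservation of flow."""
        f = self.flows(pressures, p_root)
        dp = np.zeros(self.n_free)
        np.add.at(dp, self.v_child, f)
        mask = self.v_parent >= 0
        np.subtract.at(dp, self.v_parent[mask], f[mask])
        if nephron_outflows is not None:
            np.subtract.at(dp, self.aa_node_index, nephron_outflows)
        return dp / self.c_hdr

    # -- steady state ------------------------------------------------------

    def laplacian(self):
        n = self.n_free
        rows, cols, vals = [], [], []
        for (i, j, g) in zip(self.v_parent, self.v_child, self.conductance):
            rows.append(j); cols.append(j); vals.append(g)
            if i >= 0:
                rows.append(i); cols.append(i); vals.append(g)
                rows.append(i); cols.append(j); vals.append(-g)
                rows.append(j); cols.append(i); vals.append(-g)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def steady_state(self, p_root, nephron_outflows=None):
        """Nodal pressures solving the linear resistor network with fixed
        root pressure and prescribed nephron outflows."""
        b = np.zeros(self.n_free)
        root_children = self.v_parent < 0
        np.add.at(b, self.v_child[root_children],
                  p_root * self.conductance[root_children])
        if nephron_outflows is not None:
            np.subtract.at(b, self.aa_node_index,
                           np.asarray(nephron_outflows, float))
        return spla.spsolve(self.laplacian().tocsc(), b)


def pressure_derivatives(pressures, network: HemodynamicNetwork, p_root,
                         nephron_outflows=None):
    """Functional wrapper over :meth:`HemodynamicNetwork.derivatives`."""
    return network.derivatives(np.asarray(pressures, float), p_root,
                               nephron_outflows)


def steady_state_pressures(tree: VascularTree, p_root,
                           nephron_outflows=None, c_hdr: float = C_HDR_DEFAULT):
    """Steady nodal pressures of a tree; returns (node_ids, pressures)."""
    net = HemodynamicNetwork.from_tree(tree, c_hdr)
    p = net.steady_state(p_root, nephron_outflows)
    return net.node_of_free, p
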
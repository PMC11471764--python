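"""Gaussian and anisotropic elastic networks on a C-alpha trace.

The protein is a bead-spring network: consecutive residues are joined by
stiff backbone springs (spring constant c*kappa), and any residue pair
closer than the cutoff r_c in the native structure by a weaker spring
(kappa).  The topology lives in the Kirchhoff (connectivity) matrix Gamma:

    Gamma_ij = -c   if |i-j| = 1
    Gamma_ij = -1   if |i-j| > 1 and r_ij < r_c   (intact contact)
    Gamma_ij =  0   otherwise
    Gamma_ii = -sum_{j != i} Gamma_ij             (zero row sums)

Thermal fluctuations follow from the pseudoinverse of Gamma
(<dRi.dRj> = 3 kBT/kappa [Gamma^+]_ij); directional normal modes from the
anisotropic Hessian H_ij = kappa Gamma_ij n_ij n_ij^T built on the native
bond unit vectors n_ij.  Gamma is mutated in place as bonds break during
unfolding; backbone springs never break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats

from .structure_io import CalphaStructure, ContactSet, contact_list

__all__ = [
    "ElasticNetwork",
    "ModeSet",
    "UnbalancedForceError",
    "build_gamma",
    "build_network",
    "pseudo_inverse",
    "pair_fluctuations",
    "force_displacements",
    "anm_hessian",
    "floppy_modes",
    "fit_bfactors",
    "connected_components",
]

#: Relative eigenvalue cutoff below which Gamma modes are treated as null
#: space when pseudoinverting.
PINV_RTOL = 1e-10

#: Absolute Hessian eigenvalue below which a mode counts as floppy.
FLOPPY_THRESHOLD = 1e-4


class UnbalancedForceError(ValueError):
    """Net force on a connected fragment is nonzero: no static solution."""


@dataclass
class ElasticNetwork:
    """Mutable elastic-network state for one protein.

    ``contacts`` holds the currently intact non-covalent pairs; ``broken``
    the ordered list of pairs removed so far.  Pairs are 1-based (i, j),
    i < j.  ``gamma`` is kept consistent with the bond sets at all times.
    """

    gamma: np.ndarray
    kappa: float
    c: float
    r_c: float
    backbone: frozenset
    contacts: set
    coords0: np.ndarray | None = None
    broken: list = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return int(self.gamma.shape[0])

    @property
    def n_bonds(self) -> int:
        return len(self.backbone) + len(self.contacts)

    @property
    def mean_coordination(self) -> float:
        """Average number of bonded neighbours per residue, <z> = 2 bonds / N."""
        return 2.0 * self.n_bonds / self.n_residues

    def break_bond(self, pair: tuple[int, int]) -> None:
        """Remove one non-covalent contact and update Gamma in place.

        Gamma_ij -> Gamma_ij + 1, Gamma_ii -> Gamma_ii - 1,
        Gamma_jj -> Gamma_jj - 1 (and symmetrically), so row sums stay 0.
        """
        i, j = int(pair[0]), int(pair[1])
        if (i, j) not in self.contacts:
            raise KeyError(f"({i}, {j}) is not an intact non-covalent contact")
        a, b = i - 1, j - 1
        self.gamma[a, b] += 1.0
        self.gamma[b, a] += 1.0
        self.gamma[a, a] -= 1.0
        self.gamma[b, b] -= 1.0
        self.contacts.discard((i, j))
        self.broken.append((i, j))

    def copy(self) -> "ElasticNetwork":
        return ElasticNetwork(
            gamma=self.gamma.copy(),
            kappa=self.kappa,
            c=self.c,
            r_c=self.r_c,
            backbone=self.backbone,
            contacts=set(self.contacts),
            coords0=None if self.coords0 is None else self.coords0.copy(),
            broken=list(self.broken),
        )

    def adjacency(self) -> scipy.sparse.coo_matrix:
        """0/1 adjacency of the current bond graph (backbone + contacts)."""
        pairs = list(self.backbone) + list(self.contacts)
        n = self.n_residues
        if not pairs:
            return scipy.sparse.coo_matrix((n, n))
        rows = [p[0] - 1 for p in pairs] + [p[1] - 1 for p in pairs]
        cols = [p[1] - 1 for p in pairs] + [p[0] - 1 for p in pairs]
        return scipy.sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )


@dataclass
class ModeSet:
    """Eigendecomposition of the anisotropic Hessian, sorted ascending.

    ``floppy_count`` is the number of modes with eigenvalue below the
    absolute threshold (six of them are always the rigid-body translations
    and rotations of a connected 3-D structure); ``floppy_fraction`` is
    that count divided by 3N.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, aligned with eigenvalues
    floppy_threshold: float = FLOPPY_THRESHOLD

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.size)

    @property
    def floppy_count(self) -> int:
        return int(np.count_nonzero(self.eigenvalues < self.floppy_threshold))

    @property
    def floppy_fraction(self) -> float:
        return self.floppy_count / self.n_modes

    def floppy_vectors(self) -> np.ndarray:
        """(3N, f_abs) matrix of floppy eigenvectors."""
        return self.eigenvectors[:, self.eigenvalues < self.floppy_threshold]


def build_gamma(
    contacts: ContactSet,
    c: float,
    n_residues: int,
    *,
    kappa: float = 1.0,
    r_c: float = 7.0,
    coords0: np.ndarray | None = None,
) -> ElasticNetwork:
    """Assemble the Kirchhoff matrix from a contact partition."""
    if c <= 0:
        raise ValueError("backbone stiffness ratio c must be positive")
    gamma = np.zeros((n_residues, n_residues))
    for (i, j) in contacts.backbone:
        gamma[i - 1, j - 1] = gamma[j - 1, i - 1] = -c
    for (i, j) in contacts.noncovalent:
        gamma[i - 1, j - 1] = gamma[j - 1, i - 1] = -1.0
    np.fill_diagonal(gamma, 0.0)
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    return ElasticNetwork(
        gamma=gamma,
        kappa=float(kappa),
        c=float(c),
        r_c=float(r_c),
        backbone=frozenset(contacts.backbone),
        contacts=set(contacts.noncovalent),
        coords0=None if coords0 is None else np.asarray(coords0, dtype=float),
    )


def build_network(
    s: CalphaStructure, *, c: float, kappa: float, r_c: float = 7.0
) -> ElasticNetwork:
    """Convenience: contact list at r_c plus Kirchhoff assembly."""
    contacts = contact_list(s, r_c)
    return build_gamma(
        contacts, c, s.n_residues, kappa=kappa, r_c=r_c, coords0=s.coords
    )


def pseudo_inverse(matrix: np.ndarray, rtol: float = PINV_RTOL) -> np.ndarray:
    """Moore-Penrose pseudoinverse of a symmetric PSD matrix.

    Eigenvalues below rtol * lambda_max are treated as exact zeros (the
    Kirchhoff matrix always has at least one zero mode, more after the
    network fragments).
    """
    w, v = np.linalg.eigh(matrix)
    cut = rtol * max(w.max(), 0.0) if w.size else 0.0
    inv = np.where(w > cut, 1.0 / np.where(w > cut, w, 1.0), 0.0)
    return (v * inv) @ v.T


def pair_fluctuations(net: ElasticNetwork, kBT: float = 1.0) -> np.ndarray:
    """Mean-square fluctuation of every inter-residue distance vector.

    Returns the full symmetric N x N matrix
    (3 kBT / kappa) * (G+_ii + G+_jj - 2 G+_ij); only entries for currently
    bonded pairs are meaningful to the unfolding engine.
    """
    gplus = pseudo_inverse(net.gamma)
    d = np.diag(gplus)
    return (3.0 * kBT / net.kappa) * (d[:, None] + d[None, :] - 2.0 * gplus)


def connected_components(net: ElasticNetwork) -> np.ndarray:
    """Component label per residue for the current bond graph."""
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        net.adjacency(), directed=False
    )
    return labels


def force_displacements(
    net: ElasticNetwork, forces: np.ndarray, *, balance_tol: float = 1e-8
) -> np.ndarray:
    """Static displacements under an external force field (Hooke's law).

    Solves kappa * Gamma u = F independently for each Cartesian component
    via the pseudoinverse, so per connected component the mean displacement
    is zero.  The net force on every connected component must vanish
    (componentwise); otherwise there is no static solution and an
    UnbalancedForceError is raised.
    """
    forces = np.asarray(forces, dtype=float)
    n = net.n_residues
    if forces.shape != (n, 3):
        raise ValueError(f"forces must have shape ({n}, 3)")
    labels = connected_components(net)
    scale = max(np.abs(forces).max(), 1.0)
    for comp in np.unique(labels):
        net_force = forces[labels == comp].sum(axis=0)
        if np.abs(net_force).max() > balance_tol * scale:
            raise UnbalancedForceError(
                f"unbalanced force on fragment {comp}: net force {net_force}"
            )
    gplus = pseudo_inverse(net.gamma)
    return (gplus @ forces) / net.kappa


def anm_hessian(net: ElasticNetwork) -> np.ndarray:
    """3N x 3N anisotropic Hessian on the *current* topology, native geometry.

    Off-diagonal blocks are kappa * Gamma_ij * n_ij n_ij^T with n_ij the
    native bond direction; diagonal blocks enforce zero net block-row sum.
    Broken bonds are absent because Gamma is current.
    """
    if net.coords0 is None:
        raise ValueError("native coordinates required to build the Hessian")
    n = net.n_residues
    coords = net.coords0
    hess = np.zeros((3 * n, 3 * n))
    pairs = list(net.backbone) + list(net.contacts)
    for (i, j) in pairs:
        a, b = i - 1, j - 1
        rij = coords[b] - coords[a]
        dist = np.linalg.norm(rij)
        if dist < 1e-9:
            raise ValueError(f"coincident residues in bonded pair ({i}, {j})")
        nij = rij / dist
        block = net.kappa * net.gamma[a, b] * np.outer(nij, nij)
        hess[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] = block
        hess[3 * b : 3 * b + 3, 3 * a : 3 * a + 3] = block
        hess[3 * a : 3 * a + 3, 3 * a : 3 * a + 3] -= block
        hess[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] -= block
    return hess


def floppy_modes(
    hess: np.ndarray, threshold: float = FLOPPY_THRESHOLD
) -> ModeSet:
    """Full eigendecomposition of the Hessian with floppy-mode bookkeeping."""
    w, v = np.linalg.eigh(hess)
    return ModeSet(eigenvalues=w, eigenvectors=v, floppy_threshold=threshold)


def floppy_count(
    hess: np.ndarray, threshold: float = FLOPPY_THRESHOLD
) -> int:
    """Number of floppy modes only (cheaper: eigenvalues without vectors)."""
    w = scipy.linalg.eigvalsh(hess)
    return int(np.count_nonzero(w < threshold))


def predicted_bfactors(net: ElasticNetwork, kBT: float = 1.0) -> np.ndarray:
    """Isotropic B-factor prediction B_i = (8 pi^2 / 3) <dR_i^2>."""
    gplus = pseudo_inverse(net.gamma)
    msf = (3.0 * kBT / net.kappa) * np.diag(gplus)
    return (8.0 * np.pi**2 / 3.0) * msf


def fit_bfactors(
    s: CalphaStructure,
    *,
    r_c: float = 7.0,
    c_grid: np.ndarray | None = None,
    kBT: float = 1.0,
) -> tuple[float, float, float]:
    """Fit (c, kappa) to the experimental B-factors.

    For each candidate backbone stiffness ratio c on the grid, the
    kappa-independent shape Gamma^+(c)_ii is correlated with the
    experimental B-factors; kappa then follows from a closed-form
    least-squares scale match of B_i = (8 pi^2 / 3)(3 kBT / kappa) G+_ii.
    Returns (c, kappa, pearson_r) at the best correlation.
    """
    b_exp = np.asarray(s.b_factors, dtype=float)
    if np.ptp(b_exp) < 1e-12:
        raise ValueError("experimental B-factors are constant; correlation undefined")
    if c_grid is None:
        c_grid = np.arange(1.0, 20.0 + 1e-9, 0.1)
    contacts = contact_list(s, r_c)
    best = None
    for c in c_grid:
        net = build_gamma(contacts, float(c), s.n_residues, r_c=r_c)
        diag = np.diag(pseudo_inverse(net.gamma))
        r = scipy.stats.pearsonr(diag, b_exp).statistic
        if best is None or r > best[2]:
            # scale alpha/kappa minimizing sum (B - (alpha/kappa) d)^2
            alpha = 8.0 * np.pi**2 * kBT
            kappa = alpha * float(diag @ diag) / float(diag @ b_exp)
            best = (float(c), float(kappa), float(r))
    return best
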
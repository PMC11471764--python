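"""Per-residue shear energy from soft-mode displacement fields.

For a displacement field applied to the native C-alpha positions, the
local deformation around residue m is estimated by the weighted discrete
deformation gradient

    F_m = A_m D_m^{-1},
    A_m = sum_n dx'_mn dx_mn^T w_mn,   D_m = sum_n dx_mn dx_mn^T w_mn,

with dx_mn the native and dx'_mn the displaced relative positions of the
neighbours n, and a radial weight that is 1 inside 6 A, ramps linearly to
0 between 6 and 8 A, and vanishes beyond.  The Eulerian strain
eps = 1/2 [I - (F F^T)^{-1}] is zero for any rigid motion; its deviatoric
(traceless) part gamma = eps - 1/3 tr(eps) I measures pure shape change,
and s_m = sum_ij gamma_ij^2 is the shear energy at residue m.

The shear field of a network state sums s_m over the soft modes of the
anisotropic Hessian (eigenvalue below the floppy threshold), each applied
as a small displacement of fixed amplitude.  High-shear residues mark the
floppy, unfolding-prone regions of the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .network import ElasticNetwork, ModeSet, anm_hessian, floppy_modes

__all__ = [
    "ShearField",
    "weight",
    "neighbour_weights",
    "deformation_gradient",
    "strain_tensors",
    "shear_energy",
    "softmode_shear_field",
    "shear_order_correlation",
]

#: Ridge added to a (near-)singular neighbourhood matrix D_m, relative to
#: trace(D_m)/3; terminal residues with sparse neighbourhoods are the risk.
RIDGE = 1e-8

#: Shear values below this are treated as zero when taking logarithms.
LOG_FLOOR = 1e-300


@dataclass
class ShearField:
    """Per-residue total shear energy for one network state."""

    s: np.ndarray
    q_label: float
    modes_used: int
    amplitude: float = 1.0
    fallback_lowest_nonzero: bool = False
    flagged_residues: list = field(default_factory=list)


def weight(r) -> np.ndarray:
    """Radial neighbourhood weight: 1 below 6 A, linear ramp to 0 at 8 A."""
    r = np.asarray(r, dtype=float)
    w = np.clip(1.0 - 0.5 * (r - 6.0), 0.0, 1.0)
    return w if w.ndim else float(w)


def neighbour_weights(coords0: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and weights of the residues in m's native neighbourhood.

    ``m`` is a 0-based residue index; residues with zero weight (beyond
    8 A) are dropped.
    """
    d = np.linalg.norm(coords0 - coords0[m], axis=1)
    w = weight(d)
    w[m] = 0.0
    idx = np.flatnonzero(w > 0.0)
    return idx, w[idx]


def deformation_gradient(
    coords0: np.ndarray,
    coords1: np.ndarray,
    m: int,
    weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, bool]:
    """Discrete deformation gradient F_m = A_m D_m^{-1} at residue m (0-based).

    Returns (F, regularized): ``regularized`` is True when the
    neighbourhood matrix D_m was (near-)singular (coplanar or collinear
    neighbours) and a small ridge was added.
    """
    coords0 = np.asarray(coords0, dtype=float)
    coords1 = np.asarray(coords1, dtype=float)
    if weights is None:
        idx, w = neighbour_weights(coords0, m)
    else:
        idx, w = weights
    if idx.size < 3:
        raise ValueError(
            f"residue {m + 1} has fewer than 3 weighted neighbours"
        )
    dx = coords0[idx] - coords0[m]
    dxp = coords1[idx] - coords1[m]
    d_m = (dx * w[:, None]).T @ dx
    a_m = (dxp * w[:, None]).T @ dx
    regularized = False
    cond = np.linalg.cond(d_m)
    if not np.isfinite(cond) or cond > 1e12:
        d_m = d_m + RIDGE * (np.trace(d_m) / 3.0) * np.eye(3)
        regularized = True
    f_m = a_m @ np.linalg.inv(d_m)
    return f_m, regularized


def strain_tensors(f_m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eulerian strain and its deviatoric (shear) part for one F_m."""
    b = f_m @ f_m.T
    if abs(np.linalg.det(b)) < 1e-300:
        raise ValueError("singular deformation gradient")
    eps = 0.5 * (np.eye(3) - np.linalg.inv(b))
    gam = eps - (np.trace(eps) / 3.0) * np.eye(3)
    return eps, gam


def shear_energy(f_m: np.ndarray) -> float:
    """Shear energy s = sum_ij gamma_ij^2 of one deformation gradient."""
    _, gam = strain_tensors(f_m)
    return float(np.sum(gam * gam))


def softmode_shear_field(
    net: ElasticNetwork,
    modeset: ModeSet | None = None,
    *,
    amplitude: float = 1.0,
    q_label: float = 1.0,
    fallback_k: int = 20,
) -> ShearField:
    """Total per-residue shear over the soft modes of the current network.

    Each soft eigenvector (unit-norm over 3N components) is applied as a
    displacement of the native coordinates at the given amplitude (A) and
    the resulting shear energies are accumulated residue-wise.

    If the soft set holds nothing beyond the six rigid-body modes (whose
    shear vanishes identically), the field would be numerically zero; in
    that case the lowest ``fallback_k`` non-floppy modes are used instead
    and the field is flagged (``fallback_lowest_nonzero``).
    """
    if net.coords0 is None:
        raise ValueError("native coordinates required for shear analysis")
    if modeset is None:
        modeset = floppy_modes(anm_hessian(net))
    coords0 = net.coords0
    n = net.n_residues

    soft = modeset.floppy_vectors()
    fallback = False
    if soft.shape[1] <= 6:
        # Only rigid-body motion is soft: strain-free by construction.
        order = np.argsort(modeset.eigenvalues)
        nonzero = [
            k for k in order
            if modeset.eigenvalues[k] >= modeset.floppy_threshold
        ][:fallback_k]
        if not nonzero:
            return ShearField(
                s=np.zeros(n), q_label=q_label, modes_used=0,
                amplitude=amplitude, fallback_lowest_nonzero=False,
            )
        soft = modeset.eigenvectors[:, nonzero]
        fallback = True

    neighbourhoods = [neighbour_weights(coords0, m) for m in range(n)]
    s_total = np.zeros(n)
    flagged: set[int] = set()
    for k in range(soft.shape[1]):
        disp = soft[:, k].reshape(n, 3) * amplitude
        coords1 = coords0 + disp
        for m in range(n):
            f_m, reg = deformation_gradient(
                coords0, coords1, m, weights=neighbourhoods[m]
            )
            if reg:
                flagged.add(m + 1)
            s_total[m] += shear_energy(f_m)
    return ShearField(
        s=s_total,
        q_label=q_label,
        modes_used=int(soft.shape[1]),
        amplitude=amplitude,
        fallback_lowest_nonzero=fallback,
        flagged_residues=sorted(flagged),
    )


def shear_order_correlation(
    native_shear: ShearField | np.ndarray,
    orders: np.ndarray,
) -> tuple[float, int, int]:
    """Pearson r between log(native shear) and mean bond-breaking order.

    Residues with undefined order (no broken bonds) or effectively zero
    shear are excluded.  Returns (r, n_used, n_excluded); fewer than 3
    usable residues is an error.
    """
    s = native_shear.s if isinstance(native_shear, ShearField) else np.asarray(native_shear)
    orders = np.asarray(orders, dtype=float)
    if s.shape != orders.shape:
        raise ValueError("shear field and order vector must be aligned")
    valid = np.isfinite(orders) & (s > LOG_FLOOR)
    n_used = int(valid.sum())
    n_excluded = int(s.size - n_used)
    if n_used < 3:
        raise ValueError(
            f"only {n_used} residues with defined order and nonzero shear"
        )
    r = scipy.stats.pearsonr(np.log(s[valid]), orders[valid]).statistic
    return float(r), n_used, n_excluded


def plot_shear_heatmap(fields: list[ShearField], path, residue_ids=None) -> None:
    """Residue-vs-Q heat map of log shear across unfolding snapshots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.log10(np.maximum(np.stack([f.s for f in fields]), LOG_FLOOR))
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(mat, aspect="auto", origin="upper", cmap="coolwarm")
    ax.set_yticks(range(len(fields)))
    ax.set_yticklabels([f"Q={f.q_label:.2f}" for f in fields])
    ax.set_xlabel("residue")
    fig.colorbar(im, ax=ax, label="log10 shear")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
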
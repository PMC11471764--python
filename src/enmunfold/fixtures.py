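"""Synthetic bead-spring structures with analytically known rigidity.

Every generator returns a CalphaStructure with 3.8 A backbone spacing (the
C-alpha virtual bond length), so the whole pipeline can be exercised and
tested without downloading real structures.  The rigidity bookkeeping of
the fixtures is known exactly:

* ``triangle-cluster``: an equilateral triangle (N=3) or a
  Boerdijk-Coxeter tetrahelix (N>3).  With a cutoff that captures exactly
  the tetrahedral edges (r_c ~ 5 A) the network is isostatic, 3N-6 bonds,
  and has exactly the 6 rigid-body floppy modes.
* ``hinge``: two rigid clusters sharing one edge; 3N-7 independent bonds,
  hence exactly 7 floppy modes (6 rigid-body + 1 hinge rotation).
* ``chain``: straight chain, backbone springs only, no contacts; a generic
  open chain has 2N+1 floppy modes (3N minus N-1 constraints).
* ``helix``: alpha-helix-like spiral with i,i+3 and i,i+4 contacts.
* ``lattice-fold``: a compact serpentine walk on a jittered cubic lattice,
  rich in non-covalent contacts; the stand-in for a small folded protein.

``make_family`` derives structural variants of a template by displacing a
controlled fraction of residues, emulating a protein family whose members
share a fold but differ in detail: the larger the rewiring rate, the lower
the expected pairwise TM-score and the more divergent the unfolding
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import CalphaStructure

__all__ = ["ToySpec", "make_toy", "make_family", "suggested_cutoff"]

#: C-alpha virtual bond length in Angstrom.
DEFAULT_SPACING = 3.8

KINDS = ("chain", "helix", "triangle-cluster", "hinge", "lattice-fold")


@dataclass
class ToySpec:
    """Recipe for one synthetic structure; generation is deterministic
    given (spec, seed)."""

    kind: str
    n: int
    spacing: float = DEFAULT_SPACING
    seed: int = 0
    jitter: float | None = None  # None -> kind-specific default
    params: dict = field(default_factory=dict)


def suggested_cutoff(kind: str) -> float:
    """Contact cutoff under which the fixture's rigidity count is exact.

    The tetrahelix and hinge need r_c between the bonded edge length
    (3.8 A) and the first non-bonded distance (~6.2 A); 5 A sits safely in
    that window.  The other kinds use the standard 7 A protein cutoff.
    """
    return 5.0 if kind in ("triangle-cluster", "hinge") else 7.0


def _tetrahelix(n: int, a: float) -> np.ndarray:
    """Boerdijk-Coxeter helix of face-sharing tetrahedra, edge length a.

    Consecutive beads and the (i, i+2), (i, i+3) pairs are all at distance
    a; the next-nearest distance is ~1.63 a, so an r_c between those gives
    exactly 3N-6 bonds: an isostatic, generically rigid cluster.
    """
    radius = 3.0 * np.sqrt(3.0) / 10.0 * a
    theta = np.arccos(-2.0 / 3.0)
    rise = a / np.sqrt(10.0)
    k = np.arange(n)
    return np.column_stack(
        [radius * np.cos(k * theta), radius * np.sin(k * theta), k * rise]
    )


def _rotation_from_to(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit(v_from) to unit(v_to)."""
    u = v_from / np.linalg.norm(v_from)
    w = v_to / np.linalg.norm(v_to)
    axis = np.cross(u, w)
    s = np.linalg.norm(axis)
    c = float(u @ w)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # Antiparallel: rotate pi about any perpendicular axis.
        perp = np.eye(3)[np.argmin(np.abs(u))]
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    return _axis_angle(axis / s, np.arctan2(s, c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    kx, ky, kz = axis
    k_cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * k_cross + (1 - np.cos(angle)) * k_cross @ k_cross


def _hinge(n: int, a: float) -> np.ndarray:
    """Two rigid tetrahelix arms sharing one edge (the hinge axis)."""
    if n == 4:
        # Butterfly: two equilateral triangles sharing edge 2-3.
        h = a * np.sqrt(3.0) / 2.0
        return np.array(
            [[a / 2.0, h, 0.0], [0.0, 0.0, 0.0], [a, 0.0, 0.0], [a / 2.0, -h, 0.0]]
        )
    m = n // 2 + 1
    arm1 = _tetrahelix(m, a)
    q = n - m + 2
    arm2 = _tetrahelix(q, a)
    # Map arm2's first edge onto arm1's last edge, arm pointing away.
    p, qpt = arm1[m - 2], arm1[m - 1]
    rot = _rotation_from_to(arm2[1] - arm2[0], qpt - p)
    arm2 = (arm2 - arm2[0]) @ rot.T + p
    # Spin arm2 about the shared edge to maximize arm separation.
    axis = (qpt - p) / np.linalg.norm(qpt - p)
    best, best_sep = arm2, -np.inf
    for phi in np.linspace(0.0, 2 * np.pi, 36, endpoint=False):
        spun = (arm2 - p) @ _axis_angle(axis, phi).T + p
        sep = np.min(
            np.linalg.norm(
                spun[2:, None, :] - arm1[None, : m - 2, :], axis=-1
            )
        ) if m > 2 else np.inf
        if sep > best_sep:
            best, best_sep = spun, sep
    return np.vstack([arm1, best[2:]])


def _lattice_fold(n: int, a: float) -> np.ndarray:
    """Serpentine walk on a cubic lattice with spacing a (compact fold)."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    coords = []
    for z in range(side):
        for yy in range(side):
            y = yy if z % 2 == 0 else side - 1 - yy
            xs = range(side) if (yy + z) % 2 == 0 else range(side - 1, -1, -1)
            for x in xs:
                coords.append((x, y, z))
                if len(coords) == n:
                    return np.array(coords, dtype=float) * a
    return np.array(coords[:n], dtype=float) * a


def _helix(n: int, a: float, radius: float = 2.3, rise: float = 1.5) -> np.ndarray:
    """Alpha-helix-like spiral; turn angle set by spacing, radius and rise."""
    chord = np.sqrt(max(a**2 - rise**2, 1e-9))
    theta = 2.0 * np.arcsin(min(chord / (2.0 * radius), 1.0))
    k = np.arange(n)
    return np.column_stack(
        [radius * np.cos(k * theta), radius * np.sin(k * theta), k * rise]
    )


#: Default coordinate jitter (A) per kind; breaks lattice/helix symmetry so
#: placements are generic, while staying far below the contact margins.
_DEFAULT_JITTER = {
    "chain": 0.0,
    "helix": 0.0,
    "triangle-cluster": 0.0,
    "hinge": 0.03,
    "lattice-fold": 0.08,
}


def _ss_labels(kind: str, n: int) -> list[str]:
    if kind == "helix":
        return ["alpha"] * n
    if kind == "lattice-fold":
        thirds = np.minimum(np.arange(n) * 3 // n, 2) + 1
        return [f"s{t}" for t in thirds]
    if kind == "hinge":
        m = n // 2 + 1 if n > 4 else 2
        return ["armA"] * m + ["armB"] * (n - m)
    return ["loop"] * n


def make_toy(spec: ToySpec) -> CalphaStructure:
    """Build one synthetic C-alpha structure from a spec, deterministically."""
    if spec.n < 3:
        raise ValueError("need at least 3 residues")
    if spec.kind not in KINDS:
        raise ValueError(f"unknown toy kind {spec.kind!r}; choose from {KINDS}")
    a = spec.spacing
    n = spec.n
    if spec.kind == "chain":
        coords = np.column_stack([np.arange(n) * a, np.zeros(n), np.zeros(n)])
    elif spec.kind == "helix":
        coords = _helix(n, a, **{k: spec.params[k] for k in ("radius", "rise")
                                 if k in spec.params})
    elif spec.kind == "triangle-cluster":
        if n == 3:
            coords = np.array(
                [[0.0, 0.0, 0.0], [a, 0.0, 0.0], [a / 2.0, a * np.sqrt(3) / 2, 0.0]]
            )
        else:
            coords = _tetrahelix(n, a)
    elif spec.kind == "hinge":
        if n < 4:
            raise ValueError("hinge needs at least 4 residues")
        coords = _hinge(n, a)
    else:  # lattice-fold
        coords = _lattice_fold(n, a)

    jitter = _DEFAULT_JITTER[spec.kind] if spec.jitter is None else spec.jitter
    if jitter > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    b_factors = np.round(np.linspace(10.0, 20.0, n), 2)
    return CalphaStructure(
        residue_ids=np.arange(1, n + 1),
        coords=coords,
        b_factors=b_factors,
        chain_id="A",
        ss_labels=_ss_labels(spec.kind, n),
    )


def make_family(
    template: CalphaStructure,
    n_variants: int,
    rewiring_rate: float,
    seed: int = 0,
    *,
    sigma: float = 1.5,
) -> list[CalphaStructure]:
    """Structural variants of a template with controlled contact rewiring.

    A fraction ``rewiring_rate`` of residues is displaced by isotropic
    Gaussian noise of scale ``sigma`` (A), large enough to make and break
    7-A contacts.  Rate 0 returns exact copies; higher rates lower the
    expected pairwise TM-score and decorrelate the unfolding pathways.
    """
    if not 0.0 <= rewiring_rate <= 1.0:
        raise ValueError("rewiring_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = template.n_residues
    n_move = int(round(rewiring_rate * n))
    variants = []
    for v in range(n_variants):
        coords = template.coords.copy()
        if n_move > 0:
            moved = rng.choice(n, size=n_move, replace=False)
            coords[moved] += rng.normal(0.0, sigma, (n_move, 3))
        variants.append(
            CalphaStructure(
                residue_ids=template.residue_ids.copy(),
                coords=coords,
                b_factors=template.b_factors.copy(),
                chain_id=template.chain_id,
                ss_labels=None if template.ss_labels is None
                else list(template.ss_labels),
            )
        )
    return variants
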
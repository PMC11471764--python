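"""Region-wise pathway encoding and family-level pathway comparison.

A bond-breaking trajectory is summarized by assigning every broken contact
to a structural region (a pair of secondary-structure elements, e.g.
"beta1-beta2"), one-hot encoding the region of each event, and flattening
the resulting N_b x N_r matrix into a vector.  Across a protein family the
covariance/correlation matrix of these vectors quantifies how similar the
unfolding pathways are; the TM-score on a supplied residue correspondence
quantifies how similar the native structures are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .unfolding import UnfoldingTrajectory

__all__ = [
    "RegionScheme",
    "PathwayEncoding",
    "FamilyComparison",
    "ci2_region_scheme",
    "barnase_region_scheme",
    "generic_region_scheme",
    "default_region_scheme",
    "encode_pathway",
    "family_covariance",
    "tm_score_on_correspondence",
    "floppy_curve_divergence",
]

#: Canonical element names for the chymotrypsin-inhibitor (CI2) scheme.
CI2_ELEMENTS = ("nterm", "alpha", "beta1", "beta2", "beta3", "loop1", "loop2")

#: Canonical element names for the barnase scheme: N-terminus, three
#: helices, three strands, two loops.
BARNASE_ELEMENTS = (
    "nterm", "alpha1", "alpha2", "alpha3",
    "beta1", "beta2", "beta3", "loop1", "loop2",
)


@dataclass
class RegionScheme:
    """Maps any non-covalent residue pair to exactly one region.

    ``elements`` gives the secondary-structure element label of each
    residue (chain order); ``pair_to_region`` maps an unordered element
    pair to a region index.  Pairs not in the map fall into the catch-all
    "rest" region, so the partition is exhaustive.
    """

    labels: list[str]
    elements: list[str]
    pair_to_region: dict[frozenset, int]
    rest_index: int

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def region_of(self, pair: tuple[int, int]) -> int:
        """Region index of a (1-based) residue pair."""
        i, j = pair
        key = frozenset((self.elements[i - 1], self.elements[j - 1]))
        return self.pair_to_region.get(key, self.rest_index)


@dataclass
class PathwayEncoding:
    """One-hot region encoding of a bond-breaking sequence."""

    matrix: np.ndarray  # (N_b, N_r), one-hot rows (all-zero rows = padding)
    protein_id: str = ""
    n_padded: int = 0

    @property
    def flat(self) -> np.ndarray:
        return self.matrix.reshape(-1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class FamilyComparison:
    """Pairwise pathway and structure similarity over a protein family."""

    protein_ids: list[str]
    pathway_covariance: np.ndarray
    pathway_correlation: np.ndarray
    tm_scores: np.ndarray | None = None
    floppy_divergence: np.ndarray | None = None


def _validate_elements(ss_labels: Sequence[str]) -> list[str]:
    if ss_labels is None:
        raise ValueError(
            "secondary-structure labels are required; supply a per-residue "
            "annotation (TSV: residue_id <tab> element label)"
        )
    return [str(lab) for lab in ss_labels]


def ci2_region_scheme(ss_labels: Sequence[str]) -> RegionScheme:
    """The five CI2 regions: N-terminus-beta3, alpha-loop2, beta1-beta2,
    beta2-beta3, and the rest of the non-covalent bonds."""
    elements = _validate_elements(ss_labels)
    labels = [
        "N-terminus-beta3", "alpha-loop2", "beta1-beta2", "beta2-beta3", "rest",
    ]
    pair_to_region = {
        frozenset(("nterm", "beta3")): 0,
        frozenset(("alpha", "loop2")): 1,
        frozenset(("beta1", "beta2")): 2,
        frozenset(("beta2", "beta3")): 3,
    }
    return RegionScheme(labels, elements, pair_to_region, rest_index=4)


def barnase_region_scheme(
    ss_labels: Sequence[str],
    contacts: Sequence[tuple[int, int]],
    *,
    n_regions: int = 30,
) -> RegionScheme:
    """Barnase-style scheme: element-pair regions capped at ``n_regions``.

    All unordered pairs of the nine named elements are enumerated, pairs
    with no native contact are dropped, and if more than ``n_regions - 1``
    populated pairs remain, the most populated ones are kept and the
    remainder merged into "rest".  This is a documented reconstruction of
    a contact-map clustering; the exact original partition is not
    recoverable.
    """
    elements = _validate_elements(ss_labels)
    counts: dict[frozenset, int] = {}
    for (i, j) in contacts:
        ei, ej = elements[i - 1], elements[j - 1]
        if ei in BARNASE_ELEMENTS and ej in BARNASE_ELEMENTS:
            counts[frozenset((ei, ej))] = counts.get(frozenset((ei, ej)), 0) + 1
    populated = sorted(
        counts, key=lambda k: (-counts[k], tuple(sorted(k)))
    )[: n_regions - 1]
    labels = ["-".join(sorted(k)) for k in populated] + ["rest"]
    pair_to_region = {k: idx for idx, k in enumerate(populated)}
    return RegionScheme(labels, elements, pair_to_region, rest_index=len(populated))


def generic_region_scheme(ss_labels: Sequence[str]) -> RegionScheme:
    """All unordered pairs (including self-pairs) of the distinct element
    labels, plus a catch-all rest region."""
    elements = _validate_elements(ss_labels)
    uniq = sorted(set(elements))
    pairs = [
        frozenset((a, b))
        for ai, a in enumerate(uniq)
        for b in uniq[ai:]
    ]
    labels = ["-".join(sorted(p)) if len(p) > 1 else f"{next(iter(p))}-self"
              for p in pairs] + ["rest"]
    pair_to_region = {p: idx for idx, p in enumerate(pairs)}
    return RegionScheme(labels, elements, pair_to_region, rest_index=len(pairs))


def default_region_scheme(
    ss_labels: Sequence[str],
    family: str = "generic",
    contacts: Sequence[tuple[int, int]] | None = None,
) -> RegionScheme:
    """Dispatch to the family-specific scheme (ci2 | barnase | generic)."""
    if family == "ci2":
        return ci2_region_scheme(ss_labels)
    if family == "barnase":
        if contacts is None:
            raise ValueError("barnase scheme needs the native contact list")
        return barnase_region_scheme(ss_labels, contacts)
    if family == "generic":
        return generic_region_scheme(ss_labels)
    raise ValueError(f"unknown family {family!r}")


def encode_pathway(
    traj: UnfoldingTrajectory,
    scheme: RegionScheme,
    n_b: int | None = None,
    protein_id: str = "",
) -> PathwayEncoding:
    """One-hot encode the region of each breaking event, in event order.

    ``n_b`` fixes the row count across a family: shorter trajectories are
    padded with all-zero rows (and the padding count recorded), longer
    ones truncated.
    """
    n_b = traj.n_events if n_b is None else int(n_b)
    mat = np.zeros((n_b, scheme.n_regions))
    for event in traj.events[:n_b]:
        mat[event.step - 1, scheme.region_of(event.pair)] = 1.0
    n_padded = max(n_b - traj.n_events, 0)
    return PathwayEncoding(matrix=mat, protein_id=protein_id, n_padded=n_padded)


def family_covariance(encodings: Sequence[PathwayEncoding]) -> FamilyComparison:
    """Covariance and correlation of flattened pathway vectors over a family.

    Rows of the stacked matrix are proteins, columns the N_b * N_r
    positions; the N_p x N_p covariance is over positions.
    """
    if len(encodings) < 2:
        raise ValueError("need at least two pathways to compare")
    shapes = {e.shape for e in encodings}
    if len(shapes) > 1:
        raise ValueError(f"pathway encodings have mismatched shapes: {shapes}")
    x = np.stack([e.flat for e in encodings])
    cov = np.cov(x)
    corr = np.corrcoef(x)
    return FamilyComparison(
        protein_ids=[e.protein_id for e in encodings],
        pathway_covariance=np.atleast_2d(cov),
        pathway_correlation=np.atleast_2d(corr),
    )


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R p + t - q|^2."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, qc - r @ pc


def tm_score_on_correspondence(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    pairs: Sequence[tuple[int, int]] | None = None,
    *,
    l_ref: int | None = None,
    d0_min: float = 0.5,
) -> float:
    """TM-score of two structures on a supplied residue correspondence.

    score = max over superpositions of (1/L) sum_k 1 / (1 + (d_k/d0)^2)
    with d0 = 1.24 (L - 15)^(1/3) - 1.8 (floored at ``d0_min``) and L the
    reference length (second structure by default).  The maximization uses
    the standard iterative-cut refinement: superpose on a seed subset,
    drop far pairs, repeat; seeded from the full correspondence and
    shorter contiguous fragments.  No alignment search is performed; the
    correspondence is the caller's responsibility.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if pairs is None:
        if len(coords_a) != len(coords_b):
            raise ValueError("identity correspondence needs equal lengths")
        pairs = [(k + 1, k + 1) for k in range(len(coords_a))]
    if len(pairs) < 3:
        raise ValueError("need at least 3 corresponding residue pairs")
    ia = np.array([p[0] - 1 for p in pairs])
    ib = np.array([p[1] - 1 for p in pairs])
    a, b = coords_a[ia], coords_b[ib]
    k = len(pairs)
    l = int(l_ref) if l_ref is not None else len(coords_b)
    d0 = max(1.24 * np.cbrt(max(l - 15, 0)) - 1.8, d0_min) if l > 15 else d0_min

    def tm_of(subset: np.ndarray) -> tuple[float, np.ndarray]:
        r, t = _kabsch(a[subset], b[subset])
        d = np.linalg.norm(a @ r.T + t - b, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l), d

    best = 0.0
    seed_lens = sorted({k, max(k // 2, 3), max(k // 4, 3), min(4, k)}, reverse=True)
    for seed_len in seed_lens:
        for start in range(0, k - seed_len + 1, max(seed_len // 2, 1)):
            subset = np.arange(start, start + seed_len)
            prev: np.ndarray | None = None
            for _ in range(20):
                score, d = tm_of(subset)
                best = max(best, score)
                d_cut = d0
                new = np.flatnonzero(d < d_cut)
                while new.size < 3:
                    d_cut += 0.5
                    new = np.flatnonzero(d < d_cut)
                if prev is not None and np.array_equal(new, prev):
                    break
                prev, subset = new, new
    return best


def floppy_curve_divergence(
    curves: Sequence[tuple[np.ndarray, np.ndarray]],
    n_grid: int = 50,
) -> np.ndarray:
    """Pairwise L2 distance between floppy-mode curves f(<z>).

    Each curve is (z, f) sampled along one trajectory; curves are linearly
    interpolated on a common <z> grid spanning the overlap of all curves
    and compared by root-mean-square difference.
    """
    prepped = []
    lo, hi = -np.inf, np.inf
    for z, f in curves:
        z = np.asarray(z, dtype=float)
        f = np.asarray(f, dtype=float)
        order = np.argsort(z)
        prepped.append((z[order], f[order]))
        lo, hi = max(lo, z.min()), min(hi, z.max())
    if hi <= lo:
        raise ValueError("floppy curves have no overlapping <z> range")
    grid = np.linspace(lo, hi, n_grid)
    interp = np.stack([np.interp(grid, z, f) for z, f in prepped])
    diff = interp[:, None, :] - interp[None, :, :]
    return np.sqrt(np.mean(diff**2, axis=-1))
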
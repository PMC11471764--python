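"""Read PDB files into a minimal C-alpha representation; write tabular outputs.

The whole toolkit works on a coarse-grained view of a protein: one bead per
residue, placed at the C-alpha position, carrying the experimental B-factor.
Everything downstream (Kirchhoff matrix, Hessian, shear field) is built from
this representation plus a distance-cutoff contact list.

Residue indices used in bond labels are 1-based positions along the chain
(1..N), independent of the author residue numbering, which is kept in
``residue_ids`` for reporting.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "CalphaStructure",
    "ContactSet",
    "read_calpha",
    "contact_list",
    "write_calpha_pdb",
    "read_ss_annotation",
    "write_ss_annotation",
    "write_events_csv",
    "write_shear_csv",
    "write_matrix_csv",
    "write_meta_json",
]


@dataclass
class CalphaStructure:
    """One protein chain reduced to its C-alpha trace.

    Attributes
    ----------
    residue_ids:
        Author residue numbers, in file order (one entry per residue).
    coords:
        (N, 3) Cartesian positions in Angstrom.
    b_factors:
        Per-residue experimental B-factors in Angstrom^2.
    chain_id:
        Chain identifier the trace was taken from.
    ss_labels:
        Optional per-residue secondary-structure element label
        (e.g. "alpha", "beta1", "nterm", "loop2"); ``None`` if unknown.
    """

    residue_ids: np.ndarray
    coords: np.ndarray
    b_factors: np.ndarray
    chain_id: str = "A"
    ss_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        n = self.coords.shape[0]
        if n < 3:
            raise ValueError(f"need at least 3 residues, got {n}")
        if len(self.residue_ids) != n or len(self.b_factors) != n:
            raise ValueError("residue_ids, coords and b_factors must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.ss_labels is not None and len(self.ss_labels) != n:
            raise ValueError("ss_labels length must match residue count")

    @property
    def n_residues(self) -> int:
        return int(self.coords.shape[0])


class ContactSet(NamedTuple):
    """Exhaustive, disjoint partition of bonded residue pairs (1-based, i<j).

    ``backbone`` holds every (i, i+1) pair; ``noncovalent`` every pair with
    |i-j| > 1 whose native C-alpha separation is below the cutoff.
    """

    backbone: tuple[tuple[int, int], ...]
    noncovalent: tuple[tuple[int, int], ...]

    @property
    def n_bonds(self) -> int:
        return len(self.backbone) + len(self.noncovalent)


def read_calpha(pdb_source, chain: str | None = None) -> CalphaStructure:
    """Read one chain of a PDB file as a C-alpha trace.

    Parameters
    ----------
    pdb_source:
        Path to a PDB file, or the PDB text itself, or a text file handle.
    chain:
        Chain identifier. Mandatory when the file has several chains;
        if ``None`` and exactly one chain is present, that chain is used.

    Alternate locations are resolved by occupancy (ties go to altloc 'A');
    only the first model of multi-model files is read; hetero atoms and
    waters are ignored. A gap in author numbering between consecutive
    C-alphas is logged as a warning but the two residues are still treated
    as backbone neighbours downstream.
    """
    if isinstance(pdb_source, (str, Path)) and "\n" in str(pdb_source):
        handle = io.StringIO(str(pdb_source))
    elif isinstance(pdb_source, (str, Path)):
        handle = open(pdb_source)
    else:
        handle = pdb_source
    try:
        pdb_file = pdbio.PDBFile.read(handle)
    finally:
        if handle is not pdb_source:
            handle.close()
    try:
        atoms = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["b_factor"]
        )
    except ValueError as err:
        raise ValueError(f"no C-alpha ATOM records found in source ({err})")
    atoms = atoms[
        (atoms.atom_name == "CA")
        & ~atoms.hetero
        & np.isin(atoms.element, ["C", ""])
    ]
    if atoms.array_length() == 0:
        raise ValueError("no C-alpha ATOM records found in source")
    chains = sorted(set(atoms.chain_id))
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"source has multiple chains {chains}; specify one explicitly"
            )
        chain = chains[0]
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available chains: {chains}")
    atoms = atoms[atoms.chain_id == chain]

    # One CA per residue, file order; duplicates (leftover altloc weirdness)
    # collapse to the first occurrence.
    seen: dict[tuple[int, str], int] = {}
    keep: list[int] = []
    for k in range(atoms.array_length()):
        key = (int(atoms.res_id[k]), str(atoms.ins_code[k]))
        if key not in seen:
            seen[key] = k
            keep.append(k)
    atoms = atoms[keep]

    res_ids = atoms.res_id.astype(int)
    gaps = np.flatnonzero(np.diff(res_ids) > 1)
    for g in gaps:
        warnings.warn(
            f"chain break between residues {res_ids[g]} and {res_ids[g + 1]} "
            f"of chain {chain}; treating them as backbone neighbours",
            stacklevel=2,
        )
    return CalphaStructure(
        residue_ids=res_ids,
        coords=atoms.coord.astype(float),
        b_factors=atoms.b_factor.astype(float),
        chain_id=str(chain),
    )


def contact_list(s: CalphaStructure, r_c: float) -> ContactSet:
    """Partition residue pairs into backbone and non-covalent contacts.

    Backbone pairs (i, i+1) are always bonded.  A pair with |i-j| > 1 is a
    non-covalent contact iff its native C-alpha distance is strictly below
    the cutoff ``r_c`` (Angstrom).  Indices are 1-based chain positions.
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    n = s.n_residues
    backbone = tuple((i, i + 1) for i in range(1, n))
    d = np.linalg.norm(s.coords[:, None, :] - s.coords[None, :, :], axis=-1)
    ii, jj = np.triu_indices(n, k=2)
    mask = d[ii, jj] < r_c
    noncov = tuple(
        (int(a) + 1, int(b) + 1) for a, b in zip(ii[mask], jj[mask])
    )
    return ContactSet(backbone=backbone, noncovalent=noncov)


def write_calpha_pdb(s: CalphaStructure, path) -> None:
    """Write the trace back out as CA-only ATOM records (PDB format)."""
    n = s.n_residues
    atoms = struc.AtomArray(n)
    atoms.coord = s.coords
    atoms.chain_id[:] = s.chain_id
    atoms.res_id = s.residue_ids
    atoms.res_name[:] = "GLY"
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = False
    atoms.set_annotation("b_factor", s.b_factors)
    atoms.set_annotation("occupancy", np.ones(n))
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


def read_ss_annotation(path) -> dict[int, str]:
    """Read a residue -> secondary-structure-element TSV (residue_id, label)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["residue_id", "label"],
                        comment="#", dtype={"residue_id": int, "label": str})
    return dict(zip(table["residue_id"], table["label"]))


def write_ss_annotation(labels: Sequence[str], path, residue_ids=None) -> None:
    ids = residue_ids if residue_ids is not None else range(1, len(labels) + 1)
    with open(path, "w") as fh:
        for rid, lab in zip(ids, labels):
            fh.write(f"{int(rid)}\t{lab}\n")


def write_events_csv(traj, path) -> None:
    """Write an unfolding trajectory as events.csv (step,i,j,criterion,Q,z,f)."""
    rows = {
        "step": [e.step for e in traj.events],
        "i": [e.pair[0] for e in traj.events],
        "j": [e.pair[1] for e in traj.events],
        "criterion": [e.value for e in traj.events],
        "Q": traj.q_series,
        "z": traj.z_series,
        "f": traj.f_series if traj.f_series is not None else np.nan,
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_shear_csv(field_, path, residue_ids=None) -> None:
    """Write a shear field snapshot as shear.csv (residue_id, s, Q)."""
    n = len(field_.s)
    ids = residue_ids if residue_ids is not None else np.arange(1, n + 1)
    pd.DataFrame(
        {"residue_id": ids, "s": field_.s, "Q": field_.q_label}
    ).to_csv(path, index=False, float_format="%.10g")


def write_matrix_csv(matrix: np.ndarray, ids: Sequence[str], path) -> None:
    """Write a square comparison matrix with ids as header row and column."""
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(
        path, float_format="%.10g"
    )


def write_meta_json(meta: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
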
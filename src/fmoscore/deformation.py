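"""Ligand deformation (strain) energy from a conformer ensemble.

A bound ligand pays an energetic penalty for adopting its bioactive
conformation.  Given single-point energies of candidate conformers (all at
one consistent level of theory) the reference energy is the minimum over the
lowest-energy representatives after clustering/deduplication, and

    dE_def = E(bound conformation) - E(reference conformer)

Conformer generation and geometry optimisation happen upstream; this module
operates on the resulting energies and (optionally) pairwise heavy-atom RMSDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateInputError

__all__ = [
    "DEFAULT_ENERGY_TOL",
    "DEFAULT_RMSD_TOL",
    "ConformerEnsemble",
    "dedup_cluster",
    "reference_energy",
    "deformation_energy",
]

#: Default duplicate thresholds: conformers within 0.1 kcal/mol AND 0.5 A
#: RMSD of each other are treated as the same structure.
DEFAULT_ENERGY_TOL = 0.1
DEFAULT_RMSD_TOL = 0.5


@dataclass
class ConformerEnsemble:
    """Candidate ligand conformers: ids, energies and optional pairwise RMSDs.

    ``energies`` are single-point energies in kcal/mol at one consistent
    theory level; ``rmsd`` (if given) is a symmetric matrix in angstrom with a
    zero diagonal.
    """

    conformer_ids: list[str]
    energies: np.ndarray
    rmsd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        n = len(self.conformer_ids)
        if self.energies.shape != (n,):
            raise ValueError(f"expected {n} energies, got shape {self.energies.shape}")
        if n and not np.all(np.isfinite(self.energies)):
            raise ValueError("conformer energies must be finite")
        if len(set(self.conformer_ids)) != n:
            raise ValueError("conformer_ids must be unique")
        if self.rmsd is not None:
            self.rmsd = np.asarray(self.rmsd, dtype=float)
            if self.rmsd.shape != (n, n):
                raise ValueError(f"rmsd matrix must be {n}x{n}, got {self.rmsd.shape}")
            if n:
                if not np.allclose(self.rmsd, self.rmsd.T, atol=1e-8):
                    raise ValueError("rmsd matrix must be symmetric")
                if np.any(np.diag(self.rmsd) != 0):
                    raise ValueError("rmsd diagonal must be zero")
                if np.any(self.rmsd < 0):
                    raise ValueError("rmsd values must be non-negative")

    def __len__(self) -> int:
        return len(self.conformer_ids)


def dedup_cluster(
    ens: ConformerEnsemble,
    energy_tol: float = DEFAULT_ENERGY_TOL,
    rmsd_tol: float | None = DEFAULT_RMSD_TOL,
) -> ConformerEnsemble:
    """Collapse duplicate conformers, keeping each group's lowest-energy member.

    Two conformers are direct duplicates when ``|dE| <= energy_tol`` and (if
    ``rmsd_tol`` is not None) their RMSD is ``<= rmsd_tol``; duplicate groups
    are the connected components of this relation (greedy single linkage, so
    chains of near-duplicates merge).  Within a group the representative is
    the lowest-energy conformer, energy ties broken by ``conformer_id``.  The
    result is sorted by energy ascending (same tie-break) and is independent
    of input ordering.
    """
    n = len(ens)
    if n == 0:
        return ConformerEnsemble(conformer_ids=[], energies=np.empty(0), rmsd=None)
    if rmsd_tol is not None and ens.rmsd is None:
        raise ValueError("rmsd_tol given but the ensemble has no rmsd matrix")
    e = ens.energies
    dup = np.abs(e[:, None] - e[None, :]) <= energy_tol
    if rmsd_tol is not None:
        dup &= ens.rmsd <= rmsd_tol
    _, labels = connected_components(csr_matrix(dup), directed=False)
    reps = []
    for g in range(labels.max() + 1):
        members = np.flatnonzero(labels == g)
        best = min(members, key=lambda k: (e[k], ens.conformer_ids[k]))
        reps.append(best)
    reps.sort(key=lambda k: (e[k], ens.conformer_ids[k]))
    rmsd = ens.rmsd[np.ix_(reps, reps)] if ens.rmsd is not None else None
    return ConformerEnsemble(
        conformer_ids=[ens.conformer_ids[k] for k in reps],
        energies=e[reps],
        rmsd=rmsd,
    )


def reference_energy(
    ens: ConformerEnsemble,
    k: int = 3,
    energy_tol: float = DEFAULT_ENERGY_TOL,
    rmsd_tol: float | None = None,
) -> float:
    """Reference (relaxed-ligand) energy: minimum over the ``k`` lowest representatives.

    The ensemble is deduplicated first (RMSD criterion only if the ensemble
    carries a matrix and ``rmsd_tol`` is given), then the ``k`` lowest-energy
    representatives are retained — mirroring workflows that re-optimise only
    the few best conformers — and their minimum is returned.  Monotone
    non-increasing in ``k``; with ``k >= n`` this is the plain ensemble
    minimum.
    """
    if len(ens) == 0:
        raise DegenerateInputError("reference_energy requires at least one conformer")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if rmsd_tol is not None and ens.rmsd is None:
        rmsd_tol = None
    reps = dedup_cluster(ens, energy_tol=energy_tol, rmsd_tol=rmsd_tol)
    return float(np.min(reps.energies[:k]))


def deformation_energy(e_bound: float, e_ref: float) -> float:
    """dE_def = E(bound conformation) - E(reference conformer), kcal/mol.

    Both energies must come from the same level of theory (caller contract).
    A negative result means the ensemble found a conformer above the relaxed
    bound structure — usually an upstream sampling failure — and is returned
    as-is with a warning rather than clamped.
    """
    if not (np.isfinite(e_bound) and np.isfinite(e_ref)):
        raise ValueError("energies must be finite")
    e_def = e_bound - e_ref
    if e_def < 0:
        warnings.warn(
            f"negative deformation energy ({e_def:.3f} kcal/mol): the conformer "
            "ensemble likely missed the relaxed neighbour of the bound pose",
            stacklevel=2,
        )
    return e_def
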
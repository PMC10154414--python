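"""Least-squares rigid superposition (Kabsch) and multi-copy RMSD summaries.

Used to quantify how closely independently determined copies of a domain
agree: Ig1 homodimers superpose at 1–2 Å, and the seven crystallographically
independent FNIII2-3 copies agree to well under 1 Å over their Cα traces,
which is the evidence that the FNIII2-3 kink is a fixed, physiological
conformation rather than a lattice artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sdscam.structmetrics.model import StructureModel


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map mobile -> reference and the resulting RMSD."""

    rotation: np.ndarray       # 3x3, orthonormal, det +1
    translation: np.ndarray    # Angstroms
    rmsd: float                # Angstroms, over matched atoms
    n_atoms: int
    matched: list[tuple]       # (chain_ref, res_ref, chain_mob, res_mob, atom)
    degenerate: bool = False   # collinear/rank-deficient point set

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(reference: np.ndarray, mobile: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Optimal proper rotation/translation mapping ``mobile`` onto
    ``reference`` (paired points), and the residual RMSD.

    Reflections are excluded: if the covariance SVD calls for one, the
    smallest singular direction is flipped, keeping det(R) = +1.
    """
    P = np.asarray(reference, float)
    Q = np.asarray(mobile, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 matched atoms")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = Q @ R.T + t - P
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    # rank-deficient (collinear) sets leave the rotation underdetermined
    degenerate = bool(S[1] < 1e-9 * max(S[0], 1.0))
    return R, t, rmsd, degenerate


def _pair_atoms(
    reference: StructureModel, mobile: StructureModel, selection: str | None
) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    ref = reference.polymer()
    mob = mobile.polymer()
    if selection is not None:
        ref = ref.atoms_named(selection)
        mob = mob.atoms_named(selection)
    ref_chains, mob_chains = ref.chains, mob.chains

    def keyed(m: StructureModel, drop_chain: bool):
        out = {}
        for i in range(len(m)):
            key = (m.res_ids[i], m.atom_names[i]) if drop_chain else (
                m.chain_ids[i], m.res_ids[i], m.atom_names[i]
            )
            out.setdefault(key, i)
        return out

    # same chain naming -> match on (chain, residue, atom); two single chains
    # with different ids -> match on (residue, atom) only
    drop_chain = set(ref_chains) != set(mob_chains)
    if drop_chain and (len(ref_chains) != 1 or len(mob_chains) != 1):
        raise ValueError(
            "chain sets differ and are not single chains; rename chains or "
            "superpose chain by chain"
        )
    kr, km = keyed(ref, drop_chain), keyed(mob, drop_chain)
    common = sorted(set(kr) & set(km))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} matched atoms; need >= 3")
    ri = [kr[c] for c in common]
    mi = [km[c] for c in common]
    matched = [
        (ref.chain_ids[i], int(ref.res_ids[i]), mob.chain_ids[j],
         int(mob.res_ids[j]), ref.atom_names[i])
        for i, j in zip(ri, mi)
    ]
    return ref.coords[ri], mob.coords[mi], matched


def kabsch_superpose(
    reference: StructureModel,
    mobile: StructureModel,
    selection: str | None = "CA",
) -> Superposition:
    """Superpose ``mobile`` onto ``reference`` over paired polymer atoms.

    Atoms are paired by chain id + residue number + atom name when the two
    models share chain naming, or by residue number + atom name when each is
    a single chain. ``selection`` restricts the match to one atom name
    (default Cα); pass ``None`` to use all polymer atoms.
    """
    P, Q, matched = _pair_atoms(reference, mobile, selection)
    R, t, rmsd, degenerate = kabsch(P, Q)
    return Superposition(R, t, rmsd, len(P), matched, degenerate)


@dataclass(frozen=True)
class RmsdSummary:
    """All pairwise RMSDs among structure copies, plus the conventions a
    single printed number could refer to (mean/max pairwise, mean onto a
    reference copy)."""

    matrix: np.ndarray
    mean_pairwise: float
    max_pairwise: float
    mean_to_reference: float
    n_atoms: int


def asu_rmsd_summary(
    models: list[StructureModel], selection: str | None = "CA"
) -> RmsdSummary:
    """Pairwise superposition RMSDs over the atom set shared by all copies.

    Intended for the independent copies of a molecule in one asymmetric
    unit: near-identical conformations give uniformly small values.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    n = len(models)
    mat = np.zeros((n, n))
    n_atoms = None
    for i in range(n):
        for j in range(i + 1, n):
            sup = kabsch_superpose(models[i], models[j], selection)
            mat[i, j] = mat[j, i] = sup.rmsd
            n_atoms = sup.n_atoms if n_atoms is None else min(n_atoms, sup.n_atoms)
    iu = np.triu_indices(n, k=1)
    return RmsdSummary(
        matrix=mat,
        mean_pairwise=float(mat[iu].mean()),
        max_pairwise=float(mat[iu].max()),
        mean_to_reference=float(mat[0, 1:].mean()),
        n_atoms=int(n_atoms),
    )
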
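"""Dimer interface metrics: buried surface area and contact residues.

The buried surface area (BSA) of a dimer is the solvent-accessible area
lost on complex formation, ΔSASA = SASA(A) + SASA(B) − SASA(A∪B). Both the
two-protomer total and the per-side half are reported, since published
figures use either convention without always saying which.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from sdscam.structmetrics.model import StructureModel
from sdscam.structmetrics.sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    shrake_rupley_sasa,
)

_BASIC_N = {
    ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
    ("LYS", "NZ"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
_ACIDIC_O = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}


@dataclass(frozen=True)
class ContactPair:
    """Residue pair across the interface with its closest heavy-atom gap."""

    chain_a: str
    res_id_a: int
    res_name_a: str
    chain_b: str
    res_id_b: int
    res_name_b: str
    min_distance: float
    salt_bridge: bool = False


@dataclass(frozen=True)
class InterfaceReport:
    """ΔSASA and contacts for one protomer pair."""

    bsa_total: float          # Å², summed over both protomers
    bsa_half: float           # Å², per-side (PISA-style) value
    contacts: list[ContactPair]
    cutoff: float
    per_residue_dsasa: dict   # (chain, res_id) -> buried Å²


def _per_residue(model: StructureModel, areas: np.ndarray) -> dict:
    out: dict = {}
    for i in range(len(model)):
        key = (model.chain_ids[i], int(model.res_ids[i]))
        out[key] = out.get(key, 0.0) + float(areas[i])
    return out


def interface_residues(
    protomer_a: StructureModel,
    protomer_b: StructureModel,
    cutoff: float = 4.5,
    salt_bridge_cutoff: float = 4.0,
) -> list[ContactPair]:
    """Residue pairs with any heavy-atom pair within ``cutoff`` Å.

    Pairs are sorted by their minimum distance. A pair is annotated as a
    salt bridge when an Arg/Lys/His side-chain nitrogen lies within
    ``salt_bridge_cutoff`` Å of an Asp/Glu carboxylate oxygen (either
    direction across the interface).
    """
    a = protomer_a.polymer().heavy()
    b = protomer_b.polymer().heavy()
    if len(a) == 0 or len(b) == 0:
        return []
    tree_b = cKDTree(b.coords)
    pairs = tree_b.query_ball_point(a.coords, cutoff)
    best: dict[tuple, float] = {}
    bridged: set[tuple] = set()
    for i, hits in enumerate(pairs):
        for j in hits:
            d = float(np.linalg.norm(a.coords[i] - b.coords[j]))
            key = (
                a.chain_ids[i], int(a.res_ids[i]), a.res_names[i],
                b.chain_ids[j], int(b.res_ids[j]), b.res_names[j],
            )
            if d < best.get(key, np.inf):
                best[key] = d
            if d <= salt_bridge_cutoff:
                fa = (a.res_names[i], a.atom_names[i])
                fb = (b.res_names[j], b.atom_names[j])
                if (fa in _BASIC_N and fb in _ACIDIC_O) or (
                    fa in _ACIDIC_O and fb in _BASIC_N
                ):
                    bridged.add(key)
    contacts = [
        ContactPair(*key, min_distance=d, salt_bridge=key in bridged)
        for key, d in best.items()
    ]
    contacts.sort(key=lambda c: c.min_distance)
    return contacts


def _concatenate(a: StructureModel, b: StructureModel) -> StructureModel:
    if a.chains and set(a.chains) & set(b.chains):
        # disambiguate so per-residue bookkeeping cannot collide
        b = StructureModel(
            np.array([c + "'" for c in b.chain_ids], dtype=object),
            b.res_ids, b.res_names, b.atom_names, b.elements, b.coords,
            b.occupancies, b.hetero, dict(b.meta),
        )
    return StructureModel(
        np.concatenate([a.chain_ids, b.chain_ids]),
        np.concatenate([a.res_ids, b.res_ids]),
        np.concatenate([a.res_names, b.res_names]),
        np.concatenate([a.atom_names, b.atom_names]),
        np.concatenate([a.elements, b.elements]),
        np.vstack([a.coords, b.coords]),
        np.concatenate([a.occupancies, b.occupancies]),
        np.concatenate([a.hetero, b.hetero]),
    )


def buried_surface_area(
    protomer_a: StructureModel,
    protomer_b: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    cutoff: float = 4.5,
) -> InterfaceReport:
    """ΔSASA of the A:B interface, with contact residues.

    Raises if the two protomers share identical atom positions (the same
    molecule passed twice), which would make the union degenerate.
    """
    a = protomer_a.polymer().heavy()
    b = protomer_b.polymer().heavy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("protomers must contain polymer atoms")
    if len(a) == len(b) and np.allclose(a.coords, b.coords):
        raise ValueError("protomers have identical coordinates (same molecule twice)")
    sasa_a = shrake_rupley_sasa(a, probe, n_points)
    sasa_b = shrake_rupley_sasa(b, probe, n_points)
    both = _concatenate(a, b)
    sasa_ab = shrake_rupley_sasa(both, probe, n_points)
    bsa = sasa_a.total + sasa_b.total - sasa_ab.total

    free = {**_per_residue(a, sasa_a.per_atom), **_per_residue(
        StructureModel(
            both.chain_ids[len(a):], b.res_ids, b.res_names, b.atom_names,
            b.elements, b.coords, b.occupancies, b.hetero,
        ),
        sasa_b.per_atom,
    )}
    bound = _per_residue(both, sasa_ab.per_atom)
    per_res = {
        key: free.get(key, 0.0) - bound.get(key, 0.0) for key in free
    }
    return InterfaceReport(
        bsa_total=float(bsa),
        bsa_half=float(bsa) / 2.0,
        contacts=interface_residues(protomer_a, protomer_b, cutoff),
        cutoff=cutoff,
        per_residue_dsasa=per_res,
    )
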
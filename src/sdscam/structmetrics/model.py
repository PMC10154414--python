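"""Array-backed structure container and PDB/mmCIF I/O.

:class:`StructureModel` keeps atoms as flat parallel arrays (chain id,
residue number, residue name, atom name, element, occupancy, coordinates)
— the layout every metric in this subpackage consumes directly. Parsing and
serialization of the crystallographic formats are delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class StructureModel:
    """Chains/residues/atoms with 3-D coordinates in Angstroms."""

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    occupancies: np.ndarray
    hetero: np.ndarray  # True for waters/ligands/glycans (non-polymer)
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(
        cls,
        chain_ids,
        res_ids,
        res_names,
        atom_names,
        elements,
        coords,
        occupancies=None,
        hetero=None,
    ) -> "StructureModel":
        n = len(chain_ids)
        coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        return cls(
            chain_ids=np.asarray(chain_ids, dtype=object),
            res_ids=np.asarray(res_ids, dtype=int),
            res_names=np.asarray(res_names, dtype=object),
            atom_names=np.asarray(atom_names, dtype=object),
            elements=np.asarray(elements, dtype=object),
            coords=coords,
            occupancies=(
                np.ones(n) if occupancies is None else np.asarray(occupancies, float)
            ),
            hetero=(
                np.zeros(n, dtype=bool) if hetero is None else np.asarray(hetero, bool)
            ),
        )

    # -- selections --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.chain_ids)

    def select(self, mask: np.ndarray) -> "StructureModel":
        mask = np.asarray(mask, bool)
        return StructureModel(
            self.chain_ids[mask], self.res_ids[mask], self.res_names[mask],
            self.atom_names[mask], self.elements[mask], self.coords[mask],
            self.occupancies[mask], self.hetero[mask], dict(self.meta),
        )

    def polymer(self) -> "StructureModel":
        """Polymer atoms only (waters/ligands/glycans dropped)."""
        return self.select(~self.hetero)

    def chain(self, chain_id: str) -> "StructureModel":
        return self.select(self.chain_ids == chain_id)

    def atoms_named(self, name: str) -> "StructureModel":
        return self.select(self.atom_names == name)

    def heavy(self) -> "StructureModel":
        return self.select(self.elements != "H")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def sequence(self, chain_id: str) -> str:
        """One-letter polymer sequence of a chain (unknown residues as X)."""
        ch = self.chain(chain_id).polymer()
        seq = []
        last = None
        for rid, rname in zip(ch.res_ids, ch.res_names):
            if rid != last:
                seq.append(_THREE_TO_ONE.get(rname, "X"))
                last = rid
        return "".join(seq)

    # -- gemmi conversion --------------------------------------------------

    def to_gemmi(self, name: str = "model") -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = name
        model = gemmi.Model("1")
        for cid in self.chains:
            chain = gemmi.Chain(str(cid))
            sel = self.chain(cid)
            # group atom indices by residue, preserving order
            groups: dict[int, list[int]] = {}
            for i in range(len(sel)):
                groups.setdefault(int(sel.res_ids[i]), []).append(i)
            for rid, idxs in groups.items():
                res = gemmi.Residue()
                res.name = str(sel.res_names[idxs[0]])
                res.seqid = gemmi.SeqId(rid, " ")
                res.het_flag = "H" if sel.hetero[idxs[0]] else "A"
                for i in idxs:
                    atom = gemmi.Atom()
                    atom.name = str(sel.atom_names[i])
                    atom.element = gemmi.Element(str(sel.elements[i]))
                    atom.occ = float(sel.occupancies[i])
                    atom.pos = gemmi.Position(*sel.coords[i])
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st

    def write(self, path: str | Path) -> None:
        """Write as PDB (``.pdb``) or mmCIF (``.cif``)."""
        path = Path(path)
        st = self.to_gemmi(path.stem)
        if path.suffix.lower() in (".cif", ".mmcif"):
            st.make_mmcif_document().write_file(str(path))
        else:
            st.write_pdb(str(path))


def _from_gemmi(st: gemmi.Structure) -> StructureModel:
    st.setup_entities()
    chain_ids, res_ids, res_names, atom_names = [], [], [], []
    elements, coords, occs, hetero = [], [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H" or res.name in _WATER_NAMES
            # altloc resolution: keep the highest-occupancy conformer per atom
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    by_name[atom.name] = atom
            for atom in by_name.values():
                el = atom.element.name
                if el == "X":
                    warnings.warn(
                        f"unknown element for atom {atom.name} in {res.name}; "
                        "a fallback vdW radius will be used downstream"
                    )
                chain_ids.append(chain.name)
                res_ids.append(res.seqid.num)
                res_names.append(res.name)
                atom_names.append(atom.name)
                elements.append(el)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occs.append(atom.occ)
                hetero.append(is_het)
    return StructureModel.from_arrays(
        chain_ids, res_ids, res_names, atom_names, elements,
        np.array(coords).reshape(-1, 3), occs, hetero,
    )


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Altlocs are resolved to the highest-occupancy conformer; waters and
    non-polymer entities are flagged ``hetero`` and excluded from polymer
    operations by default. ``fmt`` overrides extension-based detection
    (``"pdb"`` or ``"cif"``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "cif":
            st = gemmi.make_structure_from_block(
                gemmi.cif.read(str(path)).sole_block()
            )
        else:
            st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    model = _from_gemmi(st)
    if len(model) == 0:
        raise ValueError(f"no atoms parsed from {path} (format {fmt})")
    return model
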
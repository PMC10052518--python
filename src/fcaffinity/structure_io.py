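"""Read and write Fc/FcRn complex structures.

The central container is :class:`ComplexModel`: an ordered list of
residues, each tagged with a *chain role* (the Fc homodimer chain that
contacts the receptor, the FcRn alpha chain, or beta-2-microglobulin)
and an EU-numbered position.  Chain roles are declared explicitly in a
chain map — never inferred — so that a given PDB file always produces
the same model.

PDB text is parsed with :mod:`gemmi`; hydrogens, waters and
heteroatoms are discarded, and alternate locations are resolved to the
highest-occupancy conformer (ties broken alphabetically by altloc).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from typing import Iterable, Mapping

import gemmi
import numpy as np
import yaml

from .chemistry import AA3_TO_1, AA1_TO_3, CANONICAL_AA, vdw_radius

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised for unparseable or structurally inconsistent input."""


class ChainRole(str, enum.Enum):
    FC = "FC"
    FCRN_ALPHA = "FCRN_ALPHA"
    B2M = "B2M"


@dataclasses.dataclass
class Atom:
    """A heavy atom: PDB name, element, coordinates (Å), vdW radius (Å)."""

    name: str
    element: str
    coords: np.ndarray
    radius: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: invalid coordinates")
        if self.radius <= 0 or not self.element:
            raise StructureError(f"atom {self.name}: invalid element/radius")


@dataclasses.dataclass
class ResidueSite:
    """One residue: chain role, EU position, 1-letter code, ordered atoms."""

    chain_role: ChainRole
    eu_number: int
    amino_acid: str
    atoms: list[Atom]

    def __post_init__(self):
        if self.amino_acid not in CANONICAL_AA:
            raise StructureError(
                f"non-canonical amino acid {self.amino_acid!r} "
                f"at {self.chain_role.value} {self.eu_number}"
            )

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"{self.chain_role.value} {self.eu_number} has no atom {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclasses.dataclass
class ComplexModel:
    """Parsed complex: ordered residues plus the declared chain map."""

    sites: list[ResidueSite]
    chain_map: dict[str, ChainRole]
    source_id: str = ""

    def __post_init__(self):
        roles = list(self.chain_map.values())
        if len(roles) != len(set(roles)):
            raise StructureError("chain_map assigns one role to several chains")

    def sites_by_role(self, role: ChainRole) -> list[ResidueSite]:
        return [s for s in self.sites if s.chain_role == role]

    def site(self, role: ChainRole, eu_number: int) -> ResidueSite:
        hits = [s for s in self.sites
                if s.chain_role == role and s.eu_number == eu_number]
        if not hits:
            raise KeyError(f"no residue {role.value} {eu_number}")
        if len(hits) > 1:
            raise StructureError(f"duplicate residue {role.value} {eu_number}")
        return hits[0]

    def roles(self) -> list[ChainRole]:
        seen = []
        for s in self.sites:
            if s.chain_role not in seen:
                seen.append(s.chain_role)
        return seen

    def copy(self) -> "ComplexModel":
        sites = [
            ResidueSite(s.chain_role, s.eu_number, s.amino_acid,
                        [Atom(a.name, a.element, a.coords.copy(), a.radius)
                         for a in s.atoms])
            for s in self.sites
        ]
        return ComplexModel(sites, dict(self.chain_map), self.source_id)


def _coerce_chain_map(chain_map: Mapping[str, str | ChainRole]) -> dict[str, ChainRole]:
    return {cid: ChainRole(role) for cid, role in chain_map.items()}


def _prevalidate_atom_lines(pdb_text: str) -> None:
    for i, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise StructureError(f"unparseable ATOM record at line {i}")


def read_complex(pdb_text: str,
                 chain_map: Mapping[str, str | ChainRole],
                 source_id: str = "") -> ComplexModel:
    """Parse PDB text into a :class:`ComplexModel`.

    Only chains named in ``chain_map`` are kept.  Hydrogens, waters and
    non-amino-acid heteroatoms are dropped; altlocs are resolved to the
    highest-occupancy conformer.  Raises :class:`StructureError` if a
    mapped chain is absent or an ATOM record cannot be parsed.
    """
    cmap = _coerce_chain_map(chain_map)
    _prevalidate_atom_lines(pdb_text)
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise StructureError("no model in PDB input")
    model = structure[0]

    sites: list[ResidueSite] = []
    found_chains = set()
    for chain in model:
        role = cmap.get(chain.name)
        if role is None:
            continue
        found_chains.add(chain.name)
        n_kept = 0
        for res in chain:
            aa1 = AA3_TO_1.get(res.name)
            if aa1 is None:  # water / heteroatom / modified residue
                continue
            # resolve altlocs: highest occupancy, ties by altloc letter
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or (-atom.occ, atom.altloc) < (-prev.occ, prev.altloc):
                    best[atom.name] = atom
            if not best:
                continue
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper(),
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    radius=vdw_radius(a.element.name),
                )
                for a in best.values()
            ]
            sites.append(ResidueSite(role, res.seqid.num, aa1, atoms))
            n_kept += 1
        logger.info("chain %s (%s): %d residues", chain.name, role.value, n_kept)

    for cid, role in cmap.items():
        if cid not in found_chains:
            raise StructureError(
                f"chain {cid!r} (role {role.value}) not found in PDB input"
            )
    return ComplexModel(sites, cmap, source_id=source_id)


def write_complex(model: ComplexModel) -> str:
    """Serialize to fixed-column PDB text: ATOM records, one TER per
    chain, END.  Coordinates are written to 3 decimals."""
    role_to_chain = {role: cid for cid, role in model.chain_map.items()}
    lines: list[str] = []
    serial = 0
    prev_role: ChainRole | None = None
    for idx, site in enumerate(model.sites):
        if prev_role is not None and site.chain_role != prev_role:
            lines.append("TER")
        prev_role = site.chain_role
        chain_id = role_to_chain.get(site.chain_role, "X")
        res3 = AA1_TO_3[site.amino_acid]
        for atom in site.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res3:>3s} {chain_id}"
                f"{site.eu_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
    if model.sites:
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def eu_map(model: ComplexModel,
           offset_table: Mapping[str | ChainRole, int]) -> ComplexModel:
    """Renumber residues to EU numbering by per-role integer offsets.

    Roles absent from ``offset_table`` keep author numbering (the
    receptor chains are conventionally referred to in author numbering).
    Raises :class:`StructureError` on a numbering collision.
    """
    offsets = {ChainRole(k): int(v) for k, v in offset_table.items()}
    out = model.copy()
    seen: set[tuple[ChainRole, int]] = set()
    for site in out.sites:
        site.eu_number += offsets.get(site.chain_role, 0)
        key = (site.chain_role, site.eu_number)
        if key in seen:
            raise StructureError(
                f"numbering collision: two residues at {key[0].value} {key[1]}"
            )
        seen.add(key)
    return out


def load_config(path_or_text: str) -> dict:
    """Load a YAML run configuration (chain map, EU offsets, overrides)."""
    try:
        with open(path_or_text) as fh:
            text = fh.read()
    except (OSError, ValueError):
        text = path_or_text
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise StructureError("configuration must be a mapping")
    return cfg


def iter_atoms(model: ComplexModel) -> Iterable[tuple[ResidueSite, Atom]]:
    for site in model.sites:
        for atom in site.atoms:
            yield site, atom
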
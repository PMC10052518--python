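"""Structure-derived interface features for one Fc/FcRn complex model.

Per-residue features (for a configurable set of Fc and receptor-side
positions): accessible surface area in the complex (ASA, Å²), surface
area buried on complex formation (BSA = isolated-chain ASA minus
complex ASA, Å²), and an atomic-solvation-parameter energy (kcal/mol).

Complex-level features: counts of interface hydrogen bonds (heavy-atom
donor-acceptor pairs within 3.5 Å), salt bridges (charged side-chain
groups within 4.0 Å, one per residue pair), Cα-Cα contacts (4.0 Å),
paired hydrophilic residues, atoms in contact between the Fc and
beta-2-microglobulin, the number of interface residues, the solvation
energy gain on binding, and two documented surrogates for interface
hydrophobicity and theoretical binding energy.

Surface areas use Shrake-Rupley quadrature on a deterministic spiral
point set (default 960 points, probe 1.4 Å).
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import (
    AA1_TO_3,
    HB_ACCEPTORS,
    HB_DONORS,
    HYDROPHILIC,
    NEGATIVE_ATOMS,
    POSITIVE_ATOMS,
    SOLVATION_ASP,
)
from .structure_io import ChainRole, ComplexModel, ResidueSite

# The 21 Fc interface positions (EU numbering) over which variants are
# modeled; mutations elsewhere do not enter the feature set.
FC_POSITIONS: tuple[int, ...] = (
    251, 252, 253, 254, 255, 256, 257,
    285, 286, 288,
    307, 308, 309, 310, 311, 314,
    428, 433, 434, 435, 436,
)

HBOND_CUTOFF = 3.5
SALT_BRIDGE_CUTOFF = 4.0
CA_CONTACT_CUTOFF = 4.0
CONTACT_CUTOFF = 4.0          # hydrophilic pairs & Fc-β2m atom contacts
PISA_HBOND_CUTOFF = 3.9       # surrogate for PISA's more permissive criterion
INTERFACE_BSA_MIN = 0.1       # Å²; residues above this count as interface

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

COMPLEX_METRICS = (
    "n_interface_residues",
    "solvation_gain",
    "hydrophobic_fraction",
    "binding_energy",
    "pisa_hbonds",
    "pisa_salt_bridges",
    "hbonds",
    "salt_bridges",
    "ca_contacts",
    "mean_hbond_distance",
    "hydrophilic_pairs",
    "b2m_fc_atom_contacts",
)


class FeatureError(ValueError):
    pass


class FeatureKind(str, enum.Enum):
    PER_RESIDUE_ASA = "PER_RESIDUE_ASA"
    PER_RESIDUE_BSA = "PER_RESIDUE_BSA"
    PER_RESIDUE_SOLV = "PER_RESIDUE_SOLV"
    COMPLEX_LEVEL = "COMPLEX_LEVEL"


@dataclasses.dataclass(frozen=True)
class FeatureEntry:
    feature_id: str
    kind: FeatureKind
    selector: tuple[str, int] | str  # (role, number) or metric name


@dataclasses.dataclass
class FeatureCatalog:
    """Ordered list of feature definitions; the default has 147 entries."""

    entries: list[FeatureEntry]

    def __post_init__(self):
        ids = [e.feature_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise FeatureError("duplicate feature ids in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def fc_positions(self) -> frozenset[int]:
        return frozenset(
            e.selector[1] for e in self.entries
            if isinstance(e.selector, tuple) and e.selector[0] == ChainRole.FC.value
        )

    def to_dict(self) -> dict:
        return {
            "entries": [
                {"id": e.feature_id, "kind": e.kind.value,
                 "selector": list(e.selector) if isinstance(e.selector, tuple)
                 else e.selector}
                for e in self.entries
            ]
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FeatureCatalog":
        entries = []
        for row in data["entries"]:
            sel = row["selector"]
            if isinstance(sel, (list, tuple)):
                sel = (str(sel[0]), int(sel[1]))
            entries.append(FeatureEntry(row["id"], FeatureKind(row["kind"]), sel))
        return cls(entries)


@dataclasses.dataclass
class FeatureVector:
    values: np.ndarray
    feature_ids: list[str]
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.feature_ids):
            raise FeatureError("feature vector / catalog length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("non-finite feature value")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_ids, self.values.tolist()))


# --- solvent-accessible surface area ----------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_arrays(coords: np.ndarray, radii: np.ndarray,
                probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by Shrake-Rupley
    quadrature: test points on each expanded sphere (radius + probe) are
    discarded when inside any other expanded sphere."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if n_points < 100:
        raise FeatureError("n_points must be >= 100")
    if probe <= 0:
        raise FeatureError("probe radius must be positive")
    n = len(coords)
    if n == 0:
        return np.empty(0)
    tree = cKDTree(coords)
    if tree.query_pairs(1e-6):
        raise FeatureError("coincident atom centers (degenerate geometry)")
    unit = sphere_points(n_points)
    expanded = radii + probe
    # occluding pairs: expanded spheres overlap
    pairs = tree.query_pairs(2 * expanded.max(), output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(n)]
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        close = d < expanded[pairs[:, 0]] + expanded[pairs[:, 1]]
        for i, j in pairs[close]:
            neighbors[i].append(j)
            neighbors[j].append(i)
    areas = np.empty(n)
    for i in range(n):
        js = neighbors[i]
        if not js:
            areas[i] = 4 * np.pi * expanded[i] ** 2
            continue
        pts = coords[i] + expanded[i] * unit          # (P, 3)
        diff = pts[None, :, :] - coords[js][:, None, :]
        d2 = np.einsum("kpd,kpd->kp", diff, diff)     # (k, P)
        free = np.all(d2 >= (expanded[js] ** 2)[:, None], axis=0)
        areas[i] = 4 * np.pi * expanded[i] ** 2 * free.sum() / n_points
    return areas


def sasa(atoms: Sequence, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom SASA for a list of :class:`~fcaffinity.structure_io.Atom`."""
    coords = np.array([a.coords for a in atoms]).reshape(-1, 3)
    radii = np.array([a.radius for a in atoms])
    return sasa_arrays(coords, radii, probe, n_points)


# --- cached per-model computation -------------------------------------

class FeatureComputer:
    """Computes and caches every feature for one :class:`ComplexModel`.

    SASA is evaluated once for the full complex and once per isolated
    chain; all per-residue and complex-level quantities are derived from
    those arrays and from distance queries on the heavy-atom coordinates.
    """

    def __init__(self, model: ComplexModel,
                 probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS):
        self.model = model
        self.probe = probe
        self.n_points = n_points
        self._flat = [(si, site, atom)
                      for si, site in enumerate(model.sites)
                      for atom in site.atoms]
        self.coords = np.array([a.coords for _, _, a in self._flat]).reshape(-1, 3)
        self.radii = np.array([a.radius for _, _, a in self._flat])
        self.site_index = np.array([si for si, _, _ in self._flat])
        self.roles = np.array([s.chain_role.value for _, s, _ in self._flat])
        self._complex_sasa: np.ndarray | None = None
        self._isolated_sasa: np.ndarray | None = None
        self._metrics: dict[str, float] | None = None

    # -- SASA layers --

    @property
    def complex_sasa(self) -> np.ndarray:
        if self._complex_sasa is None:
            self._complex_sasa = sasa_arrays(
                self.coords, self.radii, self.probe, self.n_points)
        return self._complex_sasa

    @property
    def isolated_sasa(self) -> np.ndarray:
        """Per-atom SASA with each chain taken in isolation."""
        if self._isolated_sasa is None:
            out = np.empty(len(self.coords))
            for role in set(self.roles):
                mask = self.roles == role
                out[mask] = sasa_arrays(
                    self.coords[mask], self.radii[mask],
                    self.probe, self.n_points)
            self._isolated_sasa = out
        return self._isolated_sasa

    @property
    def atom_bsa(self) -> np.ndarray:
        return self.isolated_sasa - self.complex_sasa

    def _site_mask(self, site: ResidueSite) -> np.ndarray:
        si = self.model.sites.index(site)
        return self.site_index == si

    # -- per-residue features --

    def residue_asa_bsa(self, site: ResidueSite) -> tuple[float, float]:
        mask = self._site_mask(site)
        asa = float(self.complex_sasa[mask].sum())
        bsa = float(self.atom_bsa[mask].sum())
        return asa, bsa

    def residue_solvation(self, site: ResidueSite) -> float:
        mask = self._site_mask(site)
        total = 0.0
        for k in np.flatnonzero(mask):
            atom = self._flat[k][2]
            if atom.element not in SOLVATION_ASP:
                raise FeatureError(f"no solvation parameter for {atom.element}")
            total += SOLVATION_ASP[atom.element] * self.complex_sasa[k]
        return total

    # -- complex-level features --

    def metrics(self) -> dict[str, float]:
        if self._metrics is None:
            self._metrics = self._compute_metrics()
        return self._metrics

    def _donor_acceptor_indices(self) -> tuple[set[int], set[int]]:
        donors, acceptors = set(), set()
        for k, (_, site, atom) in enumerate(self._flat):
            res3 = AA1_TO_3[site.amino_acid]
            if atom.name == "N" and res3 != "PRO":
                donors.add(k)
            if atom.name == "O":
                acceptors.add(k)
            if atom.name in HB_DONORS.get(res3, ()):
                donors.add(k)
            if atom.name in HB_ACCEPTORS.get(res3, ()):
                acceptors.add(k)
        return donors, acceptors

    def _cross_pairs(self, cutoff: float) -> list[tuple[int, int]]:
        tree = cKDTree(self.coords)
        return [
            (i, j) for i, j in tree.query_pairs(cutoff)
            if self.roles[i] != self.roles[j]
        ]

    def _compute_metrics(self) -> dict[str, float]:
        m: dict[str, float] = {}
        donors, acceptors = self._donor_acceptor_indices()

        def hbond_pairs(cutoff: float) -> list[float]:
            dists = []
            for i, j in self._cross_pairs(cutoff):
                if (i in donors and j in acceptors) or \
                   (j in donors and i in acceptors):
                    dists.append(float(np.linalg.norm(
                        self.coords[i] - self.coords[j])))
            return dists

        # hydrogen bonds at the strict and the PISA-style surrogate cutoff
        hb = hbond_pairs(HBOND_CUTOFF)
        m["hbonds"] = float(len(hb))
        m["mean_hbond_distance"] = float(np.mean(hb)) if hb else 0.0
        m["pisa_hbonds"] = float(len(hbond_pairs(PISA_HBOND_CUTOFF)))

        # charged-group contacts
        neg, pos = set(), set()
        for k, (_, site, atom) in enumerate(self._flat):
            res3 = AA1_TO_3[site.amino_acid]
            if atom.name in NEGATIVE_ATOMS.get(res3, ()):
                neg.add(k)
            if atom.name in POSITIVE_ATOMS.get(res3, ()):
                pos.add(k)
        bridge_atom_pairs = [
            (i, j) for i, j in self._cross_pairs(SALT_BRIDGE_CUTOFF)
            if (i in neg and j in pos) or (i in pos and j in neg)
        ]
        m["pisa_salt_bridges"] = float(len(bridge_atom_pairs))
        m["salt_bridges"] = float(len({
            tuple(sorted((self.site_index[i], self.site_index[j])))
            for i, j in bridge_atom_pairs
        }))

        # Cα-Cα contacts
        ca = [k for k, (_, _, a) in enumerate(self._flat) if a.name == "CA"]
        ca_set = set(ca)
        m["ca_contacts"] = float(sum(
            1 for i, j in self._cross_pairs(CA_CONTACT_CUTOFF)
            if i in ca_set and j in ca_set
        ))

        # paired hydrophilic residues (any heavy-atom contact)
        contact_res_pairs = {
            tuple(sorted((self.site_index[i], self.site_index[j])))
            for i, j in self._cross_pairs(CONTACT_CUTOFF)
        }
        m["hydrophilic_pairs"] = float(sum(
            1 for si, sj in contact_res_pairs
            if self.model.sites[si].amino_acid in HYDROPHILIC
            and self.model.sites[sj].amino_acid in HYDROPHILIC
        ))

        # atoms in contact between Fc and β2m
        b2m_atoms: set[int] = set()
        for i, j in self._cross_pairs(CONTACT_CUTOFF):
            ri, rj = self.roles[i], self.roles[j]
            if {ri, rj} == {ChainRole.FC.value, ChainRole.B2M.value}:
                b2m_atoms.update((i, j))
        m["b2m_fc_atom_contacts"] = float(len(b2m_atoms))

        # SASA-derived complex features
        atom_bsa = self.atom_bsa
        site_bsa = np.bincount(self.site_index, weights=atom_bsa,
                               minlength=len(self.model.sites))
        m["n_interface_residues"] = float(np.sum(site_bsa > INTERFACE_BSA_MIN))

        asp = np.array([SOLVATION_ASP.get(a.element, 0.0)
                        for _, _, a in self._flat])
        m["solvation_gain"] = float(np.sum(
            asp * (self.complex_sasa - self.isolated_sasa)))

        apolar = np.array([a.element in ("C", "S") for _, _, a in self._flat])
        total_bsa = float(atom_bsa.sum())
        m["hydrophobic_fraction"] = (
            float(atom_bsa[apolar].sum()) / total_bsa if total_bsa > 1e-9 else 0.0
        )
        m["binding_energy"] = -m["solvation_gain"] + 0.5 * m["hbonds"]
        return m


# --- standalone operation wrappers ------------------------------------

def per_residue_asa_bsa(model: ComplexModel, site: ResidueSite,
                        probe: float = DEFAULT_PROBE,
                        n_points: int = DEFAULT_N_POINTS) -> tuple[float, float]:
    """(ASA in the complex, area buried on complex formation), Å²."""
    return FeatureComputer(model, probe, n_points).residue_asa_bsa(site)


def solvation_energy(model: ComplexModel, site: ResidueSite,
                     probe: float = DEFAULT_PROBE,
                     n_points: int = DEFAULT_N_POINTS) -> float:
    return FeatureComputer(model, probe, n_points).residue_solvation(site)


def solvation_gain(model: ComplexModel, **kw) -> float:
    return FeatureComputer(model, **kw).metrics()["solvation_gain"]


def count_hbonds(model: ComplexModel) -> tuple[int, float]:
    m = FeatureComputer(model).metrics()
    return int(m["hbonds"]), m["mean_hbond_distance"]


def count_salt_bridges(model: ComplexModel) -> int:
    return int(FeatureComputer(model).metrics()["salt_bridges"])


def count_ca_contacts(model: ComplexModel) -> int:
    return int(FeatureComputer(model).metrics()["ca_contacts"])


def paired_hydrophilic(model: ComplexModel) -> int:
    return int(FeatureComputer(model).metrics()["hydrophilic_pairs"])


def b2m_fc_atom_contacts(model: ComplexModel) -> int:
    return int(FeatureComputer(model).metrics()["b2m_fc_atom_contacts"])


def interface_residue_count(model: ComplexModel,
                            probe: float = DEFAULT_PROBE,
                            n_points: int = DEFAULT_N_POINTS) -> int:
    fc = FeatureComputer(model, probe, n_points)
    return int(fc.metrics()["n_interface_residues"])


# --- catalog construction and extraction ------------------------------

def _per_residue_entries(role: ChainRole, number: int) -> list[FeatureEntry]:
    tag = f"{role.value}_{number}"
    sel = (role.value, number)
    return [
        FeatureEntry(f"asa_{tag}", FeatureKind.PER_RESIDUE_ASA, sel),
        FeatureEntry(f"bsa_{tag}", FeatureKind.PER_RESIDUE_BSA, sel),
        FeatureEntry(f"solv_{tag}", FeatureKind.PER_RESIDUE_SOLV, sel),
    ]


def default_catalog(model: ComplexModel,
                    fc_positions: Sequence[int] = FC_POSITIONS,
                    n_receptor_sites: int = 24,
                    receptor_sites: Sequence[tuple[str, int]] | None = None,
                    probe: float = DEFAULT_PROBE,
                    n_points: int = DEFAULT_N_POINTS) -> FeatureCatalog:
    """Build the default 147-entry catalog against a reference model:
    ASA/BSA/solvation for the 21 Fc positions, for 24 receptor-side
    positions (FcRn alpha-chain and β2m interface residues ranked by
    buried area, always including FcRn 129 when present), plus the 12
    complex-level metrics."""
    entries: list[FeatureEntry] = []
    for pos in fc_positions:
        model.site(ChainRole.FC, pos)  # raises KeyError if unresolvable
        entries.extend(_per_residue_entries(ChainRole.FC, pos))

    if receptor_sites is None:
        fc = FeatureComputer(model, probe, n_points)
        candidates = []
        for site in model.sites:
            if site.chain_role == ChainRole.FC:
                continue
            _, bsa = fc.residue_asa_bsa(site)
            candidates.append((site.chain_role, site.eu_number, bsa))
        # FcRn 129 is pinned first when present, then by buried area
        def sort_key(item):
            role, num, bsa = item
            pinned = role == ChainRole.FCRN_ALPHA and num == 129
            return (not pinned, -bsa, role.value, num)
        candidates.sort(key=sort_key)
        receptor_sites = [(r.value, n) for r, n, _ in candidates[:n_receptor_sites]]
    if len(receptor_sites) != n_receptor_sites:
        raise FeatureError(
            f"need {n_receptor_sites} receptor-side positions, "
            f"got {len(receptor_sites)}"
        )
    for role, num in receptor_sites:
        entries.extend(_per_residue_entries(ChainRole(role), num))

    entries.extend(
        FeatureEntry(name, FeatureKind.COMPLEX_LEVEL, name)
        for name in COMPLEX_METRICS
    )
    return FeatureCatalog(entries)


def extract_features(model: ComplexModel, catalog: FeatureCatalog,
                     probe: float = DEFAULT_PROBE,
                     n_points: int = DEFAULT_N_POINTS,
                     provenance: str = "") -> FeatureVector:
    """Evaluate every catalog entry on the model, in catalog order."""
    fc = FeatureComputer(model, probe, n_points)
    residue_cache: dict[tuple[str, int], tuple[float, float, float]] = {}
    values = np.empty(len(catalog))
    for k, entry in enumerate(catalog.entries):
        if entry.kind is FeatureKind.COMPLEX_LEVEL:
            values[k] = fc.metrics()[entry.selector]
            continue
        key = entry.selector
        if key not in residue_cache:
            try:
                site = model.site(ChainRole(key[0]), key[1])
            except KeyError:
                raise FeatureError(
                    f"catalog site {key[0]} {key[1]} not present in model"
                ) from None
            asa, bsa = fc.residue_asa_bsa(site)
            residue_cache[key] = (asa, bsa, fc.residue_solvation(site))
        asa, bsa, solv = residue_cache[key]
        values[k] = {
            FeatureKind.PER_RESIDUE_ASA: asa,
            FeatureKind.PER_RESIDUE_BSA: bsa,
            FeatureKind.PER_RESIDUE_SOLV: solv,
        }[entry.kind]
    return FeatureVector(values, catalog.feature_ids, provenance)
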
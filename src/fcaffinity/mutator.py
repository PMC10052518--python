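"""Mutation parsing and deterministic in-silico side-chain replacement.

Variants are written in the field's slash notation over EU numbering,
e.g. ``"M252Y/S254T/T256E"``.  Building the 3D model of a variant never
moves the backbone: the wild-type side chain beyond the beta carbon is
deleted and an ideal-geometry template of the target residue is grafted
onto the N-CA-C(-CB) frame.  The chi1 (and chi2 where present) dihedrals
are scanned on a 30-degree grid and the rotamer with the lowest
soft-sphere clash score against the rest of the complex is kept, ties
going to the first rotamer in scan order.  The procedure is fully
deterministic.
"""

from __future__ import annotations

import dataclasses
import itertools
import re
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import AA1_TO_3, CANONICAL_AA, SCANNED_CHIS, SIDE_CHAIN_ZMAT, element_of, vdw_radius
from .structure_io import Atom, ChainRole, ComplexModel, ResidueSite

# CB internal coordinates on the N-C-CA frame (ideal L-residue geometry)
CB_BOND = 1.54
CB_ANGLE = 112.8          # C-CA-CB
CB_DIHEDRAL = 120.9       # N-C-CA-CB improper

CHI_STEP = 30.0
_ENV_CUTOFF = 12.0        # Å; side chains never reach farther from CA


class MutationError(ValueError):
    """Malformed mutation string or wild-type mismatch."""


@dataclasses.dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution, e.g. ``M252Y``."""

    eu_position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.wt_aa not in CANONICAL_AA or self.mut_aa not in CANONICAL_AA:
            raise MutationError(f"non-canonical amino acid in {self}")
        if self.wt_aa == self.mut_aa:
            raise MutationError(
                f"{self.wt_aa}{self.eu_position}{self.mut_aa}: "
                "wild-type equals mutant"
            )

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.eu_position}{self.mut_aa}"


@dataclasses.dataclass(frozen=True)
class VariantSpec:
    """An unordered set of substitutions, at most one per position."""

    mutations: frozenset[Mutation]
    label: str = dataclasses.field(default="", compare=False)

    def __post_init__(self):
        positions = [m.eu_position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise MutationError("several mutations at one position")

    def sorted_mutations(self) -> list[Mutation]:
        return sorted(self.mutations)

    def positions(self) -> frozenset[int]:
        return frozenset(m.eu_position for m in self.mutations)

    def __str__(self) -> str:
        if not self.mutations:
            return "WT"
        return "/".join(str(m) for m in self.sorted_mutations())

    def __len__(self) -> int:
        return len(self.mutations)


WILD_TYPE = VariantSpec(frozenset(), label="WT")

_TOKEN_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutations(text: str, max_mutations: int = 12) -> VariantSpec:
    """Parse a slash-separated mutation string into a :class:`VariantSpec`.

    ``"WT"`` (or an equivalent empty marker) denotes the unmutated Fc.
    Raises :class:`MutationError` naming the offending token for a
    malformed entry, a duplicated position, or wt == mutant.
    """
    stripped = text.strip()
    if not stripped:
        raise MutationError("empty mutation string (use 'WT' for wild type)")
    if stripped.upper() in ("WT", "WILDTYPE", "WILD-TYPE", "NONE"):
        return WILD_TYPE
    mutations = []
    for token in stripped.split("/"):
        token = token.strip()
        m = _TOKEN_RE.match(token)
        if m is None:
            raise MutationError(f"malformed mutation token {token!r}")
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        try:
            mutations.append(Mutation(pos, wt, mut))
        except MutationError as err:
            raise MutationError(f"bad token {token!r}: {err}") from None
    spec = VariantSpec(frozenset(mutations), label=stripped)
    if len(spec) > max_mutations:
        raise MutationError(
            f"{len(spec)} mutations exceed the limit of {max_mutations}"
        )
    return spec


# --- geometry ---------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement: return the point at
    distance ``bond`` from ``c``, with angle(b, c, x) = ``angle`` and
    dihedral(a, b, c, x) = ``torsion`` (degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_side_chain(aa1: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                     chi: dict[str, float] | None = None) -> list[tuple[str, np.ndarray]]:
    """Construct ideal side-chain heavy atoms for residue type ``aa1``
    on the given backbone frame.  ``chi`` overrides the scanned chi
    angles (defaults: 180 degrees each).  Glycine returns no atoms."""
    res3 = AA1_TO_3[aa1]
    zmat = SIDE_CHAIN_ZMAT[res3]
    if aa1 == "G":
        return []
    chi = dict(chi or {})
    for name in SCANNED_CHIS[res3]:
        chi.setdefault(name, 180.0)
    pos = {"N": np.asarray(n, float), "CA": np.asarray(ca, float),
           "C": np.asarray(c, float)}
    built: list[tuple[str, np.ndarray]] = []
    cb = place_atom(pos["N"], pos["C"], pos["CA"], CB_BOND, CB_ANGLE, CB_DIHEDRAL)
    pos["CB"] = cb
    built.append(("CB", cb))
    for name, (ra, rb, rc), bond, angle, torsion in zmat:
        if isinstance(torsion, tuple):
            torsion = chi[torsion[0]] + torsion[1]
        xyz = place_atom(pos[ra], pos[rb], pos[rc], bond, angle, torsion)
        pos[name] = xyz
        built.append((name, xyz))
    return built


def clash_score(coords: np.ndarray, radii: np.ndarray,
                env_coords: np.ndarray, env_radii: np.ndarray) -> float:
    """Soft-sphere overlap: sum over cross pairs of max(0, ri+rj-d)^2."""
    if len(coords) == 0 or len(env_coords) == 0:
        return 0.0
    d = np.linalg.norm(coords[:, None, :] - env_coords[None, :, :], axis=-1)
    overlap = np.maximum(0.0, radii[:, None] + env_radii[None, :] - d)
    return float(np.sum(overlap ** 2))


def _chi_grid(res3: str) -> Iterable[dict[str, float]]:
    chis = SCANNED_CHIS[res3]
    if not chis:
        yield {}
        return
    values = np.arange(0.0, 360.0, CHI_STEP)
    for combo in itertools.product(values, repeat=len(chis)):
        yield dict(zip(chis, combo))


def apply_mutations(model: ComplexModel, spec: VariantSpec,
                    chain_role: ChainRole = ChainRole.FC) -> ComplexModel:
    """Build the variant model.  The backbone and every non-mutated
    residue are untouched; each mutated side chain is replaced by the
    clash-optimal rotamer of the target residue (see module docstring).

    Raises :class:`MutationError` if the wild-type amino acid recorded
    in the model does not match the mutation string.
    """
    out = model.copy()
    for mut in spec.sorted_mutations():
        try:
            site = out.site(chain_role, mut.eu_position)
        except KeyError:
            raise MutationError(
                f"no residue at {chain_role.value} {mut.eu_position}"
            ) from None
        if site.amino_acid != mut.wt_aa:
            raise MutationError(
                f"position {mut.eu_position}: expected wild-type "
                f"{mut.wt_aa}, found {site.amino_acid}"
            )
        _replace_side_chain(out, site, mut.mut_aa)
    return out


def _replace_side_chain(model: ComplexModel, site: ResidueSite, mut_aa: str) -> None:
    backbone = {a.name: a for a in site.atoms if a.name in ("N", "CA", "C", "O")}
    for name in ("N", "CA", "C"):
        if name not in backbone:
            raise MutationError(
                f"residue {site.eu_number} lacks backbone atom {name}"
            )
    n, ca, c = (backbone[k].coords for k in ("N", "CA", "C"))

    env_coords, env_radii = _environment(model, site)
    best: list[tuple[str, np.ndarray]] | None = None
    best_score = np.inf
    for chi in _chi_grid(AA1_TO_3[mut_aa]):
        candidate = build_side_chain(mut_aa, n, ca, c, chi)
        coords = np.array([xyz for _, xyz in candidate]).reshape(-1, 3)
        radii = np.array([vdw_radius(element_of(nm)) for nm, _ in candidate])
        score = clash_score(coords, radii, env_coords, env_radii)
        if score < best_score:  # strict: ties keep the first rotamer scanned
            best_score = score
            best = candidate
        if not SCANNED_CHIS[AA1_TO_3[mut_aa]]:
            break

    site.amino_acid = mut_aa
    site.atoms = [backbone[k] for k in ("N", "CA", "C", "O") if k in backbone]
    for name, xyz in best or []:
        element = element_of(name)
        site.atoms.append(Atom(name, element, xyz, vdw_radius(element)))


def _environment(model: ComplexModel, site: ResidueSite) -> tuple[np.ndarray, np.ndarray]:
    """All heavy atoms outside ``site`` within reach of its CA."""
    coords, radii = [], []
    for other in model.sites:
        if other is site:
            continue
        for atom in other.atoms:
            coords.append(atom.coords)
            radii.append(atom.radius)
    if not coords:
        return np.empty((0, 3)), np.empty(0)
    coords = np.array(coords)
    radii = np.array(radii)
    ca = site.atom("CA").coords
    idx = cKDTree(coords).query_ball_point(ca, _ENV_CUTOFF)
    return coords[idx], radii[idx]
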
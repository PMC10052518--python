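"""Synthetic fixtures with known ground truth.

Real Fc/FcRn affinity data and the reference co-crystal structure are
not redistributable, so every test input is generated here:

* **Toy two/three-chain complexes** with *planted* interface geometry —
  each hydrogen bond, salt bridge, Cα contact, hydrophilic pair and
  Fc/β2m atom contact is placed at an exact stated distance inside its
  cutoff, with all other cross-chain atom pairs kept outside cutoff
  plus a safety margin.  The accompanying manifest states exactly what
  the feature extractor must count.
* **A reference-like Fc/FcRn/β2m complex**: three short chains with
  the wild-type amino acids at the 21 EU interface positions (plus two
  off-catalog decoy positions, 235 and 239), full ideal-geometry side
  chains, arranged to form a broad synthetic interface.  It stands in
  for the experimental co-complex template and is labelled synthetic.
* **Variant/affinity tables**: random multi-mutation variants modeled
  on the reference-like complex, with log10 KD generated as a known
  sparse linear function of the extracted (z-scored) features plus
  Gaussian noise, a pH 6.0 minority stored as KD divided by the
  harmonization factor, and planted effective-signature duplicates.

Chains here are idealised peptide scaffolds, not folds: only the
cutoff geometry and the feature→response link are meaningful.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_curation import VariantRecord, effective_signature
from .interface_features import (
    CA_CONTACT_CUTOFF,
    CONTACT_CUTOFF,
    FC_POSITIONS,
    HBOND_CUTOFF,
    PISA_HBOND_CUTOFF,
    SALT_BRIDGE_CUTOFF,
    FeatureCatalog,
)
from .mutator import VariantSpec, build_side_chain, parse_mutations
from .structure_io import Atom, ChainRole, ComplexModel, ResidueSite
from .variant_generator import LibrarySpec, random_library
from .chemistry import element_of, vdw_radius


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------
# toy complexes with planted, exactly countable interface geometry
# ---------------------------------------------------------------------

_SLOT_SPACING = 10.0      # Å between interaction slots along x
_CHAIN_SEPARATION = 16.0  # Å between chain baselines along y
_MARGIN = 0.5             # Å clearance beyond each cutoff


@dataclasses.dataclass
class ToyGeometrySpec:
    """Planted interactions: one slot per entry, distances in Å."""

    hbond_distances: tuple[float, ...] = ()
    salt_bridge_distances: tuple[float, ...] = ()      # (3.5, 4.0]
    ca_contact_distances: tuple[float, ...] = ()
    hydrophilic_distances: tuple[float, ...] = ()
    b2m_contact_distances: tuple[float, ...] = ()
    pad_fc: int = 2
    pad_fcrn: int = 2
    pad_b2m: int = 0

    def validate(self) -> None:
        for d in self.hbond_distances:
            if not 2.0 <= d <= HBOND_CUTOFF:
                raise SyntheticError(f"H-bond distance {d} outside (2.0, 3.5]")
        for d in self.salt_bridge_distances:
            if not HBOND_CUTOFF < d <= SALT_BRIDGE_CUTOFF:
                raise SyntheticError(
                    f"salt-bridge distance {d} must lie in (3.5, 4.0] so it "
                    "cannot double-count as a hydrogen bond")
        for d in self.ca_contact_distances:
            if not 2.0 <= d <= CA_CONTACT_CUTOFF:
                raise SyntheticError(f"Cα distance {d} outside (2.0, 4.0]")
        for d in self.hydrophilic_distances:
            if not 2.0 <= d <= CONTACT_CUTOFF:
                raise SyntheticError(f"contact distance {d} outside (2.0, 4.0]")
        for d in self.b2m_contact_distances:
            if not 2.0 <= d <= CONTACT_CUTOFF:
                raise SyntheticError(f"contact distance {d} outside (2.0, 4.0]")


@dataclasses.dataclass
class ToyComplexManifest:
    """What the feature extractor must find on the emitted structure."""

    hbonds: int
    mean_hbond_distance: float
    salt_bridges: int
    pisa_hbonds: int
    pisa_salt_bridges: int
    ca_contacts: int
    hydrophilic_pairs: int
    b2m_fc_atom_contacts: int
    n_interface_residues: int
    residues_per_chain: dict[str, int]
    interface_sites: list[tuple[str, int]]

    def counts(self) -> dict[str, float]:
        return {
            "hbonds": float(self.hbonds),
            "mean_hbond_distance": self.mean_hbond_distance,
            "salt_bridges": float(self.salt_bridges),
            "pisa_hbonds": float(self.pisa_hbonds),
            "pisa_salt_bridges": float(self.pisa_salt_bridges),
            "ca_contacts": float(self.ca_contacts),
            "hydrophilic_pairs": float(self.hydrophilic_pairs),
            "b2m_fc_atom_contacts": float(self.b2m_fc_atom_contacts),
            "n_interface_residues": float(self.n_interface_residues),
        }


def _plain_residue(aa: str, x: float, y: float, flip: bool) -> list[tuple[str, np.ndarray]]:
    """Minimal backbone at baseline y; O offset in z keeps atoms distinct."""
    s = -1.0 if flip else 1.0
    return [
        ("N", np.array([x, y, 0.0])),
        ("CA", np.array([x + 1.5, y, 0.0])),
        ("C", np.array([x + 3.0, y, 0.0])),
        ("O", np.array([x + 3.0, y + 0.4 * s, 1.2])),
    ]


def _mk_site(role: ChainRole, number: int, aa: str,
             atoms: list[tuple[str, np.ndarray]]) -> ResidueSite:
    return ResidueSite(role, number, aa, [
        Atom(name, element_of(name), xyz, vdw_radius(element_of(name)))
        for name, xyz in atoms
    ])


def make_toy_complex(spec: ToyGeometrySpec | None = None,
                     seed: int = 0) -> tuple[str, ToyComplexManifest, ComplexModel]:
    """Build a toy complex with exactly the planted interactions.

    Returns (PDB text, manifest, model).  Construction is fully
    deterministic; ``seed`` is accepted for interface uniformity but
    the geometry does not depend on it.

    Layout: each planted interaction occupies its own slot along x
    (10 Å apart), the participating "tip" atoms meet midway between the
    two chain baselines (16 Å apart in y) at the stated distance, and
    every other cross-chain atom pair stays beyond cutoff + 0.5 Å.
    Planted residues carry only the atoms the interaction needs, so
    each count is attributable by construction.  Known couplings are
    folded into the manifest: Ser-Ser hydrogen-bond pairs and
    Lys-Asp salt bridges are also hydrophilic contact pairs, and salt
    bridges closer than the permissive hydrogen-bond cutoff also count
    there.
    """
    spec = spec or ToyGeometrySpec()
    spec.validate()
    D = _CHAIN_SEPARATION

    fc_sites: list[ResidueSite] = []
    fcrn_sites: list[ResidueSite] = []
    b2m_sites: list[ResidueSite] = []
    interface_sites: list[tuple[str, int]] = []
    slot = 0

    def tip_pair(d: float) -> tuple[float, float]:
        return (D - d) / 2.0, (D + d) / 2.0

    def add_pair(kind: str, d: float):
        nonlocal slot
        x = slot * _SLOT_SPACING
        slot += 1
        ya, yb = tip_pair(d)
        na, nb = len(fc_sites) + 1, len(fcrn_sites) + 1
        if kind == "hbond":       # Ser OG ··· Ser OG
            a = _plain_residue("S", x, 0.0, False)
            a += [("CB", np.array([x + 1.5, 3.0, 0.0])),
                  ("OG", np.array([x + 1.5, ya, 0.0]))]
            b = _plain_residue("S", x, D, True)
            b += [("CB", np.array([x + 1.5, D - 3.0, 0.0])),
                  ("OG", np.array([x + 1.5, yb, 0.0]))]
            fc_sites.append(_mk_site(ChainRole.FC, na, "S", a))
            fcrn_sites.append(_mk_site(ChainRole.FCRN_ALPHA, nb, "S", b))
        elif kind == "salt":      # Lys NZ ··· Asp OD1
            a = _plain_residue("K", x, 0.0, False)
            a += [("CB", np.array([x + 1.5, 3.0, 0.0])),
                  ("NZ", np.array([x + 1.5, ya, 0.0]))]
            b = _plain_residue("D", x, D, True)
            b += [("CB", np.array([x + 1.5, D - 3.0, 0.0])),
                  ("OD1", np.array([x + 1.5, yb, 0.0]))]
            fc_sites.append(_mk_site(ChainRole.FC, na, "K", a))
            fcrn_sites.append(_mk_site(ChainRole.FCRN_ALPHA, nb, "D", b))
        elif kind == "ca":        # Gly with displaced Cα
            a = [("N", np.array([x, 0.0, 0.0])),
                 ("CA", np.array([x + 1.5, ya, 0.0])),
                 ("C", np.array([x + 3.0, 0.0, 0.0])),
                 ("O", np.array([x + 3.0, 0.4, 1.2]))]
            b = [("N", np.array([x, D, 0.0])),
                 ("CA", np.array([x + 1.5, yb, 0.0])),
                 ("C", np.array([x + 3.0, D, 0.0])),
                 ("O", np.array([x + 3.0, D - 0.4, 1.2]))]
            fc_sites.append(_mk_site(ChainRole.FC, na, "G", a))
            fcrn_sites.append(_mk_site(ChainRole.FCRN_ALPHA, nb, "G", b))
        elif kind == "phil":      # Asn CG ··· Asn CG (carbon: no H-bond)
            a = _plain_residue("N", x, 0.0, False)
            a += [("CB", np.array([x + 1.5, 3.0, 0.0])),
                  ("CG", np.array([x + 1.5, ya, 0.0]))]
            b = _plain_residue("N", x, D, True)
            b += [("CB", np.array([x + 1.5, D - 3.0, 0.0])),
                  ("CG", np.array([x + 1.5, yb, 0.0]))]
            fc_sites.append(_mk_site(ChainRole.FC, na, "N", a))
            fcrn_sites.append(_mk_site(ChainRole.FCRN_ALPHA, nb, "N", b))
        elif kind == "b2m":       # Ala CB ··· Ala CB on the β2m chain
            a = _plain_residue("A", x, 0.0, False)
            a += [("CB", np.array([x + 1.5, -ya, 0.0]))]
            c = _plain_residue("A", x, -D, True)
            c += [("CB", np.array([x + 1.5, -yb, 0.0]))]
            nc = len(b2m_sites) + 1
            fc_sites.append(_mk_site(ChainRole.FC, na, "A", a))
            b2m_sites.append(_mk_site(ChainRole.B2M, nc, "A", c))
            interface_sites.append((ChainRole.FC.value, na))
            interface_sites.append((ChainRole.B2M.value, nc))
            return
        interface_sites.append((ChainRole.FC.value, na))
        interface_sites.append((ChainRole.FCRN_ALPHA.value, nb))

    for d in spec.hbond_distances:
        add_pair("hbond", d)
    for d in spec.salt_bridge_distances:
        add_pair("salt", d)
    for d in spec.ca_contact_distances:
        add_pair("ca", d)
    for d in spec.hydrophilic_distances:
        add_pair("phil", d)
    for d in spec.b2m_contact_distances:
        add_pair("b2m", d)

    for _ in range(spec.pad_fc):
        x = slot * _SLOT_SPACING
        slot += 1
        fc_sites.append(_mk_site(ChainRole.FC, len(fc_sites) + 1, "A",
                                 _plain_residue("A", x, 0.0, False)
                                 + [("CB", np.array([x + 1.5, 1.5, 0.0]))]))
    for _ in range(spec.pad_fcrn):
        x = slot * _SLOT_SPACING
        slot += 1
        fcrn_sites.append(_mk_site(ChainRole.FCRN_ALPHA, len(fcrn_sites) + 1, "A",
                                   _plain_residue("A", x, D, True)
                                   + [("CB", np.array([x + 1.5, D - 1.5, 0.0]))]))
    for _ in range(spec.pad_b2m):
        x = slot * _SLOT_SPACING
        slot += 1
        b2m_sites.append(_mk_site(ChainRole.B2M, len(b2m_sites) + 1, "A",
                                  _plain_residue("A", x, -D, True)
                                  + [("CB", np.array([x + 1.5, -D + 1.5, 0.0]))]))

    if not fc_sites or not fcrn_sites:
        raise SyntheticError("toy complex needs at least Fc and FcRn residues")

    chain_map = {"A": ChainRole.FC, "B": ChainRole.FCRN_ALPHA}
    sites = fc_sites + fcrn_sites
    if b2m_sites:
        chain_map["C"] = ChainRole.B2M
        sites = sites + b2m_sites
    model = ComplexModel(sites, chain_map, source_id="synthetic-toy")

    n_hb = len(spec.hbond_distances)
    n_sb = len(spec.salt_bridge_distances)
    n_sb_pisa_hb = sum(1 for d in spec.salt_bridge_distances
                       if d <= PISA_HBOND_CUTOFF)
    manifest = ToyComplexManifest(
        hbonds=n_hb,
        mean_hbond_distance=(float(np.mean(spec.hbond_distances))
                             if n_hb else 0.0),
        salt_bridges=n_sb,
        pisa_hbonds=n_hb + n_sb_pisa_hb,
        pisa_salt_bridges=n_sb,
        ca_contacts=len(spec.ca_contact_distances),
        hydrophilic_pairs=len(spec.hydrophilic_distances) + n_hb + n_sb,
        b2m_fc_atom_contacts=2 * len(spec.b2m_contact_distances),
        n_interface_residues=len(interface_sites),
        residues_per_chain={
            "A": len(fc_sites), "B": len(fcrn_sites),
            **({"C": len(b2m_sites)} if b2m_sites else {}),
        },
        interface_sites=interface_sites,
    )
    from .structure_io import write_complex
    return write_complex(model), manifest, model


# ---------------------------------------------------------------------
# reference-like Fc/FcRn/β2m complex
# ---------------------------------------------------------------------

# Wild-type amino acids at the modeled Fc positions (EU numbering),
# plus the two off-catalog decoy positions 235/239 used to plant
# effective-signature duplicates.
WT_FC: dict[int, str] = {
    235: "L", 239: "S",
    251: "L", 252: "M", 253: "I", 254: "S", 255: "R", 256: "T", 257: "P",
    285: "H", 286: "N", 288: "K",
    307: "T", 308: "V", 309: "L", 310: "H", 311: "Q", 314: "L",
    428: "M", 433: "H", 434: "N", 435: "H", 436: "Y",
}

_FCRN_SEQ = "EWSHLQKNDYTVRFGE"        # FcRn alpha positions 120..135
_FCRN_START = 120
_B2M_SEQ = "KQDNSYTE"                 # β2m positions 1..8

# ideal backbone template, CA at origin, side chains extending +y
_BB_TEMPLATE = {
    "N": np.array([-0.676, 0.0, -1.294]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.500, 0.0, -0.174]),
    "O": np.array([2.031, -0.011, -1.291]),
}


def _scaffold_residue(aa: str, number: int, role: ChainRole,
                      origin: np.ndarray, flip: bool) -> ResidueSite:
    # 180° rotation about x (chirality-preserving) points side chains
    # the other way along y; the plain template points them toward -y.
    orient = np.array([1.0, -1.0, -1.0]) if flip else np.array([1.0, 1.0, 1.0])
    atoms: list[tuple[str, np.ndarray]] = []
    frame = {}
    for name, offset in _BB_TEMPLATE.items():
        xyz = origin + offset * orient
        frame[name] = xyz
        atoms.append((name, xyz))
    side = build_side_chain(aa, frame["N"], frame["CA"], frame["C"])
    atoms.extend(side)
    return _mk_site(role, number, aa, atoms)


def make_fc_complex() -> ComplexModel:
    """Synthetic stand-in for the Fc/FcRn/β2m reference co-complex.

    Three idealised chains: an Fc chain carrying the wild-type residues
    of :data:`WT_FC`, a 16-residue FcRn alpha chain (author numbering
    120-135, including position 129) and an 8-residue β2m chain, laid
    out so the receptor chains face the Fc across an 8 Å interface.
    Deterministic; every catalog position resolves.
    """
    spacing = 5.0
    gap = 6.5
    fc_sites = []
    for i, pos in enumerate(sorted(WT_FC)):
        fc_sites.append(_scaffold_residue(
            WT_FC[pos], pos, ChainRole.FC,
            np.array([i * spacing, 0.0, 0.0]), flip=True))
    fcrn_sites = []
    for i, aa in enumerate(_FCRN_SEQ):
        fcrn_sites.append(_scaffold_residue(
            aa, _FCRN_START + i, ChainRole.FCRN_ALPHA,
            np.array([(i + 1.0) * spacing + 0.7, gap, 1.2]), flip=False))
    b2m_sites = []
    n_fcrn = len(_FCRN_SEQ)
    for i, aa in enumerate(_B2M_SEQ):
        b2m_sites.append(_scaffold_residue(
            aa, i + 1, ChainRole.B2M,
            np.array([(n_fcrn + 1.5 + i) * spacing + 0.7, gap, 1.2]),
            flip=False))
    return ComplexModel(
        fc_sites + fcrn_sites + b2m_sites,
        {"A": ChainRole.FC, "B": ChainRole.FCRN_ALPHA, "C": ChainRole.B2M},
        source_id="synthetic-fc-fcrn",
    )


# ---------------------------------------------------------------------
# synthetic variant/affinity tables
# ---------------------------------------------------------------------

# default sparse truth: weights on z-scored features
DEFAULT_TRUTH_WEIGHTS = {
    "bsa_FC_434": -0.8,
    "asa_FC_255": 0.6,
    "bsa_FC_252": -0.5,
    "hbonds": -0.4,
    "hydrophilic_pairs": 0.3,
}


@dataclasses.dataclass
class SyntheticTruth:
    """Generative parameters of a synthetic affinity table."""

    n_records: int = 500
    sigma: float = 0.15              # log10 KD units
    weights: dict[str, float] | None = None
    intercept: float = -7.0          # typical log10 KD scale
    ph6_fraction: float = 0.15       # minority reported at pH 6 only
    n_duplicate_pairs: int = 5
    n_mutations: tuple[int, int] = (1, 3)
    harmonization_factor: float = 68.0
    seed: int = 0

    def resolved_weights(self) -> dict[str, float]:
        return dict(self.weights or DEFAULT_TRUTH_WEIGHTS)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["weights"] = self.resolved_weights()
        return json.dumps(d, indent=2)


_DECOYS = ("L235R", "S239K")


@dataclasses.dataclass
class SyntheticDataset:
    """A generated table plus everything needed to assert against it."""

    records: list[VariantRecord]
    specs: list[VariantSpec]                 # the unique primary variants
    features: pd.DataFrame                   # raw features, one row/variant
    y: np.ndarray                            # log10 KD (pH 7 scale), w/ noise
    truth: SyntheticTruth
    column_means: pd.Series
    column_stds: pd.Series
    ph6_signatures: list[str]
    duplicate_signatures: list[str]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mutations": [str(r.spec) for r in self.records],
            "kd_molar": [r.kd for r in self.records],
            "ph": [r.ph for r in self.records],
            "method": [r.method for r in self.records],
            "binder_flag": [r.binder_flag for r in self.records],
        })

    def zscores(self, features: pd.DataFrame) -> pd.DataFrame:
        stds = self.column_stds.replace(0.0, 1.0)
        return (features - self.column_means) / stds

    def truth_response(self, features: pd.DataFrame) -> np.ndarray:
        """Noise-free log10 KD under the planted linear truth."""
        z = self.zscores(features)
        w = self.truth.resolved_weights()
        out = np.full(len(features), self.truth.intercept)
        for fid, weight in w.items():
            out += weight * z[fid].to_numpy()
        return out


def _variant_features(reference: ComplexModel, catalog: FeatureCatalog,
                      specs: Sequence[VariantSpec]) -> pd.DataFrame:
    from .learning import variant_feature_table
    return variant_feature_table(reference, catalog, specs)


def make_variant_table(truth: SyntheticTruth,
                       reference: ComplexModel,
                       catalog: FeatureCatalog) -> SyntheticDataset:
    """Generate a variant/affinity table with known generative truth.

    Unique variants are drawn over the 21 Fc positions, modeled with
    the real mutator and featurizer, and assigned
    ``log10 KD = intercept + w · z(features) + N(0, sigma)``.
    A seeded minority is stored as pH 6.0 ELISA records with KD divided
    by the harmonization factor (so curation must invert it), and
    ``n_duplicate_pairs`` extra records replicate existing pH 7.0
    variants with an off-catalog decoy mutation added — effective
    duplicates that deduplication must remove.
    """
    rng = np.random.default_rng(truth.seed)
    wt = {pos: WT_FC[pos] for pos in FC_POSITIONS}
    specs = random_library(
        LibrarySpec(n_variants=truth.n_records, n_mutations=truth.n_mutations,
                    positions=FC_POSITIONS, seed=truth.seed),
        wt)
    features = _variant_features(reference, catalog, specs)

    weights = truth.resolved_weights()
    means = features.mean(axis=0)
    stds = features.std(axis=0, ddof=0)
    for fid in weights:
        if fid not in features.columns:
            raise SyntheticError(f"truth weight on unknown feature {fid!r}")
        if stds[fid] <= 1e-9:
            raise SyntheticError(
                f"feature {fid!r} is constant in the sample; the planted "
                "truth would be unidentifiable")
    z = (features - means) / stds.replace(0.0, 1.0)
    y = np.full(len(specs), truth.intercept)
    for fid, w in weights.items():
        y += w * z[fid].to_numpy()
    y += rng.normal(0.0, truth.sigma, size=len(specs))

    n_ph6 = int(round(truth.ph6_fraction * len(specs)))
    ph6_idx = set(rng.choice(len(specs), size=n_ph6, replace=False).tolist())

    records: list[VariantRecord] = []
    ph6_signatures: list[str] = []
    for i, spec in enumerate(specs):
        kd7 = 10.0 ** y[i]
        if i in ph6_idx:
            records.append(VariantRecord(
                spec, kd7 / truth.harmonization_factor, 6.0, "ELISA"))
            ph6_signatures.append(str(spec))
        else:
            records.append(VariantRecord(spec, kd7, 7.0, "SPR"))

    duplicate_signatures: list[str] = []
    ph7_indices = [i for i in range(len(specs)) if i not in ph6_idx]
    if truth.n_duplicate_pairs > len(ph7_indices):
        raise SyntheticError("not enough pH 7 records to plant duplicates")
    for k in range(truth.n_duplicate_pairs):
        i = ph7_indices[k]
        decoy = next(iter(parse_mutations(_DECOYS[k % len(_DECOYS)]).mutations))
        twin = VariantSpec(specs[i].mutations | {decoy})
        records.append(VariantRecord(twin, 10.0 ** y[i], 7.0, "SPR"))
        duplicate_signatures.append(
            effective_signature(specs[i], FC_POSITIONS))

    return SyntheticDataset(
        records=records, specs=specs, features=features, y=y, truth=truth,
        column_means=means, column_stds=stds,
        ph6_signatures=ph6_signatures,
        duplicate_signatures=duplicate_signatures,
    )


def truth_effect(dataset: SyntheticDataset, reference: ComplexModel,
                 catalog: FeatureCatalog, spec: VariantSpec) -> float:
    """Noise-free change in log10 KD of ``spec`` relative to wild type
    under the dataset's planted truth function."""
    feats = _variant_features(reference, catalog, [spec, VariantSpec(frozenset())])
    resp = dataset.truth_response(feats)
    return float(resp[0] - resp[1])


def make_singles_table(dataset: SyntheticDataset, reference: ComplexModel,
                       catalog: FeatureCatalog,
                       targets: Mapping[int, Sequence[str]] | None = None
                       ) -> dict[str, float]:
    """Exact single-mutation effects (Δ log10 KD vs wild type) under the
    planted truth, for feeding the constrained library generator.

    ``targets`` maps position → candidate amino acids; the default
    evaluates three representative substitutions per position.
    """
    if targets is None:
        targets = {pos: [a for a in ("A", "Y", "E") if a != WT_FC[pos]][:2]
                   for pos in FC_POSITIONS}
    specs = []
    tokens = []
    for pos, aas in sorted(targets.items()):
        for aa in aas:
            if aa == WT_FC[pos]:
                continue
            token = f"{WT_FC[pos]}{pos}{aa}"
            tokens.append(token)
            specs.append(parse_mutations(token))
    feats = _variant_features(reference, catalog,
                              specs + [VariantSpec(frozenset())])
    resp = dataset.truth_response(feats)
    wt_resp = resp[-1]
    return {tok: float(r - wt_resp) for tok, r in zip(tokens, resp[:-1])}
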
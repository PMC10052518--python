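import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fcaffinity.chemistry import element_of, vdw_radius
from fcaffinity.interface_features import (
    FeatureComputer,
    FeatureError,
    FeatureCatalog,
    extract_features,
    per_residue_asa_bsa,
)
from fcaffinity.structure_io import Atom, ChainRole, ComplexModel, ResidueSite
from fcaffinity.synthetic_data import ToyGeometrySpec, make_toy_complex


def _atom(name, xyz):
    return Atom(name, element_of(name), np.array(xyz, float),
                vdw_radius(element_of(name)))


def _residue(role, number, aa, named_coords):
    return ResidueSite(role, number, aa,
                       [_atom(n, c) for n, c in named_coords])


def _backbone(x, y):
    return [("N", [x, y, 0.0]), ("CA", [x + 1.5, y, 0.0]),
            ("C", [x + 3.0, y, 0.0]), ("O", [x + 3.0, y + 0.4, 1.2])]


def two_residue_model(aa_a, extra_a, aa_b, extra_b):
    """One residue per chain, baselines 16 Å apart, plus tip atoms."""
    a = _residue(ChainRole.FC, 1, aa_a, _backbone(0.0, 0.0) + extra_a)
    b = _residue(ChainRole.FCRN_ALPHA, 1, aa_b, _backbone(0.0, 16.0) + extra_b)
    return ComplexModel([a, b], {"A": ChainRole.FC, "B": ChainRole.FCRN_ALPHA})


class TestPlantedGeometry:
    def test_all_manifest_counts_recovered(self, toy_bundle):
        _, manifest, model = toy_bundle
        metrics = FeatureComputer(model).metrics()
        for key, expected in manifest.counts().items():
            assert metrics[key] == pytest.approx(expected, abs=1e-9), key

    def test_all_zero_spec_has_silent_interface(self):
        _, manifest, model = make_toy_complex(
            ToyGeometrySpec(pad_fc=3, pad_fcrn=3))
        metrics = FeatureComputer(model).metrics()
        for key in ("hbonds", "salt_bridges", "ca_contacts",
                    "hydrophilic_pairs", "b2m_fc_atom_contacts",
                    "n_interface_residues", "mean_hbond_distance"):
            assert metrics[key] == 0.0, key

    def test_interface_membership_matches_manifest(self, toy_bundle):
        _, manifest, model = toy_bundle
        fc = FeatureComputer(model)
        flagged = []
        for site in model.sites:
            _, bsa = fc.residue_asa_bsa(site)
            if bsa > 0.1:
                flagged.append((site.chain_role.value, site.eu_number))
        assert sorted(flagged) == sorted(manifest.interface_sites)


class TestHydrogenBonds:
    def test_single_pair_inside_cutoff(self):
        model = two_residue_model(
            "S", [("CB", [1.5, 3.0, 0.0]), ("OG", [1.5, 6.55, 0.0])],
            "S", [("CB", [1.5, 13.0, 0.0]), ("OG", [1.5, 9.45, 0.0])])
        m = FeatureComputer(model).metrics()
        assert m["hbonds"] == 1
        assert m["mean_hbond_distance"] == pytest.approx(2.9, abs=1e-9)

    def test_pair_beyond_cutoff_not_counted(self):
        model = two_residue_model(
            "S", [("CB", [1.5, 3.0, 0.0]), ("OG", [1.5, 6.2, 0.0])],
            "S", [("CB", [1.5, 13.0, 0.0]), ("OG", [1.5, 9.8, 0.0])])
        m = FeatureComputer(model).metrics()
        assert m["hbonds"] == 0
        assert m["mean_hbond_distance"] == 0.0

    def test_three_planted_pairs_mean(self):
        _, manifest, model = make_toy_complex(
            ToyGeometrySpec(hbond_distances=(2.8, 3.0, 3.2)))
        m = FeatureComputer(model).metrics()
        assert m["hbonds"] == 3
        assert m["mean_hbond_distance"] == pytest.approx(3.0, abs=1e-9)

    def test_carbon_contact_is_not_a_bond(self):
        model = two_residue_model(
            "A", [("CB", [1.5, 6.55, 0.0])],
            "A", [("CB", [1.5, 9.45, 0.0])])
        assert FeatureComputer(model).metrics()["hbonds"] == 0


class TestSaltBridges:
    def test_one_bridge_counted_once_per_residue_pair(self):
        # both carboxylate oxygens inside 4.0 Å of NZ: still one bridge
        model = two_residue_model(
            "K", [("NZ", [1.5, 6.0, 0.0])],
            "D", [("CG", [1.5, 10.5, 0.0]),
                  ("OD1", [1.5, 9.6, 0.0]), ("OD2", [2.3, 9.7, 0.6])])
        m = FeatureComputer(model).metrics()
        assert m["salt_bridges"] == 1
        assert m["pisa_salt_bridges"] == 2  # atom-pair surrogate counts both

    def test_pair_beyond_cutoff(self):
        model = two_residue_model(
            "K", [("NZ", [1.5, 5.9, 0.0])],
            "D", [("OD1", [1.5, 10.1, 0.0])])
        assert FeatureComputer(model).metrics()["salt_bridges"] == 0

    def test_uncharged_polar_pair_is_not_a_bridge(self):
        model = two_residue_model(
            "S", [("OG", [1.5, 6.55, 0.0])],
            "S", [("OG", [1.5, 9.45, 0.0])])
        assert FeatureComputer(model).metrics()["salt_bridges"] == 0


class TestContacts:
    def test_hydrophilic_pair_requires_both_hydrophilic(self):
        leu_ser = two_residue_model(
            "L", [("CB", [1.5, 6.2, 0.0])],
            "S", [("OG", [1.5, 9.8, 0.0])])
        assert FeatureComputer(leu_ser).metrics()["hydrophilic_pairs"] == 0
        ser_asn = two_residue_model(
            "S", [("OG", [1.5, 6.2, 0.0])],
            "N", [("CG", [1.5, 9.8, 0.0])])
        assert FeatureComputer(ser_asn).metrics()["hydrophilic_pairs"] == 1

    def test_ca_contacts_symmetric_under_role_swap(self):
        _, _, model = make_toy_complex(
            ToyGeometrySpec(ca_contact_distances=(3.8, 3.9)))
        swapped = model.copy()
        for site in swapped.sites:
            site.chain_role = {
                ChainRole.FC: ChainRole.FCRN_ALPHA,
                ChainRole.FCRN_ALPHA: ChainRole.FC,
            }[site.chain_role]
        swapped.chain_map = {"A": ChainRole.FCRN_ALPHA, "B": ChainRole.FC}
        a = FeatureComputer(model).metrics()["ca_contacts"]
        b = FeatureComputer(swapped).metrics()["ca_contacts"]
        assert a == b == 2

    def test_b2m_contact_counts_endpoint_atoms(self):
        _, _, model = make_toy_complex(
            ToyGeometrySpec(b2m_contact_distances=(3.8, 3.5)))
        assert FeatureComputer(model).metrics()["b2m_fc_atom_contacts"] == 4

    def test_b2m_count_monotone_in_added_contacts(self):
        _, _, small = make_toy_complex(
            ToyGeometrySpec(b2m_contact_distances=(3.8,)))
        _, _, large = make_toy_complex(
            ToyGeometrySpec(b2m_contact_distances=(3.8, 3.5)))
        assert (FeatureComputer(large).metrics()["b2m_fc_atom_contacts"]
                > FeatureComputer(small).metrics()["b2m_fc_atom_contacts"])


class TestSurfaceFeatures:
    def test_separated_residue_has_zero_bsa(self, toy_bundle):
        _, manifest, model = toy_bundle
        interface = set(map(tuple, manifest.interface_sites))
        outside = [s for s in model.sites
                   if (s.chain_role.value, s.eu_number) not in interface]
        fc = FeatureComputer(model)
        for site in outside[:3]:
            _, bsa = fc.residue_asa_bsa(site)
            assert abs(bsa) < 1e-9

    def test_bsa_additivity(self, toy_bundle):
        _, _, model = toy_bundle
        fc = FeatureComputer(model)
        total_by_residue = sum(fc.residue_asa_bsa(s)[1] for s in model.sites)
        direct = fc.isolated_sasa.sum() - fc.complex_sasa.sum()
        assert total_by_residue == pytest.approx(direct, rel=1e-6)

    def test_complex_sasa_bounded_by_isolated(self, toy_bundle):
        _, _, model = toy_bundle
        fc = FeatureComputer(model)
        assert fc.complex_sasa.sum() <= fc.isolated_sasa.sum() + 1e-9
        assert np.all(fc.atom_bsa >= -1e-9)

    def test_solvation_linearity_and_buried_zero(self, toy_bundle):
        _, _, model = toy_bundle
        fc = FeatureComputer(model)
        site = model.sites[0]
        base = fc.residue_solvation(site)
        import fcaffinity.chemistry as chem
        doubled = {k: 2 * v for k, v in chem.SOLVATION_ASP.items()}
        original = chem.SOLVATION_ASP.copy()
        try:
            chem.SOLVATION_ASP.update(doubled)
            fc2 = FeatureComputer(model.copy())
            assert fc2.residue_solvation(fc2.model.sites[0]) == \
                pytest.approx(2 * base, rel=1e-9)
        finally:
            chem.SOLVATION_ASP.clear()
            chem.SOLVATION_ASP.update(original)

    def test_solvation_matches_hand_sum(self):
        # one isolated Ser: energy must equal sum of ASP(element)*area
        from fcaffinity.chemistry import SOLVATION_ASP
        from fcaffinity.interface_features import sasa
        site = _residue(ChainRole.FC, 1, "S",
                        _backbone(0.0, 0.0) + [("OG", [1.5, 2.0, 0.0])])
        other = _residue(ChainRole.FCRN_ALPHA, 1, "G", _backbone(0.0, 40.0))
        model = ComplexModel([site, other],
                             {"A": ChainRole.FC, "B": ChainRole.FCRN_ALPHA})
        fc = FeatureComputer(model)
        areas = sasa(site.atoms)
        expected = sum(SOLVATION_ASP[a.element] * ar
                       for a, ar in zip(site.atoms, areas))
        assert fc.residue_solvation(site) == pytest.approx(expected, rel=1e-9)


class TestCatalog:
    def test_default_catalog_has_147_features(self, catalog):
        assert len(catalog) == 147

    def test_extraction_is_deterministic(self, reference, catalog):
        a = extract_features(reference, catalog)
        b = extract_features(reference, catalog)
        np.testing.assert_array_equal(a.values, b.values)

    def test_permuting_catalog_permutes_values(self, reference, catalog):
        vec = extract_features(reference, catalog)
        perm = np.random.default_rng(0).permutation(len(catalog))
        permuted = FeatureCatalog([catalog.entries[i] for i in perm])
        vec_p = extract_features(reference, permuted)
        np.testing.assert_allclose(vec_p.values, vec.values[perm])

    def test_unresolvable_site_names_it(self, toy_bundle, catalog):
        _, _, toy = toy_bundle
        with pytest.raises(FeatureError, match="FC 251"):
            extract_features(toy, catalog)

    def test_catalog_round_trips_through_dict(self, catalog):
        again = FeatureCatalog.from_dict(catalog.to_dict())
        assert again.feature_ids == catalog.feature_ids

    def test_fcrn_129_pinned_in_receptor_sites(self, catalog):
        assert "bsa_FCRN_ALPHA_129" in catalog.feature_ids

    def test_count_features_are_integral(self, toy_bundle):
        _, _, model = toy_bundle
        m = FeatureComputer(model).metrics()
        for key in ("hbonds", "salt_bridges", "ca_contacts",
                    "hydrophilic_pairs", "b2m_fc_atom_contacts",
                    "pisa_hbonds", "pisa_salt_bridges",
                    "n_interface_residues"):
            assert m[key] == int(m[key]) and m[key] >= 0


class TestRigidMotionInvariance:
    def _transform(self, model, rot, shift):
        out = model.copy()
        R = rot.as_matrix()
        for site in out.sites:
            for atom in site.atoms:
                atom.coords = R @ atom.coords + shift
        return out

    def test_counts_exactly_invariant(self, toy_bundle):
        _, _, model = toy_bundle
        rot = Rotation.from_euler("xyz", [17.0, -42.0, 99.0], degrees=True)
        moved = self._transform(model, rot, np.array([5.0, -3.0, 11.0]))
        a = FeatureComputer(model).metrics()
        b = FeatureComputer(moved).metrics()
        for key in ("hbonds", "salt_bridges", "ca_contacts",
                    "hydrophilic_pairs", "b2m_fc_atom_contacts",
                    "n_interface_residues"):
            assert a[key] == b[key], key
        assert a["mean_hbond_distance"] == pytest.approx(
            b["mean_hbond_distance"], abs=1e-9)

    def test_surface_features_invariant_to_quadrature_tolerance(self, toy_bundle):
        # the spiral point set is axis-fixed, so rotation moves the
        # quadrature grid relative to the molecule: areas agree to the
        # quadrature resolution, not machine precision
        _, _, model = toy_bundle
        rot = Rotation.from_euler("xyz", [17.0, -42.0, 99.0], degrees=True)
        moved = self._transform(model, rot, np.array([5.0, -3.0, 11.0]))
        a = FeatureComputer(model)
        b = FeatureComputer(moved)
        assert a.complex_sasa.sum() == pytest.approx(
            b.complex_sasa.sum(), rel=2e-3)
        site_a = model.sites[0]
        site_b = moved.sites[0]
        asa_a, _ = a.residue_asa_bsa(site_a)
        asa_b, _ = b.residue_asa_bsa(site_b)
        assert asa_a == pytest.approx(asa_b, rel=2e-2, abs=0.5)


def test_per_residue_wrapper_matches_computer(toy_bundle):
    _, _, model = toy_bundle
    site = model.sites[0]
    assert per_residue_asa_bsa(model, site) == \
        pytest.approx(FeatureComputer(model).residue_asa_bsa(site))
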
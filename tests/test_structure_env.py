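"""Geometry oracles: microenvironment vs exhaustive scan, rigid invariance, RSA."""

import numpy as np
import pytest

from sapgo.errors import MappingError
from sapgo.io_formats import (
    AccessibilityRecord,
    Residue,
    StructureModel,
    VariantRecord,
)
from sapgo.residues import AA_INDEX, MAX_ASA_GXG, THREE_TO_ONE
from sapgo.structure_env import (
    ResidueHandle,
    compute_accessibility,
    map_variant_to_structure,
    relative_accessibility,
    structural_environment,
)
from sapgo.synthetic_fixtures import toy_structure


def _model(coords_names):
    residues = [
        Residue(number=i + 1, icode=" ", name=name, atoms={"CA": np.asarray(c, float)})
        for i, (c, name) in enumerate(coords_names)
    ]
    return StructureModel(chains={"A": residues})


class TestMapping:
    def test_identity_mapping(self):
        model = toy_structure(5, seed=0, sequence="ACDEF")
        var = VariantRecord("p", "D", 3, "A")
        handle = map_variant_to_structure(var, model, "A")
        assert handle.residue.number == 3

    def test_type_mismatch_reports_both(self):
        model = toy_structure(5, seed=0, sequence="ACDEF")
        var = VariantRecord("p", "W", 3, "A")
        with pytest.raises(MappingError, match="TRP"):
            map_variant_to_structure(var, model, "A")

    def test_explicit_table_routes(self):
        residues = [
            Residue(number=1052, icode=" ", name="ALA", atoms={"CA": np.zeros(3)})
        ]
        model = StructureModel(chains={"A": residues})
        var = VariantRecord("p", "A", 52, "V")
        handle = map_variant_to_structure(var, model, "A", mapping={52: 1052})
        assert handle.residue.number == 1052

    def test_missing_chain_names_available(self):
        model = toy_structure(5, seed=0, sequence="ACDEF")
        with pytest.raises(MappingError, match="'A'"):
            map_variant_to_structure(VariantRecord("p", "A", 1, "V"), model, "Z")


class TestEnvironment:
    def test_cutoff_definition(self):
        model = _model(
            [
                ((0, 0, 0), "ALA"),
                ((5.0, 0, 0), "VAL"),
                ((7.0, 0, 0), "LEU"),
            ]
        )
        center = ResidueHandle("A", model.chain("A")[0])
        env = structural_environment(model, center, radius=6.0)
        assert env.neighbor_count == 1
        assert env.frequencies[AA_INDEX["V"]] == 1.0
        assert sum(env.frequencies) == pytest.approx(1.0)

    def test_boundary_tie_included(self):
        model = _model([((0, 0, 0), "ALA"), ((6.0, 0, 0), "GLY")])
        center = ResidueHandle("A", model.chain("A")[0])
        env = structural_environment(model, center, radius=6.0)
        assert env.neighbor_count == 1

    def test_isolated_residue_zero_vector(self):
        model = _model([((0, 0, 0), "ALA"), ((50, 50, 50), "GLY")])
        center = ResidueHandle("A", model.chain("A")[0])
        env = structural_environment(model, center)
        assert env.neighbor_count == 0
        assert all(f == 0.0 for f in env.frequencies)

    def test_center_without_ca_rejected(self):
        residues = [
            Residue(number=1, icode=" ", name="ALA", atoms={"N": np.zeros(3)}),
            Residue(number=2, icode=" ", name="GLY", atoms={"CA": np.ones(3)}),
        ]
        model = StructureModel(chains={"A": residues})
        with pytest.raises(MappingError, match="C-alpha"):
            structural_environment(model, ResidueHandle("A", model.chain("A")[0]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_distance_scan(self, seed):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        model = toy_structure(30, seed=seed, sequence=seq)
        residues = model.chain("A")
        center = ResidueHandle("A", residues[seed % 30])
        env = structural_environment(model, center, radius=6.0)
        # brute force: plain double loop over all residue pairs
        counts = np.zeros(20)
        n = 0
        for res in residues:
            if res.key == center.residue.key:
                continue
            d = np.sqrt(((res.ca - center.residue.ca) ** 2).sum())
            if d <= 6.0:
                counts[AA_INDEX[THREE_TO_ONE[res.name]]] += 1
                n += 1
        assert env.neighbor_count == n
        if n:
            np.testing.assert_allclose(env.frequencies, counts / n, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        from scipy.spatial.transform import Rotation

        seq = "ACDEFGHIKLMNPQRSTVWY"
        model = toy_structure(20, seed=seed, sequence=seq)
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = np.array([13.0, -7.0, 2.5])
        moved = StructureModel(
            chains={
                "A": [
                    Residue(r.number, r.icode, r.name, {k: rot @ v + shift for k, v in r.atoms.items()})
                    for r in model.chain("A")
                ]
            }
        )
        for idx in (0, 7, 19):
            env1 = structural_environment(model, ResidueHandle("A", model.chain("A")[idx]))
            env2 = structural_environment(moved, ResidueHandle("A", moved.chain("A")[idx]))
            np.testing.assert_allclose(env1.frequencies, env2.frequencies, atol=1e-9)
            assert env1.neighbor_count == env2.neighbor_count

    def test_radius_monotonicity(self):
        model = toy_structure(25, seed=3, sequence="ACDEFGHIKLMNPQRSTVWYACDEF")
        center = ResidueHandle("A", model.chain("A")[12])
        counts = [
            structural_environment(model, center, radius=r).neighbor_count
            for r in (4.0, 6.0, 8.0, 12.0)
        ]
        assert counts == sorted(counts)


class TestRsa:
    def _handle(self, name="ALA", number=1):
        return ResidueHandle(
            "A", Residue(number=number, icode=" ", name=name, atoms={"CA": np.zeros(3)})
        )

    def test_reference_maximum_gives_one(self):
        acc = AccessibilityRecord(acc={("A", 1): MAX_ASA_GXG["A"]})
        assert relative_accessibility(acc, self._handle()).rsa == pytest.approx(1.0)

    def test_zero_gives_zero(self):
        acc = AccessibilityRecord(acc={("A", 1): 0.0})
        assert relative_accessibility(acc, self._handle()).rsa == 0.0

    def test_overshoot_clamped(self):
        acc = AccessibilityRecord(acc={("A", 1): MAX_ASA_GXG["A"] * 1.4})
        assert relative_accessibility(acc, self._handle()).rsa == 1.0

    def test_missing_residue_default_policy_errors(self):
        acc = AccessibilityRecord(acc={})
        with pytest.raises(MappingError):
            relative_accessibility(acc, self._handle())

    def test_missing_residue_impute_policy(self):
        acc = AccessibilityRecord(acc={})
        with pytest.warns(UserWarning):
            rsa = relative_accessibility(acc, self._handle(), missing_policy="impute")
        assert rsa.rsa == 0.5


class TestAccessibilityFallback:
    def test_buried_residue_less_exposed_than_terminus(self):
        model = toy_structure(15, seed=2, sequence="ACDEFGHIKLMNPQR")
        acc = compute_accessibility(model)
        values = [acc.get("A", i) for i in range(1, 16)]
        assert all(v is not None and v >= 0 for v in values)
        interior = np.mean(values[5:10])
        termini = np.mean([values[0], values[-1]])
        assert termini > interior  # chain ends see more solvent

    def test_single_atom_gets_full_sphere(self):
        model = StructureModel(
            chains={"A": [Residue(1, " ", "GLY", {"CA": np.zeros(3)})]}
        )
        acc = compute_accessibility(model)
        r = 1.70 + 1.4
        assert acc.get("A", 1) == pytest.approx(4 * np.pi * r**2, rel=1e-6)
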
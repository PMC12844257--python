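"""Building-block validation and the two structural rewrites."""

import numpy as np
import pytest
from rdkit import Chem

from clickscreen import chem
from clickscreen.chem import (
    ChemValidationError,
    Role,
    acylate_sulfonamide,
    canonical_smiles,
    count_theoretical,
    cuaac_product,
    enumerate_library,
    validate_building_block,
)


def heavy_atoms(smiles: str) -> int:
    return Chem.MolFromSmiles(smiles).GetNumHeavyAtoms()


class TestValidation:
    def test_sulfonamide_alkyne_is_valid_and_flagged(self):
        bb = validate_building_block("C#CCS(N)(=O)=O", Role.ALKYNE)
        assert bb.carries_sulfonamide

    def test_plain_acid_valid_without_sulfonamide(self):
        bb = validate_building_block("CC(=O)O", "acid")
        assert not bb.carries_sulfonamide

    @pytest.mark.parametrize(
        "smiles, role, fragment",
        [
            ("C#CCC#C", "alkyne", "2 terminal alkynes"),
            ("CCO", "alkyne", "0 terminal alkynes"),
            ("[N-]=[N+]=NCC(=O)O", "azide", "stray carboxylic acid"),
            ("OC(=O)CC(=O)O", "acid", "2 carboxylic acids"),
            ("CC(=O)O.O", "acid", "multi-fragment"),
            ("", "acid", "empty"),
            ("not-smiles", "acid", "unparsable"),
        ],
    )
    def test_rejects_wrong_group_content(self, smiles, role, fragment):
        with pytest.raises(ChemValidationError, match=fragment):
            validate_building_block(smiles, role)

    def test_canonicalization_idempotent(self, pool):
        for smi in pool["azide"][:10] + pool["acid"][:10]:
            assert canonical_smiles(canonical_smiles(smi)) == canonical_smiles(smi)


class TestCuaac:
    def test_benzyl_azide_plus_propargyl_sulfonamide(self):
        az = validate_building_block("[N-]=[N+]=NCc1ccccc1", "azide")
        alk = validate_building_block("C#CCS(N)(=O)=O", "alkyne")
        # independently canonicalized reference for the 1,4-regioisomer
        assert cuaac_product(az, alk) == canonical_smiles(
            "NS(=O)(=O)Cc1cn(Cc2ccccc2)nn1"
        )

    def test_ethyne_edge_case_keeps_terminal_ch_as_c4h(self):
        az = validate_building_block("CN=[N+]=[N-]", "azide")
        alk = validate_building_block("C#C", "alkyne")
        assert cuaac_product(az, alk) == canonical_smiles("Cn1ccnn1")

    def test_cycloaddition_conserves_heavy_atoms(self, pool):
        rng = np.random.default_rng(11)
        for _ in range(25):
            az = validate_building_block(
                pool["azide"][rng.integers(len(pool["azide"]))], "azide"
            )
            alk = validate_building_block(
                pool["alkyne_sulfonamide"][rng.integers(len(pool["alkyne_sulfonamide"]))],
                "alkyne",
            )
            prod = cuaac_product(az, alk)
            assert heavy_atoms(prod) == heavy_atoms(az.smiles) + heavy_atoms(alk.smiles)

    def test_role_mismatch_rejected(self):
        acid = validate_building_block("CC(=O)O", "acid")
        alk = validate_building_block("C#CC", "alkyne")
        with pytest.raises(ChemValidationError):
            cuaac_product(acid, alk)


class TestAcylation:
    def test_benzenesulfonamide_plus_acetic_acid(self):
        acid = validate_building_block("CC(=O)O", "acid")
        assert acylate_sulfonamide("NS(=O)(=O)c1ccccc1", acid) == canonical_smiles(
            "CC(=O)NS(=O)(=O)c1ccccc1"
        )

    def test_condensation_loses_one_oxygen(self, pool):
        rng = np.random.default_rng(13)
        substrate = "NS(=O)(=O)c1ccccc1"
        for _ in range(25):
            acid = validate_building_block(
                pool["acid"][rng.integers(len(pool["acid"]))], "acid"
            )
            prod = acylate_sulfonamide(substrate, acid)
            assert (
                heavy_atoms(prod)
                == heavy_atoms(substrate) + heavy_atoms(acid.smiles) - 1
            )

    def test_substrate_without_sulfonamide_rejected(self):
        acid = validate_building_block("CC(=O)O", "acid")
        with pytest.raises(ChemValidationError, match="primary sulfonamide"):
            acylate_sulfonamide("c1ccccc1", acid)


class TestEnumeration:
    @pytest.mark.parametrize(
        "sizes, expected",
        [((83, 8, 95), 63_080), ((3, 51, 67), 10_251), ((1, 1, 1), 1)],
    )
    def test_count_theoretical_is_full_factorial(self, sizes, expected):
        class FakeDesign:
            azides = [None] * sizes[0]
            alkynes = [None] * sizes[1]
            acids = [None] * sizes[2]

        assert count_theoretical(FakeDesign()) == expected

    def test_full_factorial_matches_count_and_ids_distinct(self, small_design):
        members = list(enumerate_library(small_design))
        assert len(members) == count_theoretical(small_design) == 8
        assert len({m.member_id for m in members}) == 8

    def test_every_product_passes_member_invariants(self, small_design):
        for m in enumerate_library(small_design):
            assert chem.check_member_product(m.product_smiles) == []

    def test_planned_subset_in_order(self, small_design):
        small_design.planned = [(1, 1, 1), (2, 1, 2)]
        members = list(enumerate_library(small_design, planned_only=True))
        assert [m.indices for m in members] == [(1, 1, 1), (2, 1, 2)]

    def test_duplicate_azides_flagged_by_canonical_collision(self, pool):
        smi = pool["azide"][0]
        azides = [
            chem.validate_building_block(smi, "azide", set_label="1", index=i)
            for i in (1, 2)
        ]
        alkynes = [
            chem.validate_building_block(
                pool["alkyne_sulfonamide"][0], "alkyne", set_label="2", index=1
            )
        ]
        acids = [
            chem.validate_building_block(pool["acid"][0], "acid", set_label="3", index=1)
        ]
        design = chem.LibraryDesign("4", azides, alkynes, acids)
        members = list(enumerate_library(design))
        assert members[0].duplicate_of is None
        assert members[1].duplicate_of == members[0].member_id

    def test_carrier_set_mismatch_rejected(self, pool):
        azides = [chem.validate_building_block(pool["azide"][0], "azide")]
        alkynes = [chem.validate_building_block(pool["alkyne"][0], "alkyne")]  # no SO2NH2
        acids = [chem.validate_building_block(pool["acid"][0], "acid")]
        with pytest.raises(ChemValidationError, match="lacks a primary sulfonamide"):
            chem.LibraryDesign("4", azides, alkynes, acids)


def test_building_block_csv_roundtrip(tmp_path, small_design):
    path = tmp_path / "blocks.csv"
    blocks = [*small_design.azides, *small_design.alkynes, *small_design.acids]
    chem.write_building_blocks_csv(blocks, path)
    assert chem.read_building_blocks_csv(path) == blocks


def test_members_sdf_roundtrip(tmp_path, small_design):
    from rdkit import Chem as RDChem

    members = list(enumerate_library(small_design))
    path = tmp_path / "members.sdf"
    assert chem.write_members_sdf(members, path) == 8
    mols = [m for m in RDChem.SDMolSupplier(str(path))]
    assert [m.GetProp("member_id") for m in mols] == [m.member_id for m in members]
    assert [RDChem.MolToSmiles(m) for m in mols] == [m.product_smiles for m in members]
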
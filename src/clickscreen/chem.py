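"""Building-block validation and virtual library enumeration.

Products are assembled by two sequential structural rewrites:

1. CuAAC — copper(I)-catalysed azide–alkyne cycloaddition of an organic
   azide with a terminal alkyne, emitting exclusively the 1,4-disubstituted
   1,2,3-triazole regioisomer (the regioselectivity the copper catalyst
   enforces; no 1,5-isomer is ever generated).
2. Sulfonamide N-acylation — condensation of the primary sulfonamide
   ``-S(=O)2NH2`` carried through step 1 with a carboxylic acid, forming the
   acidic N-acyl sulfonamide ``-S(=O)2-N(H)-C(=O)-`` moiety with loss of
   water.

Reagents, catalysts and conditions are deliberately out of scope: the
transforms are purely structural, and every building block must carry
exactly one reactive group of its declared role so the product of each
rewrite is unambiguous.  Multi-fragment (salt/solvate) SMILES are rejected.

Members are labelled ``lib{i,j,k}`` after the 1-based labels of their azide,
alkyne and acid parents; labels may be non-contiguous, so planned
combinations always reference labels, never list positions.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Role",
    "BuildingBlock",
    "LibraryDesign",
    "LibraryMember",
    "ChemValidationError",
    "EnumerationError",
    "validate_building_block",
    "cuaac_product",
    "acylate_sulfonamide",
    "count_theoretical",
    "enumerate_library",
    "canonical_smiles",
    "count_group",
    "read_building_blocks_csv",
    "write_members_sdf",
    "write_members_csv",
]


class Role(str, Enum):
    AZIDE = "azide"
    ALKYNE = "alkyne"
    ACID = "acid"


class ChemValidationError(ValueError):
    """A building block failed structural validation."""


class EnumerationError(RuntimeError):
    """A structural rewrite produced zero or multiple distinct products."""


# Reactive-group queries. The azide must sit on carbon; the alkyne must be
# terminal; the sulfonamide must be primary (NH2) and C-bound.
_SMARTS = {
    "azide": "[#6][NX2]=[NX2+]=[NX1-]",
    "terminal_alkyne": "[CX2]#[CX2H1]",
    "carboxylic_acid": "[CX3](=[OX1])[OX2H1]",
    "primary_sulfonamide": "[#6][SX4](=[OX1])(=[OX1])[NX3H2]",
    "n_acyl_sulfonamide": "[SX4](=[OX1])(=[OX1])[NX3H1][CX3]=[OX1]",
    "triazole_123": "[nX3]1[cX3][cX3][nX2][nX2]1",
}
_QUERIES = {name: Chem.MolFromSmarts(s) for name, s in _SMARTS.items()}

_ROLE_GROUP = {
    Role.AZIDE: "azide",
    Role.ALKYNE: "terminal_alkyne",
    Role.ACID: "carboxylic_acid",
}

# 1,4-regioselective triazole formation: the azide's carbon substituent ends
# up on ring N1, the alkyne's substituent on C4, the former terminal CH on C5.
_CUAAC_RXN = AllChem.ReactionFromSmarts(
    "[#6:1][NX2:2]=[NX2+:3]=[NX1-:4].[C:5]#[CX2H1:6]"
    ">>[#6:1][n:2]1[cH1:6][c:5][n+0:4][n+0:3]1"
)

# Condensation of the primary sulfonamide NH2 with the acid COOH; the
# hydroxyl oxygen and one N-H leave as water.
_ACYL_RXN = AllChem.ReactionFromSmarts(
    "[#6:1][SX4:2](=[OX1:3])(=[OX1:4])[NX3H2:5].[CX3:6](=[OX1:7])[OX2H1]"
    ">>[#6:1][S:2](=[O:3])(=[O:4])[NH1:5][C:6]=[O:7]"
)


def count_group(mol: Chem.Mol, group: str) -> int:
    """Count distinct occurrences of a named reactive group.

    Symmetric SMARTS can match one physical group several times; matches are
    collapsed on their atom sets so each group is counted once.
    """
    matches = mol.GetSubstructMatches(_QUERIES[group])
    return len({frozenset(m) for m in matches})


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemValidationError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class BuildingBlock:
    """One reactant with a validated single reactive site."""

    set_label: str
    index: int
    role: Role
    smiles: str  # canonical form
    carries_sulfonamide: bool

    @property
    def block_id(self) -> str:
        return f"{self.set_label}{{{self.index}}}"

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class LibraryMember:
    member_id: str
    product_smiles: str
    parents: tuple[str, str, str]  # azide id, alkyne id, acid id
    indices: tuple[int, int, int]  # (i, j, k) labels
    duplicate_of: str | None = None


@dataclass
class FailedMember:
    indices: tuple[int, int, int]
    reason: str


@dataclass
class LibraryDesign:
    """Three building-block sets plus optional planned {i,j,k} label triples.

    Exactly one of the azide/alkyne sets must carry the primary sulfonamide
    on all members (the carrier set), matching ``sulfonamide_carrier``.
    """

    library_label: str
    azides: Sequence[BuildingBlock]
    alkynes: Sequence[BuildingBlock]
    acids: Sequence[BuildingBlock]
    sulfonamide_carrier: str = "alkyne"
    planned: list[tuple[int, int, int]] | None = None

    azide_by_label: dict[int, BuildingBlock] = field(init=False, repr=False)
    alkyne_by_label: dict[int, BuildingBlock] = field(init=False, repr=False)
    acid_by_label: dict[int, BuildingBlock] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.sulfonamide_carrier not in ("alkyne", "azide"):
            raise ValueError("sulfonamide_carrier must be 'alkyne' or 'azide'")
        carrier = self.alkynes if self.sulfonamide_carrier == "alkyne" else self.azides
        other = self.azides if self.sulfonamide_carrier == "alkyne" else self.alkynes
        for bb in carrier:
            if not bb.carries_sulfonamide:
                raise ChemValidationError(
                    f"{bb.block_id}: carrier set member lacks a primary sulfonamide"
                )
        for bb in other:
            if bb.carries_sulfonamide:
                raise ChemValidationError(
                    f"{bb.block_id}: non-carrier set member carries a sulfonamide"
                )
        for bb in self.acids:
            if bb.carries_sulfonamide:
                raise ChemValidationError(
                    f"{bb.block_id}: acid set member carries a sulfonamide"
                )
        self.azide_by_label = {bb.index: bb for bb in self.azides}
        self.alkyne_by_label = {bb.index: bb for bb in self.alkynes}
        self.acid_by_label = {bb.index: bb for bb in self.acids}
        if self.planned is not None:
            for i, j, k in self.planned:
                if (
                    i not in self.azide_by_label
                    or j not in self.alkyne_by_label
                    or k not in self.acid_by_label
                ):
                    raise ValueError(f"planned triple ({i},{j},{k}) not in design sets")


def validate_building_block(
    smiles: str,
    role: Role | str,
    *,
    set_label: str = "",
    index: int = 1,
) -> BuildingBlock:
    """Parse and validate a reactant SMILES against its declared role.

    Requirements: a single connected molecule; exactly one reactive group of
    the declared role; at most one primary sulfonamide, and none at all on
    acids (a sulfonamide-bearing acid would acylate itself downstream).
    """
    role = Role(role)
    if not smiles or not smiles.strip():
        raise ChemValidationError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemValidationError(f"unparsable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ChemValidationError(
            f"{smiles!r}: multi-fragment input (salts/solvates are rejected)"
        )

    group = _ROLE_GROUP[role]
    n = count_group(mol, group)
    if n != 1:
        pretty = group.replace("_", " ")
        raise ChemValidationError(f"{smiles!r}: {n} {pretty}s, exactly 1 required")
    # Cross-role purity: one reactive site overall.
    for other_role, other_group in _ROLE_GROUP.items():
        if other_role is not role and count_group(mol, other_group) != 0:
            raise ChemValidationError(
                f"{smiles!r}: stray {other_group.replace('_', ' ')} "
                f"in a declared {role.value}"
            )
    n_sulfo = count_group(mol, "primary_sulfonamide")
    if n_sulfo > 1:
        raise ChemValidationError(f"{smiles!r}: {n_sulfo} primary sulfonamides")
    if role is Role.ACID and n_sulfo:
        raise ChemValidationError(f"{smiles!r}: acid carries a primary sulfonamide")

    return BuildingBlock(
        set_label=set_label,
        index=index,
        role=role,
        smiles=Chem.MolToSmiles(mol),
        carries_sulfonamide=n_sulfo == 1,
    )


def _run_single_product(rxn, reactants: tuple[Chem.Mol, ...], what: str) -> str:
    out: set[str] = set()
    for (prod,) in rxn.RunReactants(reactants):
        try:
            Chem.SanitizeMol(prod)
        except Exception as exc:  # pragma: no cover - defensive
            raise EnumerationError(f"{what}: product sanitization failed: {exc}")
        out.add(Chem.MolToSmiles(prod))
    if len(out) != 1:
        raise EnumerationError(f"{what}: {len(out)} distinct products, expected 1")
    return out.pop()


def cuaac_product(azide: BuildingBlock, alkyne: BuildingBlock) -> str:
    """1,4-disubstituted 1,2,3-triazole from an azide and a terminal alkyne.

    The cycloaddition conserves atoms: the product's heavy-atom count equals
    the sum of the parents'.
    """
    if azide.role is not Role.AZIDE or alkyne.role is not Role.ALKYNE:
        raise ChemValidationError("cuaac_product needs (azide, alkyne) roles")
    return _run_single_product(
        _CUAAC_RXN,
        (azide.mol, alkyne.mol),
        f"CuAAC {azide.block_id}+{alkyne.block_id}",
    )


def acylate_sulfonamide(substrate_smiles: str, acid: BuildingBlock) -> str:
    """Acylate the unique primary sulfonamide of *substrate* with *acid*.

    Condensation loses water, so heavy atoms drop by exactly one oxygen
    relative to substrate + acid.  Only the primary sulfonamide nitrogen is
    acylated; any other N-H in the substrate is left untouched.
    """
    if acid.role is not Role.ACID:
        raise ChemValidationError("acylate_sulfonamide needs an acid building block")
    sub = Chem.MolFromSmiles(substrate_smiles)
    if sub is None:
        raise ChemValidationError(f"unparsable substrate: {substrate_smiles!r}")
    if count_group(sub, "primary_sulfonamide") != 1:
        raise ChemValidationError(
            "substrate must contain exactly one primary sulfonamide"
        )
    return _run_single_product(
        _ACYL_RXN, (sub, acid.mol), f"acylation with {acid.block_id}"
    )


def count_theoretical(design: LibraryDesign) -> int:
    """Full-factorial size of the virtual space: |azides|·|alkynes|·|acids|."""
    sizes = (len(design.azides), len(design.alkynes), len(design.acids))
    if 0 in sizes:
        warnings.warn("count_theoretical: an empty building-block set gives 0")
    return sizes[0] * sizes[1] * sizes[2]


def check_member_product(smiles: str) -> list[str]:
    """Return the list of structural-invariant violations for a product.

    A valid member has exactly one 1,2,3-triazole ring, exactly one N-acyl
    sulfonamide, and no residual azide, terminal alkyne or primary
    sulfonamide.
    """
    mol = Chem.MolFromSmiles(smiles)
    problems = []
    if mol is None:
        return [f"unparsable product {smiles!r}"]
    for group, expect in (
        ("triazole_123", 1),
        ("n_acyl_sulfonamide", 1),
        ("azide", 0),
        ("terminal_alkyne", 0),
        ("primary_sulfonamide", 0),
    ):
        n = count_group(mol, group)
        if n != expect:
            problems.append(f"{group}={n}, expected {expect}")
    return problems


def enumerate_library(
    design: LibraryDesign,
    planned_only: bool = False,
    *,
    failures: list[FailedMember] | None = None,
) -> Iterator[LibraryMember]:
    """Yield one member per (planned or full-factorial) {i,j,k} triple.

    Triples whose transforms fail are recorded in *failures* (when given)
    and skipped; the stream continues.  Distinct triples that collapse to
    the same canonical product are emitted with ``duplicate_of`` set to the
    first member that produced the structure.
    """
    if planned_only:
        if design.planned is None:
            raise ValueError("planned_only=True but design has no planned list")
        triples: Iterable[tuple[int, int, int]] = design.planned
    else:
        triples = (
            (i, j, k)
            for i in sorted(design.azide_by_label)
            for j in sorted(design.alkyne_by_label)
            for k in sorted(design.acid_by_label)
        )

    seen: dict[str, str] = {}
    for i, j, k in triples:
        az = design.azide_by_label[i]
        alk = design.alkyne_by_label[j]
        acid = design.acid_by_label[k]
        member_id = f"{design.library_label}{{{i},{j},{k}}}"
        try:
            intermediate = cuaac_product(az, alk)
            product = acylate_sulfonamide(intermediate, acid)
            problems = check_member_product(product)
            if problems:
                raise EnumerationError("; ".join(problems))
        except (ChemValidationError, EnumerationError) as exc:
            if failures is not None:
                failures.append(FailedMember((i, j, k), str(exc)))
            continue
        member = LibraryMember(
            member_id=member_id,
            product_smiles=product,
            parents=(az.block_id, alk.block_id, acid.block_id),
            indices=(i, j, k),
            duplicate_of=seen.get(product),
        )
        seen.setdefault(product, member_id)
        yield member


# ---------------------------------------------------------------------------
# I/O


def read_building_blocks_csv(path: str | Path) -> list[BuildingBlock]:
    """Load and validate blocks from a CSV with header set_label,index,role,smiles."""
    blocks = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            blocks.append(
                validate_building_block(
                    row["smiles"],
                    Role(row["role"]),
                    set_label=row["set_label"],
                    index=int(row["index"]),
                )
            )
    return blocks


def write_building_blocks_csv(blocks: Iterable[BuildingBlock], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["set_label", "index", "role", "smiles"])
        for bb in blocks:
            w.writerow([bb.set_label, bb.index, bb.role.value, bb.smiles])


def write_members_sdf(members: Iterable[LibraryMember], path: str | Path) -> int:
    """Write products as SDF with member id and parent ids as properties."""
    n = 0
    writer = Chem.SDWriter(str(path))
    try:
        for m in members:
            mol = Chem.MolFromSmiles(m.product_smiles)
            mol.SetProp("_Name", m.member_id)
            mol.SetProp("member_id", m.member_id)
            mol.SetProp("azide_id", m.parents[0])
            mol.SetProp("alkyne_id", m.parents[1])
            mol.SetProp("acid_id", m.parents[2])
            if m.duplicate_of:
                mol.SetProp("duplicate_of", m.duplicate_of)
            writer.write(mol)
            n += 1
    finally:
        writer.close()
    return n


def write_members_csv(members: Iterable[LibraryMember], path: str | Path) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["member_id", "i", "j", "k", "product_smiles", "duplicate_of"])
        for m in members:
            w.writerow(
                [m.member_id, *m.indices, m.product_smiles, m.duplicate_of or ""]
            )
            n += 1
    return n
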
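"""Structure-derived per-residue features: RSA, mean C/N/O B-factor, and a
ternary secondary-structure code.

RSA is the DSSP accessible surface area (ACC, Å²) divided by a per-amino-acid
maximum (theoretical max-ASA values of the Tien et al. style), clamped to
[0, 1].  The flexibility proxy is the arithmetic mean B-factor over the
residue's C, N and O atoms (S, H and all other elements excluded; backbone
included by default, a sidechain-only mode is provided).  DSSP's eight
classes are simplified to −1 for sheet-like (B, E, S), +1 for helical
(H, G, I), and 0 for everything else (T, blank, unknown).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .dataset import AA_SET, MutationDataset, MutationEntry

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructuralFeatures",
    "MaxAccTable",
    "TIEN_MAX_ACC",
    "parse_structure",
    "parse_dssp",
    "compute_rsa",
    "avg_bfactor",
    "simplify_ss",
    "StructureAnnotation",
    "annotate_dataset",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Theoretical maximum accessible surface areas, Å² (Tien et al. 2013 style),
# used as the RSA denominator.
TIEN_MAX_ACC: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

_HELIX = frozenset("HGI")
_SHEET = frozenset("BES")


@dataclass
class AtomRecord:
    name: str
    element: str
    xyz: tuple[float, float, float]
    b_factor: float
    occupancy: float


@dataclass
class ResidueRecord:
    """One residue of a parsed structure, keyed by author numbering."""

    chain: str
    residue_number: int
    insertion_code: str
    aa_type: str
    atoms: list[AtomRecord]


@dataclass
class StructuralFeatures:
    """The three per-residue network inputs."""

    rsa: float
    avg_b: float
    ss_code: int


@dataclass
class MaxAccTable:
    """Per-amino-acid maximum accessible surface area (the RSA denominator)."""

    values: dict[str, float] = field(default_factory=lambda: dict(TIEN_MAX_ACC))

    def __post_init__(self):
        missing = AA_SET - set(self.values)
        if missing:
            raise ValueError(f"MaxAccTable missing amino acids: {sorted(missing)}")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("MaxAccTable values must be positive")


def parse_structure(pdb_text: str) -> list[ResidueRecord]:
    """Parse PDB coordinate text into residue records (first model only).

    Heteroatoms and waters are excluded.  Alternate locations are resolved to
    the highest-occupancy conformer, ties broken by altloc identifier order.
    """
    if "ATOM" not in pdb_text:
        raise ValueError("no ATOM records in structure text")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("s", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise ValueError("no models parsed from structure text")

    records: list[ResidueRecord] = []
    for chain in models[0]:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            if hetflag.strip():
                continue  # heteroatom / water
            resname = residue.get_resname().strip()
            aa = protein_letters_3to1.get(resname)
            if aa is None or aa not in AA_SET:
                continue
            atoms: list[AtomRecord] = []
            for atom in residue:
                if atom.is_disordered():
                    # highest occupancy; ties by altloc id order
                    children = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    atom = children[0]
                coord = atom.get_coord()
                atoms.append(
                    AtomRecord(
                        name=atom.get_name(),
                        element=(atom.element or "").strip().upper(),
                        xyz=(float(coord[0]), float(coord[1]), float(coord[2])),
                        b_factor=float(atom.get_bfactor() or 0.0),
                        occupancy=float(atom.get_occupancy() or 1.0),
                    )
                )
            if atoms:
                records.append(
                    ResidueRecord(
                        chain=chain.id,
                        residue_number=int(resnum),
                        insertion_code=icode.strip(),
                        aa_type=aa,
                        atoms=atoms,
                    )
                )
    if not records:
        raise ValueError("no standard amino-acid residues parsed")
    return records


def compute_rsa(
    acc: float,
    aa_type: str,
    table: MaxAccTable | None = None,
    clamp_log: list | None = None,
) -> float:
    """ACC (Å²) → relative solvent accessibility, clamped to [0, 1].

    Clamps (ACC above the table maximum) are counted through ``clamp_log``
    when provided and warned about otherwise.
    """
    table = table or MaxAccTable()
    if aa_type not in table.values:
        raise ValueError(f"unknown amino acid: {aa_type!r}")
    if acc < 0:
        raise ValueError("acc must be non-negative")
    rsa = acc / table.values[aa_type]
    if rsa > 1.0:
        if clamp_log is not None:
            clamp_log.append((aa_type, acc))
        else:
            warnings.warn(f"RSA clamped to 1.0 for {aa_type} (ACC={acc:.1f})")
        rsa = 1.0
    return rsa


def avg_bfactor(residue: ResidueRecord, sidechain_only: bool = False) -> float:
    """Mean B-factor over the residue's C, N and O atoms.

    Other elements (S, H, ...) are excluded.  ``sidechain_only`` drops the
    backbone atoms N/CA/C/O as well.
    """
    bs = [
        a.b_factor
        for a in residue.atoms
        if a.element in ("C", "N", "O")
        and not (sidechain_only and a.name in BACKBONE_ATOMS)
    ]
    if not bs:
        raise ValueError(
            f"residue {residue.chain}{residue.residue_number} has no qualifying C/N/O atoms"
        )
    return sum(bs) / len(bs)


def simplify_ss(dssp_class: str | None) -> int:
    """DSSP class → ternary code: B/E/S → −1; H/G/I → +1; T and others → 0."""
    if not dssp_class:
        return 0
    c = dssp_class.strip().upper()
    if c in _SHEET:
        return -1
    if c in _HELIX:
        return +1
    return 0


def parse_dssp(text: str) -> dict[tuple[str, int, str], tuple[str, float]]:
    """Parse classic fixed-column DSSP output.

    Returns ``{(chain, residue_number, insertion_code): (ss_class, acc)}``.
    Chain-break rows ('!' residues) are skipped.
    """
    out: dict[tuple[str, int, str], tuple[str, float]] = {}
    in_data = False
    for line in text.splitlines():
        if not in_data:
            if line.lstrip().startswith("#  RESIDUE"):
                in_data = True
            continue
        if len(line) < 38:
            continue
        if line[13] == "!":
            continue
        resnum_s = line[5:10].strip()
        if not resnum_s:
            continue
        chain = line[11]
        icode = line[10].strip()
        ss = line[16].strip()
        acc = float(line[34:38].strip() or 0)
        out[(chain, int(resnum_s), icode)] = (ss, acc)
    return out


@dataclass
class StructureAnnotation:
    """Parsed structure plus per-residue DSSP-style assignments for one protein."""

    residues: dict[tuple[str, int], ResidueRecord]
    assignments: dict[tuple[str, int], tuple[str, float]]

    @classmethod
    def from_texts(cls, pdb_text: str, dssp_text: str) -> "StructureAnnotation":
        residues = {
            (r.chain, r.residue_number): r
            for r in parse_structure(pdb_text)
            if not r.insertion_code  # keyed without icode; icode variants need explicit keys
        }
        assignments = {
            (chain, num): (ss, acc)
            for (chain, num, icode), (ss, acc) in parse_dssp(dssp_text).items()
            if not icode
        }
        return cls(residues=residues, assignments=assignments)

    def features_for(
        self,
        chain: str,
        residue_number: int,
        max_acc: MaxAccTable | None = None,
        sidechain_only: bool = False,
        clamp_log: list | None = None,
    ) -> StructuralFeatures | None:
        key = (chain, residue_number)
        res = self.residues.get(key)
        assign = self.assignments.get(key)
        if res is None or assign is None:
            return None
        ss_class, acc = assign
        return StructuralFeatures(
            rsa=compute_rsa(acc, res.aa_type, table=max_acc, clamp_log=clamp_log),
            avg_b=avg_bfactor(res, sidechain_only=sidechain_only),
            ss_code=simplify_ss(ss_class),
        )


def annotate_dataset(
    ds: MutationDataset,
    structures: dict[str, StructureAnnotation],
    max_acc: MaxAccTable | None = None,
    sidechain_only: bool = False,
) -> MutationDataset:
    """Fill rsa/avg_b/ss_code on each entry from its structure's residue.

    Entries whose residue cannot be matched, or whose wild-type amino acid
    disagrees with the structure, are retained unannotated and flagged in the
    validation report.  ΔTm, Tm and entry count are never changed.
    """
    missing = {e.protein_id for e in ds} - set(structures)
    if missing:
        raise ValueError(f"structures missing for proteins: {sorted(missing)}")

    out = MutationDataset(provenance=ds.provenance, validation_report=list(ds.validation_report))
    clamp_log: list = []
    for i, e in enumerate(ds):
        ann = structures[e.protein_id]
        res = ann.residues.get((e.chain, e.residue_number))
        feats = ann.features_for(
            e.chain, e.residue_number, max_acc=max_acc,
            sidechain_only=sidechain_only, clamp_log=clamp_log,
        )
        new = MutationEntry(**vars(e))
        if feats is None:
            out.validation_report.append({"row": i, "reasons": ["residue-not-found"]})
        elif res is not None and res.aa_type != e.wt_aa:
            out.validation_report.append({"row": i, "reasons": ["sequence-mismatch"]})
        else:
            new.rsa, new.avg_b, new.ss_code = feats.rsa, feats.avg_b, feats.ss_code
        out.entries.append(new)
    if clamp_log:
        warnings.warn(f"{len(clamp_log)} RSA value(s) clamped to 1.0")
    return out
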
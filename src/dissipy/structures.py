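"""Protein structures as one-bead-per-residue (C-alpha) chains.

Structures are read from standard PDB text (ATOM records only); every
residue with a C-alpha atom becomes one bead, re-indexed 1..N in file
order.  Region annotations partition the residue indices into labelled
structural regions (e.g. N-lobe / C-lobe / ACT1 / ACT2).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import FormatError, InputError, SpecError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: Average residue masses (amino acid minus water), amu, by 3-letter code.
RESIDUE_MASSES: dict[str, float] = {
    "GLY": 57.0519, "ALA": 71.0788, "SER": 87.0782, "PRO": 97.1167,
    "VAL": 99.1326, "THR": 101.1051, "CYS": 103.1388, "LEU": 113.1594,
    "ILE": 113.1594, "ASN": 114.1038, "ASP": 115.0886, "GLN": 128.1307,
    "LYS": 128.1741, "GLU": 129.1155, "MET": 131.1926, "HIS": 137.1411,
    "PHE": 147.1766, "ARG": 156.1875, "TYR": 163.1760, "TRP": 186.2132,
}

#: Fallback mass for unknown residue codes, amu.
DEFAULT_MASS = 110.0


@dataclass(frozen=True)
class Residue:
    """A single C-alpha bead."""

    index: int
    name: str
    chain_id: str
    mass: float
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InputError(f"residue {self.index}: mass must be > 0")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise InputError(f"residue {self.index}: position must be a 3-vector")


@dataclass
class ProteinStructure:
    """An ordered chain of C-alpha beads."""

    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise InputError("a structure needs at least 2 residues")
        for pos, res in enumerate(self.residues, start=1):
            if res.index != pos:
                raise InputError(
                    f"residue indices must be 1..N in order; got {res.index} at {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array, Angstrom."""
        return np.array([r.position for r in self.residues], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        """(N,) mass array, amu."""
        return np.array([r.mass for r in self.residues], dtype=float)

    def to_pdb(self) -> str:
        """Serialize as minimal PDB text (one CA ATOM record per bead)."""
        lines = []
        for r in self.residues:
            x, y, z = r.position
            lines.append(
                f"ATOM  {r.index:>5d}  CA  {r.name:<3s} {r.chain_id[:1] or 'A'}"
                f"{r.index:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"           C  "
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def mass_for(resname: str) -> float:
    """Residue mass by 3-letter code, falling back to a uniform 110 amu."""
    return RESIDUE_MASSES.get(resname.upper(), DEFAULT_MASS)


def read_structure(pdb_text: str, chain: str | None = None,
                   source_id: str = "") -> ProteinStructure:
    """Parse PDB text into a C-alpha bead chain.

    Parameters
    ----------
    pdb_text : PDB-format text (ATOM records; HETATM ignored).
    chain : optional chain identifier; default is all chains in file order.
    source_id : free-text identifier stored on the structure.

    Residues without a C-alpha atom are skipped with a warning; altloc
    duplicates collapse to the first encountered.  Raises FormatError on
    unparseable text and InputError when fewer than 2 beads result.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = next(iter(parser.get_structure("s", io.StringIO(pdb_text))))
    except (PDBConstructionException, StopIteration, ValueError) as exc:
        raise FormatError(f"could not parse PDB text: {exc}") from exc

    residues: list[Residue] = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            hetfield = res.id[0]
            if hetfield != " ":
                continue  # HETATM / water
            if "CA" not in res:
                logger.warning(
                    "residue %s%s (%s) has no CA atom; skipped",
                    ch.id, res.id[1], res.get_resname(),
                )
                continue
            ca = res["CA"]
            if ca.is_disordered():
                ca = ca.disordered_get_list()[0]
            residues.append(
                Residue(
                    index=len(residues) + 1,
                    name=res.get_resname(),
                    chain_id=ch.id,
                    mass=mass_for(res.get_resname()),
                    position=np.asarray(ca.get_coord(), dtype=float),
                )
            )
    if len(residues) < 2:
        raise InputError(
            f"need at least 2 CA-bearing residues, found {len(residues)}"
        )
    return ProteinStructure(residues=residues, source_id=source_id)


@dataclass
class RegionAnnotation:
    """Partition of residue indices into labelled regions.

    Unlisted residues carry the label ``"unassigned"``.
    """

    labels: dict[int, str]
    n_residues: int
    label_order: list[str] = field(default_factory=list)

    def label_of(self, index: int) -> str:
        if not 1 <= index <= self.n_residues:
            raise SpecError(f"residue index {index} outside 1..{self.n_residues}")
        return self.labels.get(index, UNASSIGNED)

    @property
    def region_labels(self) -> list[str]:
        """Distinct labels in first-appearance order (unassigned last if present)."""
        out = list(self.label_order)
        if len(self.labels) < self.n_residues and UNASSIGNED not in out:
            out.append(UNASSIGNED)
        return out

    def region_sizes(self) -> dict[str, int]:
        sizes = {lab: 0 for lab in self.region_labels}
        for i in range(1, self.n_residues + 1):
            sizes[self.label_of(i)] += 1
        return sizes


def annotate_regions(structure: ProteinStructure,
                     spec: list[tuple[int, int, str]]) -> RegionAnnotation:
    """Build a region annotation from (start, end, label) ranges (inclusive).

    Ranges must lie within 1..N and must not overlap; residues in no
    range are labelled ``"unassigned"``.
    """
    n = structure.n_residues
    labels: dict[int, str] = {}
    order: list[str] = []
    for start, end, label in spec:
        if not (1 <= start <= end <= n):
            raise SpecError(f"range ({start},{end}) outside 1..{n}")
        for i in range(start, end + 1):
            if i in labels:
                raise SpecError(f"residue {i} covered by overlapping ranges")
            labels[i] = label
        if label not in order:
            order.append(label)
    return RegionAnnotation(labels=labels, n_residues=n, label_order=order)


def read_region_spec(text: str) -> list[tuple[int, int, str]]:
    """Parse a 3-column delimited region spec: start, end, label."""
    spec = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 3:
            raise SpecError(f"region spec line {lineno}: expected 3 columns")
        try:
            spec.append((int(parts[0]), int(parts[1]), parts[2]))
        except ValueError as exc:
            raise SpecError(f"region spec line {lineno}: bad integer") from exc
    return spec
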
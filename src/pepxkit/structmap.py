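"""Write per-residue scalar values into the B-factor column of a PDB file.

Intensity ratios (or any per-residue scalar) are visualized on a structure
by replacing the B-factor of every atom of each mapped residue with the
clamped value, so a molecular viewer can color by B-factor (e.g. a 0.30-0.70
ramp).  Residues in the mapped chain that carry no value receive a sentinel
(-1.00 by default) so "unassigned" can be colored distinctly.

The file is handled at the line level: only columns 61-66 (the B-factor
field) of ATOM/HETATM records in the mapped chain are rewritten, every other
byte of the file round-trips exactly.  Residue matching uses the author
residue number on a single chain; insertion codes in the mapped chain are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ResidueValueMap",
    "PDBStructure",
    "Atom",
    "read_structure",
    "map_to_bfactor",
    "write_structure",
    "read_residue_values",
]


@dataclass
class Atom:
    """Parsed fields of one ATOM/HETATM record (line kept verbatim)."""

    line_index: int
    record: str
    name: str
    chain: str
    resnum: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    bfactor: float


@dataclass
class PDBStructure:
    """A PDB file as its raw lines plus parsed ATOM/HETATM records."""

    lines: list[str]
    atoms: list[Atom]

    def to_text(self) -> str:
        return "".join(self.lines)


@dataclass
class ResidueValueMap:
    """Per-residue values on one chain, with a clamp range and a default.

    ``lo < hi`` define the display clamp; residues of the chain absent from
    ``values`` get ``default_value`` (a sentinel outside the ramp, so viewers
    can color unmapped/unassigned residues separately).
    """

    chain: str
    values: dict[int, float]
    lo: float
    hi: float
    default_value: float = -1.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("clamp range requires lo < hi")
        for resnum in self.values:
            if not (isinstance(resnum, (int,)) and resnum > 0):
                raise ValueError(f"residue numbers must be positive integers, "
                                 f"got {resnum!r}")


def _parse_atom_line(line: str, index: int) -> Atom:
    try:
        return Atom(
            line_index=index,
            record=line[0:6].strip(),
            name=line[12:16].strip(),
            chain=line[21],
            resnum=int(line[22:26]),
            icode=line[26] if len(line) > 26 else " ",
            x=float(line[30:38]),
            y=float(line[38:46]),
            z=float(line[46:54]),
            occupancy=float(line[54:60]),
            bfactor=float(line[60:66]),
        )
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed ATOM/HETATM record at line {index + 1}: "
                         f"{exc}") from exc


def read_structure(pdb_text: str) -> PDBStructure:
    """Parse PDB text, retaining every line verbatim.

    ATOM and HETATM records are parsed into :class:`Atom` objects; all other
    records pass through untouched.  A malformed fixed-width ATOM line raises
    with its line number.
    """
    lines = pdb_text.splitlines(keepends=True)
    atoms = []
    for i, line in enumerate(lines):
        if line.startswith(("ATOM  ", "HETATM")):
            atoms.append(_parse_atom_line(line, i))
    return PDBStructure(lines=lines, atoms=atoms)


def map_to_bfactor(structure: PDBStructure,
                   value_map: ResidueValueMap) -> PDBStructure:
    """Return a structure whose B column carries the mapped values.

    Every atom of a mapped residue gets ``clamp(value, lo, hi)``; atoms of
    the mapped chain whose residue is absent from the map get the default
    sentinel.  Atoms on other chains, and all non-ATOM records, are
    untouched.  The B value is written in PDB fixed width ``%6.2f``.
    """
    chain_atoms = [a for a in structure.atoms if a.chain == value_map.chain]
    if not chain_atoms:
        raise ValueError(f"chain {value_map.chain!r} not found in structure")
    bad_icode = [a for a in chain_atoms if a.icode not in (" ", "")]
    if bad_icode:
        raise ValueError("insertion codes in the mapped chain are not "
                         f"supported (residue {bad_icode[0].resnum}"
                         f"{bad_icode[0].icode})")

    new_lines = list(structure.lines)
    new_atoms = []
    for atom in structure.atoms:
        if atom.chain != value_map.chain:
            new_atoms.append(atom)
            continue
        if atom.resnum in value_map.values:
            v = value_map.values[atom.resnum]
            b = min(max(v, value_map.lo), value_map.hi)
        else:
            b = value_map.default_value
        line = new_lines[atom.line_index]
        new_lines[atom.line_index] = line[:60] + f"{b:6.2f}" + line[66:]
        new_atoms.append(Atom(**{**atom.__dict__, "bfactor": b}))
    return PDBStructure(lines=new_lines, atoms=new_atoms)


def write_structure(structure: PDBStructure) -> str:
    """Serialize back to text (byte-identical outside any edited B fields)."""
    return structure.to_text()


def read_residue_values(csv_text_or_df, lo: float, hi: float,
                        default_value: float = -1.0) -> ResidueValueMap:
    """Build a :class:`ResidueValueMap` from a (chain, resnum, value) table.

    Accepts a DataFrame or a path/buffer readable by :func:`pandas.read_csv`.
    All rows must share one chain (the mapping targets a single chain).
    """
    if isinstance(csv_text_or_df, pd.DataFrame):
        df = csv_text_or_df
    else:
        df = pd.read_csv(csv_text_or_df)
    chains = df["chain"].unique()
    if len(chains) != 1:
        raise ValueError("value file must target exactly one chain, "
                         f"got {list(chains)}")
    values = {int(r.resnum): float(r.value) for r in df.itertuples()}
    return ResidueValueMap(chain=str(chains[0]), values=values,
                           lo=lo, hi=hi, default_value=default_value)
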
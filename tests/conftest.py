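"""Shared fixtures: all inputs are generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from pepxkit.hsqcratio import PeakList


def atom_line(serial, name, resname, chain, resseq, x, y, z,
              occ=1.00, b=20.00, icode=" ", element=None):
    """One fixed-width PDB ATOM record."""
    element = element or name[0]
    return (f"ATOM  {serial:5d} {name:^4s} {resname:3s} {chain}{resseq:4d}"
            f"{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}\n")


@pytest.fixture
def mini_pdb_text():
    """Synthetic three-residue mini structure (not a deposited entry)."""
    lines = ["HEADER    SYNTHETIC MINI STRUCTURE\n",
             "REMARK    generated fixture for B-factor mapping tests\n"]
    serial = 1
    coords = iter(np.linspace(0.0, 25.0, 100))
    for resseq, resname in ((140, "THR"), (141, "ILE"), (142, "VAL")):
        for name in ("N", "CA", "C", "O"):
            c = next(coords)
            lines.append(atom_line(serial, name, resname, "A", resseq,
                                   c, c + 1.0, c + 2.0))
            serial += 1
    # a second chain that mapping must leave untouched
    lines.append(atom_line(serial, "CA", "GLY", "B", 1, 9.0, 9.0, 9.0))
    lines.append("TER\n")
    lines.append("END\n")
    return "".join(lines)


@pytest.fixture
def hand_peaklists():
    """Ten-residue pair with hand-set intensities: nine at ratio 1.0, one at 0.2."""
    ids = [f"T{140 + i}" for i in range(10)]
    ref = pd.DataFrame({
        "assignment_id": ids,
        "h_ppm": np.linspace(7.0, 9.0, 10),
        "n_ppm": np.linspace(110.0, 125.0, 10),
        "intensity": [1000.0] * 10,
    })
    per = ref.copy()
    per["intensity"] = [1000.0] * 2 + [200.0] + [1000.0] * 7
    return PeakList(ref, label="ref"), PeakList(per, label="per")
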
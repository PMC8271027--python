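"""HSQC peak intensity-ratio (line-broadening) analysis.

Comparing a TROSY-HSQC spectrum of a complex alone (reference, ``I0``)
against the same complex after a perturbation -- UV cleavage of the bound
peptide, or addition of a chaperone -- reports which residues experience
line broadening (``I/I0`` well below the bulk) or chemical-shift changes.
Residues whose ratio falls below ``mean - delta`` (delta = one standard
deviation of the ratio distribution over quantified residues) are flagged as
significantly attenuated; peaks that vanish entirely get ratio 0 and are
always flagged.  Chemical-shift perturbations use the conventional amide
weighting ``sqrt(ddH**2 + (ddN / 5)**2)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "RatioTable",
    "match_peaks",
    "intensity_ratios",
    "flag_attenuated",
    "chemical_shift_perturbation",
    "residue_values",
]

#: Conventional downweighting of the nitrogen shift in amide CSPs.
CSP_N_WEIGHT = 1.0 / 5.0


@dataclass
class PeakList:
    """Quantified peaks of one spectrum: id, position (ppm) and intensity."""

    table: pd.DataFrame          # assignment_id, h_ppm, n_ppm, intensity
    label: str = ""

    def __post_init__(self) -> None:
        required = {"assignment_id", "h_ppm", "n_ppm", "intensity"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"peak list missing columns: {sorted(missing)}")
        dup = self.table["assignment_id"][self.table["assignment_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate assignment id(s): "
                             f"{sorted(dup.unique().tolist())}")
        if (self.table["intensity"].dropna() < 0).any():
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RatioTable:
    """Per-residue I/I0 table with its summary statistics.

    ``delta`` is the sample standard deviation of the ratios over residues
    quantified in both spectra; the attenuation rule flags ratios strictly
    below ``mean - delta``.
    """

    table: pd.DataFrame          # assignment_id, ratio, csp, vanished, excluded
    mean: float
    delta: float
    n_quantified: int


def match_peaks(reference: PeakList, perturbed: PeakList
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join two peak lists on assignment id.

    Returns ``(paired, unmatched)``; ``unmatched`` lists ids present in only
    one spectrum with a ``which`` column (those residues are plotted
    separately, like unassigned residues in ratio bar plots).
    """
    ref = reference.table.set_index("assignment_id")
    per = perturbed.table.set_index("assignment_id")
    shared = ref.index.intersection(per.index)
    if shared.empty:
        raise ValueError("peak lists share no assignment ids")
    paired = ref.loc[shared].join(per.loc[shared], lsuffix="_ref",
                                  rsuffix="_per").reset_index()
    only_ref = ref.index.difference(per.index)
    only_per = per.index.difference(ref.index)
    unmatched = pd.DataFrame({
        "assignment_id": list(only_ref) + list(only_per),
        "which": (["reference"] * len(only_ref)
                  + ["perturbed"] * len(only_per))})
    return paired, unmatched


def chemical_shift_perturbation(paired: pd.DataFrame) -> pd.Series:
    """Weighted amide CSP per residue: ``sqrt(ddH^2 + (ddN/5)^2)`` in ppm.

    Rows with a missing position in either spectrum yield NaN.
    """
    dh = paired["h_ppm_per"] - paired["h_ppm_ref"]
    dn = paired["n_ppm_per"] - paired["n_ppm_ref"]
    return np.sqrt(dh**2 + (CSP_N_WEIGHT * dn) ** 2)


def intensity_ratios(paired: pd.DataFrame) -> RatioTable:
    """Per-residue intensity ratio I/I0 with mean and SD (delta).

    The mean and delta run over residues quantified in both spectra
    (reference intensity > 0, finite perturbed intensity).  A perturbed
    intensity of zero is a vanished peak: ratio 0, kept in the statistics.
    A zero reference intensity cannot be ratioed: the id is flagged
    ``excluded`` and left out of the statistics.
    """
    i0 = paired["intensity_ref"].to_numpy(dtype=float)
    i1 = paired["intensity_per"].to_numpy(dtype=float)
    excluded = ~(i0 > 0) | ~np.isfinite(i1)
    ratio = np.full(i0.shape, np.nan)
    ok = ~excluded
    ratio[ok] = i1[ok] / i0[ok]
    vanished = ok & (i1 == 0)

    table = pd.DataFrame({
        "assignment_id": paired["assignment_id"],
        "ratio": ratio,
        "csp": chemical_shift_perturbation(paired),
        "vanished": vanished,
        "excluded": excluded,
    })
    quantified = table.loc[ok, "ratio"]
    mean = float(quantified.mean())
    delta = float(quantified.std(ddof=1)) if len(quantified) >= 2 else 0.0
    return RatioTable(table=table, mean=mean, delta=delta,
                      n_quantified=int(ok.sum()))


def flag_attenuated(rt: RatioTable) -> RatioTable:
    """Mark significantly attenuated residues: ratio < mean - delta.

    The inequality is strict; vanished peaks are always flagged.  Refuses
    with fewer than 3 quantified residues, where delta is meaningless.
    """
    if rt.n_quantified < 3:
        raise ValueError("need at least 3 quantified residues to flag "
                         "attenuation")
    threshold = rt.mean - rt.delta
    att = (rt.table["ratio"] < threshold) | rt.table["vanished"]
    att &= ~rt.table["excluded"]
    table = rt.table.copy()
    table["attenuated"] = att
    table["threshold"] = threshold
    return RatioTable(table=table, mean=rt.mean, delta=rt.delta,
                      n_quantified=rt.n_quantified)


_ID_RE = re.compile(r"^[A-Za-z]{1,3}(\d+)")


def residue_values(rt: RatioTable, chain: str = "A") -> pd.DataFrame:
    """Turn a ratio table into a (chain, resnum, value) frame for mapping.

    Assignment ids are parsed as one-to-three letter residue codes followed
    by the author residue number (e.g. ``"T143"`` or ``"Ile23"``); ids that
    do not parse, or were excluded, are skipped.
    """
    rows = []
    for _, rec in rt.table.iterrows():
        if rec["excluded"] or not np.isfinite(rec["ratio"]):
            continue
        m = _ID_RE.match(str(rec["assignment_id"]))
        if not m:
            continue
        rows.append({"chain": chain, "resnum": int(m.group(1)),
                     "value": float(rec["ratio"])})
    return pd.DataFrame(rows, columns=["chain", "resnum", "value"])
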
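"""Synthetic data with known ground truth for every analysis stage.

Because the raw plate-reader, NMR and melt data behind the published summary
statistics are not deposited, each analysis stage is exercised on synthetic
inputs whose ground-truth parameters are known exactly.  The preset table is
calibrated so that the *ratios* the pipeline estimates (catalyst fold
changes of the observed association rate, relative catalytic activities of
tapasin scoop-loop mutants) equal the published summary values; absolute
rates, amplitudes and noise levels are conventions, documented in the
methods note.

Generators:

* :func:`gen_fp_trace` -- exponential FP association plus a free-peptide
  baseline well, Gaussian noise;
* :func:`gen_cpmg_profile` -- two-state fast-exchange dispersion intensities
  on the standard 15-point schedule with duplicate frequencies;
* :func:`gen_peaklist_pair` -- paired HSQC peak lists with chosen per-residue
  attenuations and shifts;
* :func:`gen_melt_curve` -- Boltzmann sigmoid melt curves.

All generators are deterministic for a fixed seed; wells derive child
streams from ``(seed, condition, replicate)`` so different replicates and
conditions see different noise but identical ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .cpmg import DispersionProfile, dispersion_curve
from .fpkinetics import FPTrace
from .hsqcratio import PeakList
from .thermoshift import MeltCurve

__all__ = [
    "FPPreset", "CPMGPreset", "PeakPairPreset", "MeltPreset",
    "gen_fp_trace", "gen_fp_replicates", "gen_cpmg_profile",
    "gen_peaklist_pair", "gen_melt_curve",
    "preset_table", "fp_preset", "TSN_WT_FOLD", "TAPBPR_FOLD",
    "RELATIVE_ACTIVITY", "NU_SCHEDULE", "UNCATALYZED_K",
]

#: The standard CPMG pulse-frequency schedule (Hz); 0 marks the reference
#: scan, 50 and 300 are measured in duplicate for error estimation.
NU_SCHEDULE: tuple[float, ...] = (0, 950, 50, 300, 150, 800, 100, 250,
                                  400, 600, 200, 50, 500, 300, 700)

#: Conventional uncatalyzed association rate (1/s); only ratios to it are
#: calibrated against published values.
UNCATALYZED_K = 1e-4

# -- published summary statistics the preset table is calibrated to --------

#: ERp57-tapasin(WT) fold change of K_on per allotype, (value, SD).
TSN_WT_FOLD: dict[str, tuple[float, float]] = {
    "A*03:01": (10.89, 1.48),
    "B*27:05": (5.83, 1.06),
    "B*27:09": (3.83, 0.07),
    "A*02:01": (1.31, 0.08),
}

#: TAPBPR fold change of K_on per allotype, (value, SD).
TAPBPR_FOLD: dict[str, tuple[float, float]] = {
    "A*02:01": (30.9, 1.12),
    "A*03:01": (34.28, 5.3),
    "B*27:09": (3.13, 0.23),
    "B*27:05": (1.48, 0.23),
}

#: Relative catalytic activity (vs Tsn-WT) of scoop-loop mutants,
#: (value, SD); SD None where only a qualitative statement is published
#: ("no activity" -> 0.0, "as efficient as WT" -> 1.0).
RELATIVE_ACTIVITY: dict[tuple[str, str], tuple[float, float | None]] = {
    ("A*03:01", "L18G"): (0.36, 0.06),
    ("B*27:05", "L18G"): (0.05, 0.02),
    ("B*27:09", "L18G"): (0.04, 0.06),
    ("A*03:01", "K16G"): (0.77, 0.12),
    ("B*27:05", "K16G"): (0.86, 0.05),
    ("B*27:09", "K16G"): (0.95, 0.15),
    ("A*03:01", "GGGGG"): (0.01, 0.01),
    ("B*27:05", "GGGGG"): (0.02, 0.01),
    ("B*27:09", "GGGGG"): (0.03, 0.02),
    ("A*03:01", "K16L"): (0.93, 0.16),
    ("B*27:09", "K16L"): (1.26, 0.06),
    ("A*03:01", "L18K"): (0.0, None),
    ("B*27:09", "L18K"): (0.0, None),
    ("A*03:01", "GGGGL"): (0.40, 0.12),
    ("B*27:09", "GGGGL"): (0.77, 0.14),
    ("A*03:01", "GGGGK"): (0.23, 0.05),
    ("B*27:09", "GGGGK"): (0.0, None),
    ("A*03:01", "GGLGG"): (0.35, 0.05),
    ("B*27:09", "GGLGG"): (1.0, None),
    ("A*03:01", "GGKGG"): (1.0, None),
    ("B*27:09", "GGKGG"): (0.0, None),
}


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise ValueError(f"{name}: non-finite preset field")


@dataclass
class FPPreset:
    """Ground truth for one (allotype, catalyst) FP association condition."""

    allotype: str
    catalyst: str
    k_true: float                   # observed association rate (1/s)
    y0_true: float = 150.0          # plateau polarization (FP units)
    a_true: float = 150.0           # amplitude (FP units)
    baseline_true: float = 35.0     # free-peptide polarization (FP units)
    noise_sd: float = 2.0           # FP units
    n_timepoints: int = 40
    t_end: float | None = None      # s; None -> clip(8/k, 1 h, 5 h)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        _check_finite("FPPreset", self.k_true, self.y0_true, self.a_true,
                      self.baseline_true, self.noise_sd)
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")
        if self.a_true <= 0:
            raise ValueError("a_true must be positive")
        if self.n_timepoints < 8:
            raise ValueError("need at least 8 time points")
        if self.t_end is None:
            # measuring time differs per condition: resolve the rise but
            # stay within the 1-5 h plate-reader window
            self.t_end = float(np.clip(8.0 / self.k_true, 3600.0, 18000.0))
        _check_finite("FPPreset", self.t_end)


@dataclass
class CPMGPreset:
    """Ground truth for one methyl's dispersion profile."""

    methyl_id: str = "I23-CD1"
    r2_0: float = 12.0              # intrinsic relaxation rate (1/s)
    kex: float = 1500.0             # exchange rate (1/s)
    phi: float = 1.5e4              # p_a*p_b*d_omega^2 (1/s^2); amp 10 1/s
    t_cpmg: float = 0.040           # constant-time delay (s)
    nu_schedule: tuple[float, ...] = NU_SCHEDULE
    i_ref: float = 1.0e6            # reference intensity
    noise_sd: float = 1.0e4         # intensity units (1% of i_ref)

    def __post_init__(self) -> None:
        _check_finite("CPMGPreset", self.r2_0, self.kex, self.phi,
                      self.t_cpmg, self.i_ref, self.noise_sd)
        if self.r2_0 < 0:
            raise ValueError("r2_0 must be non-negative")
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if any(nu < 0 for nu in self.nu_schedule):
            raise ValueError("nu_CPMG values must be non-negative")


@dataclass
class PeakPairPreset:
    """Ground truth for a paired (reference, perturbed) peak-list fixture."""

    residues: tuple[str, ...]
    attenuation_map: dict[str, float] = field(default_factory=dict)
    shift_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    intensity_scale: float = 1.0e6
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("residue ids must be unique")
        for rid, att in self.attenuation_map.items():
            if att < 0:
                raise ValueError(f"attenuation for {rid} must be positive")


@dataclass
class MeltPreset:
    """Ground truth for one Boltzmann melt curve."""

    condition: str = ""
    tm_true: float = 65.0           # degC
    slope_true: float = 1.5         # degC
    f_min: float = 1000.0
    f_max: float = 9000.0
    t_range: tuple[float, float] = (25.0, 95.0)
    step: float = 0.5               # degC (2 degC/min ramp, 15 s reads)
    noise_sd: float = 80.0          # 1% of the transition height

    def __post_init__(self) -> None:
        if self.f_max <= self.f_min:
            raise ValueError("f_max must exceed f_min")
        if not (self.t_range[0] < self.tm_true < self.t_range[1]):
            raise ValueError("tm_true must lie inside t_range")
        if self.step <= 0:
            raise ValueError("step must be positive")


# ---------------------------------------------------------------- generators

def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, key)])


def _label_key(*labels: str) -> int:
    """Stable integer stream key for condition labels (crc32 is versionless)."""
    import zlib
    return zlib.crc32("/".join(labels).encode())


def gen_fp_trace(preset: FPPreset, seed: int,
                 replicate: int = 0) -> tuple[FPTrace, FPTrace]:
    """Generate one FP association trace and its free-peptide baseline well.

    The sample well reads ``baseline + (y0 - a * exp(-k t)) + noise``; the
    baseline well reads ``baseline + noise`` on the same even time grid.
    Noise streams are keyed by (seed, condition, replicate) so different
    conditions never share a noise realization.
    """
    rng = _rng(seed, _label_key(preset.allotype, preset.catalyst), replicate)
    t = np.linspace(0.0, preset.t_end, preset.n_timepoints)
    signal = (preset.baseline_true + preset.y0_true
              - preset.a_true * np.exp(-preset.k_true * t))
    fp = signal + rng.normal(0.0, preset.noise_sd, size=t.size)
    base = (preset.baseline_true
            + rng.normal(0.0, preset.noise_sd, size=t.size))
    trace = FPTrace(time=t, fp=fp, allotype=preset.allotype,
                    catalyst=preset.catalyst, replicate=replicate,
                    role="sample")
    baseline = FPTrace(time=t, fp=base, allotype=preset.allotype,
                       catalyst=preset.catalyst, replicate=replicate,
                       role="baseline")
    return trace, baseline


def gen_fp_replicates(preset: FPPreset,
                      seed: int) -> Iterator[tuple[FPTrace, FPTrace]]:
    """Yield ``preset.n_replicates`` independent (trace, baseline) pairs."""
    for rep in range(preset.n_replicates):
        yield gen_fp_trace(preset, seed, replicate=rep)


def gen_cpmg_profile(preset: CPMGPreset, seed: int) -> DispersionProfile:
    """Generate one methyl's CPMG intensity profile.

    ``nu > 0`` rows carry ``i_ref * exp(-t_cpmg * R2(nu))`` under the
    fast-exchange two-state curve; ``nu = 0`` rows carry the reference
    intensity itself (the reference scan has no relaxation block).  Every
    scheduled point -- including duplicated frequencies -- receives
    independent Gaussian noise.
    """
    rng = _rng(seed)
    nu = np.asarray(preset.nu_schedule, dtype=float)
    r2 = dispersion_curve(nu, preset.r2_0, preset.kex, preset.phi)
    clean = np.where(nu > 0,
                     preset.i_ref * np.exp(-preset.t_cpmg * r2),
                     preset.i_ref)
    intensity = clean + rng.normal(0.0, preset.noise_sd, size=nu.size)
    return DispersionProfile(methyl_id=preset.methyl_id, nu=nu,
                             intensity=intensity, t_cpmg=preset.t_cpmg,
                             i_ref=None if preset.noise_sd > 0
                             else preset.i_ref)


def gen_peaklist_pair(preset: PeakPairPreset,
                      seed: int) -> tuple[PeakList, PeakList]:
    """Generate a reference and a perturbed HSQC peak list.

    Reference intensities are drawn once around ``intensity_scale``; the
    perturbed list multiplies each residue's intensity by its attenuation
    (default 1) and shifts its position by the preset's (ddH, ddN).
    """
    rng = _rng(seed)
    n = len(preset.residues)
    h = rng.uniform(6.5, 10.5, size=n).round(3)
    nppm = rng.uniform(105.0, 130.0, size=n).round(2)
    base = preset.intensity_scale * rng.uniform(0.5, 1.5, size=n)

    ref_rows, per_rows = [], []
    for i, rid in enumerate(preset.residues):
        att = preset.attenuation_map.get(rid, 1.0)
        dh, dn = preset.shift_map.get(rid, (0.0, 0.0))
        noise_r = rng.normal(0.0, preset.noise_sd) if preset.noise_sd else 0.0
        noise_p = rng.normal(0.0, preset.noise_sd) if preset.noise_sd else 0.0
        ref_rows.append({"assignment_id": rid, "h_ppm": h[i],
                         "n_ppm": nppm[i],
                         "intensity": max(base[i] + noise_r, 0.0)})
        per_rows.append({"assignment_id": rid, "h_ppm": h[i] + dh,
                         "n_ppm": nppm[i] + dn,
                         "intensity": max(base[i] * att + noise_p, 0.0)})
    return (PeakList(pd.DataFrame(ref_rows), label="reference"),
            PeakList(pd.DataFrame(per_rows), label="perturbed"))


def gen_melt_curve(preset: MeltPreset, seed: int,
                   replicate: int = 0) -> MeltCurve:
    """Generate one Boltzmann melt curve with Gaussian noise."""
    rng = _rng(seed, _label_key(preset.condition), replicate)
    t = np.arange(preset.t_range[0], preset.t_range[1] + preset.step / 2,
                  preset.step)
    f = preset.f_min + (preset.f_max - preset.f_min) / (
        1.0 + np.exp((preset.tm_true - t) / preset.slope_true))
    f = f + rng.normal(0.0, preset.noise_sd, size=t.size)
    return MeltCurve(temperature=t, fluorescence=f,
                     condition=preset.condition, replicate=replicate)


# -------------------------------------------------------------- preset table

def _mutant_k(allotype: str, activity: float) -> float:
    """Invert the relative-activity formula: k = k_none + r * (k_wt - k_none)."""
    k_none = UNCATALYZED_K
    k_wt = UNCATALYZED_K * TSN_WT_FOLD[allotype][0]
    return k_none + activity * (k_wt - k_none)


def preset_table() -> dict[tuple[str, str], FPPreset]:
    """Named FP presets for every published (allotype, catalyst) statistic.

    Keys are (allotype, catalyst).  Uncatalyzed rates are the conventional
    ``UNCATALYZED_K``; Tsn-WT and TAPBPR rates multiply it by the published
    fold change; scoop-loop mutant rates invert the relative-activity
    formula against the allotype's WT and uncatalyzed rates.
    """
    table: dict[tuple[str, str], FPPreset] = {}
    for allotype in sorted(TSN_WT_FOLD):
        table[(allotype, "none")] = FPPreset(allotype, "none", UNCATALYZED_K)
        table[(allotype, "Tsn-WT")] = FPPreset(
            allotype, "Tsn-WT", UNCATALYZED_K * TSN_WT_FOLD[allotype][0])
        table[(allotype, "TAPBPR")] = FPPreset(
            allotype, "TAPBPR", UNCATALYZED_K * TAPBPR_FOLD[allotype][0])
    for (allotype, mutant), (activity, _) in RELATIVE_ACTIVITY.items():
        table[(allotype, mutant)] = FPPreset(
            allotype, mutant, _mutant_k(allotype, activity))
    return table


def fp_preset(allotype: str, catalyst: str) -> FPPreset:
    """Look up one preset from :func:`preset_table`."""
    table = preset_table()
    try:
        return table[(allotype, catalyst)]
    except KeyError:
        raise KeyError(f"no published statistic encodes "
                       f"({allotype}, {catalyst})") from None


def manifest(presets, seed: int) -> pd.DataFrame:
    """Ground-truth manifest (preset name, seed, parameters) for a run."""
    rows = []
    for p in presets:
        rec = {"seed": seed, **p.__dict__}
        rec["preset"] = f"{getattr(p, 'allotype', getattr(p, 'condition', ''))}" \
                        f"/{getattr(p, 'catalyst', type(p).__name__)}"
        rows.append(rec)
    return pd.DataFrame(rows)
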
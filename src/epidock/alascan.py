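"""Binding-curve fitting, fold-change computation and restraint scenarios.

ELISA dose-response curves are fitted with a four-parameter logistic (4PL),

    A450(x) = bottom + (top - bottom) / (1 + (ec50 / x)^hill),

whose midpoint (EC50) serves as an apparent Kd. A mutant's effect is the
fold *decrease* in binding relative to wild type, either as a Kd ratio
(titration mode) or as a wild-type/mutant signal ratio at one concentration
(spot mode). Mutants whose curve cannot be fitted (binding knocked out) are
right-censored at a bound (default 100-fold) and classified in the top bin.

Fold-change bins mirror the asterisk convention of scanning figures:
none (1-2), * (2-10), ** (>10-100), *** (>100 or censored).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

from scipy.optimize import OptimizeWarning
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .structmodel import ResidueKey

__all__ = [
    "BindingCurve",
    "FourPLFit",
    "Bin",
    "FoldChangeRecord",
    "HotspotTable",
    "RestraintScenario",
    "fit_4pl",
    "fold_change",
    "classify_bins",
    "build_scenarios",
    "export_restraints",
    "read_restraints",
    "four_pl",
]


def four_pl(x, bottom, top, ec50, hill):
    """Four-parameter logistic response."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


@dataclass
class BindingCurve:
    mutant_id: str
    concentrations: Sequence[float]
    signals: Sequence[float]
    unit: str = "nM"
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if len(self.concentrations) != len(self.signals):
            raise ValueError("concentrations and signals must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.signals = self.signals[order]


@dataclass
class FourPLFit:
    mutant_id: str
    bottom: float
    top: float
    ec50: float
    hill: float
    converged: bool
    residual_rms: float = float("nan")

    @property
    def kd_estimate(self) -> float:
        return self.ec50


def fit_4pl(
    curve: BindingCurve,
    max_iter: int = 10000,
    min_amplitude: float = 0.1,
    hill_bounds: Tuple[float, float] = (0.2, 5.0),
) -> FourPLFit:
    """Least-squares 4PL fit with heuristic initialisation.

    Initialisation: bottom = min signal, top = max signal, hill = 1, EC50 =
    concentration nearest the half-range signal. The fit is flagged
    unconverged when the optimiser fails, the fitted amplitude is below
    ``min_amplitude`` (flat curve: no measurable binding) or the EC50 falls
    more than 10x above the top tested concentration.
    """
    x = curve.concentrations
    y = curve.signals
    if len(x) < 4:
        raise ValueError(f"{curve.mutant_id}: need >= 4 points to fit a 4PL")
    lo, hi = float(y.min()), float(y.max())
    half = 0.5 * (lo + hi)
    ec50_init = float(x[np.argmin(np.abs(y - half))])
    p0 = [lo, hi, ec50_init, 1.0]
    bounds = (
        [-np.inf, -np.inf, x.min() / 1e6, hill_bounds[0]],
        [np.inf, np.inf, x.max() * 1e6, hill_bounds[1]],
    )
    try:
        with warnings.catch_warnings():
            # degenerate (flat) curves legitimately yield an unestimable
            # covariance; convergence is judged below instead
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(four_pl, x, y, p0=p0, bounds=bounds, maxfev=max_iter)
    except (RuntimeError, ValueError):
        return FourPLFit(curve.mutant_id, lo, hi, float("nan"), float("nan"), False)
    bottom, top, ec50, hill = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((four_pl(x, *popt) - y) ** 2)))
    converged = (top - bottom) >= min_amplitude and ec50 <= 10.0 * x.max()
    return FourPLFit(curve.mutant_id, bottom, top, ec50, hill, converged, resid)


class Bin(enum.IntEnum):
    """Fold-decrease bins, ordered none < star < star2 < star3."""

    NONE = 0   # fold < 2 (includes improvements, fold < 1)
    STAR = 1   # 2 <= fold <= 10
    STAR2 = 2  # 10 < fold <= 100
    STAR3 = 3  # fold > 100, or censored

    @property
    def label(self) -> str:
        return {0: "none", 1: "*", 2: "**", 3: "***"}[int(self)]


def classify_bins(fold: Optional[float], censored: bool = False) -> Bin:
    """Bin a fold decrease per the asterisk legend (boundaries inclusive low)."""
    if censored:
        return Bin.STAR3
    if fold is None:
        raise ValueError("fold is None but record is not censored")
    if fold < 0:
        raise ValueError(f"negative fold change: {fold}")
    if fold < 2:
        return Bin.NONE
    if fold <= 10:
        return Bin.STAR
    if fold <= 100:
        return Bin.STAR2
    return Bin.STAR3


@dataclass
class FoldChangeRecord:
    mutant_id: str
    mode: str                      # "kd_ratio" | "spot_a450"
    fold: Optional[float]          # None when censored
    censored: bool
    censor_bound: float
    bin: Bin
    residue_key: Optional[ResidueKey] = None

    def __post_init__(self) -> None:
        if self.censored and self.bin != Bin.STAR3:
            raise ValueError("censored records must carry the top bin")

    @property
    def fold_label(self) -> str:
        return f">{self.censor_bound:g}" if self.censored else f"{self.fold:g}"


def fold_change(
    mutant: Union[FourPLFit, float],
    wildtype: Union[FourPLFit, float],
    mode: str = "kd_ratio",
    censor_bound: float = 100.0,
    mutant_id: Optional[str] = None,
    residue_key: Optional[ResidueKey] = None,
) -> FoldChangeRecord:
    """Fold decrease in binding of a mutant relative to wild type.

    kd_ratio mode: fold = Kd(mutant) / Kd(wild type) from 4PL fits; a
    non-converged mutant fit is censored at ``censor_bound``. spot_a450
    mode: fold = A450(wild type) / A450(mutant) at one concentration.
    """
    if mode == "kd_ratio":
        if not isinstance(mutant, FourPLFit) or not isinstance(wildtype, FourPLFit):
            raise TypeError("kd_ratio mode requires FourPLFit inputs")
        mid = mutant_id or mutant.mutant_id
        if not wildtype.converged:
            raise ValueError("wild-type fit did not converge; no reference Kd")
        if not mutant.converged:
            return FoldChangeRecord(
                mid, mode, None, True, censor_bound, Bin.STAR3, residue_key
            )
        fold = mutant.kd_estimate / wildtype.kd_estimate
    elif mode == "spot_a450":
        mut_sig = float(mutant)
        wt_sig = float(wildtype)
        mid = mutant_id or "mutant"
        if wt_sig <= 0:
            raise ValueError("wild-type spot signal must be positive")
        if mut_sig <= 0:
            return FoldChangeRecord(
                mid, mode, None, True, censor_bound, Bin.STAR3, residue_key
            )
        fold = wt_sig / mut_sig
    else:
        raise ValueError(f"unknown fold-change mode {mode!r}")
    if fold > censor_bound:
        return FoldChangeRecord(
            mid, mode, None, True, censor_bound, Bin.STAR3, residue_key
        )
    return FoldChangeRecord(
        mid, mode, float(fold), False, censor_bound, classify_bins(fold), residue_key
    )


@dataclass
class HotspotTable:
    records: Dict[str, FoldChangeRecord]
    hotspot_threshold_bin: Bin = Bin.STAR2

    def hotspots(self) -> List[FoldChangeRecord]:
        return [
            r for r in self.records.values() if r.bin >= self.hotspot_threshold_bin
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mutant_id": r.mutant_id,
                "mode": r.mode,
                "fold": r.fold if not r.censored else float("nan"),
                "censored": r.censored,
                "bin": r.bin.label,
                "hotspot": r.bin >= self.hotspot_threshold_bin,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RestraintScenario:
    """Active-residue restraints for one data-driven docking run."""

    name: str
    epitope_active: List[ResidueKey]
    paratope_active: List[ResidueKey]

    def __post_init__(self) -> None:
        if not self.epitope_active or not self.paratope_active:
            raise ValueError(f"scenario {self.name!r}: restraint sets must be non-empty")
        self.epitope_active = _dedup_sorted(self.epitope_active)
        self.paratope_active = _dedup_sorted(self.paratope_active)


def _dedup_sorted(keys: Iterable[ResidueKey]) -> List[ResidueKey]:
    return sorted(set(keys), key=lambda k: (k[0], k[1], k[2]))


def build_scenarios(
    epitope_groups: Mapping[str, Iterable[ResidueKey]],
    paratope_hotspots: Iterable[ResidueKey],
) -> List[RestraintScenario]:
    """One scenario per epitope hotspot group plus a combined scenario.

    The paratope restraint set is held constant across scenarios. When a
    single group is given (combined == the group) only one scenario is
    returned.
    """
    paratope = list(paratope_hotspots)
    if not epitope_groups:
        raise ValueError("need at least one epitope hotspot group")
    if not paratope:
        raise ValueError("paratope restraint set must be non-empty")
    scenarios = [
        RestraintScenario(name, list(group), paratope)
        for name, group in epitope_groups.items()
    ]
    combined: List[ResidueKey] = []
    for group in epitope_groups.values():
        combined.extend(group)
    combined_scenario = RestraintScenario("combined", combined, paratope)
    if all(s.epitope_active != combined_scenario.epitope_active for s in scenarios):
        scenarios.append(combined_scenario)
    return scenarios


def _format_keys(keys: List[ResidueKey]) -> str:
    return ",".join(f"{c}:{n}{i}" for c, n, i in keys)


def _parse_keys(text: str) -> List[ResidueKey]:
    keys = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        chain, rest = token.split(":")
        num = ""
        icode = ""
        for ch in rest:
            if ch.isdigit() or (ch == "-" and not num):
                num += ch
            else:
                icode += ch
        keys.append((chain, int(num), icode))
    return keys


def export_restraints(scenario: RestraintScenario, path) -> None:
    """Write a deterministic plain-text active-residue list."""
    lines = [
        f"name: {scenario.name}",
        f"antigen_active: {_format_keys(scenario.epitope_active)}",
        f"antibody_active: {_format_keys(scenario.paratope_active)}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_restraints(path) -> RestraintScenario:
    fields = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, value = line.partition(":")
            fields[key.strip()] = value.strip()
    return RestraintScenario(
        name=fields.get("name", "unnamed"),
        epitope_active=_parse_keys(fields["antigen_active"]),
        paratope_active=_parse_keys(fields["antibody_active"]),
    )
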
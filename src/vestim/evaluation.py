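"""Recruitment curves, ROC/AUC selectivity and charge/energy metrics.

Fiber recruitment of a branch at amplitude a is the fraction of its fibers
with activation threshold ≤ a — a right-continuous non-decreasing step
function.  Selectivity of a configuration is the area under the ROC curve
of target recruitment (true positive rate) against the recruitment of the
maximally activated non-target branch (false positive rate), swept over
amplitude: 1 = perfectly selective, 0 = anti-selective, 0.5 = neutral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .electrodes import StimulusWaveform
from .neuron import ThresholdResult
from .potential import UnitPotential


@dataclass
class RecruitmentCurve:
    """Sorted per-fiber thresholds of one branch; non-excitable fibers count
    in the denominator but never activate."""

    branch: str
    thresholds: np.ndarray     # sorted, may contain +inf
    n_total: int

    def __post_init__(self) -> None:
        self.thresholds = np.sort(np.asarray(self.thresholds, dtype=float))
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")

    @property
    def finite_thresholds(self) -> np.ndarray:
        return self.thresholds[np.isfinite(self.thresholds)]

    def recruitment(self, a: float | np.ndarray) -> np.ndarray | float:
        """Fraction of fibers with threshold ≤ a."""
        r = np.searchsorted(self.thresholds, np.asarray(a, dtype=float), side="right") / self.n_total
        return r if r.ndim else float(r)


def recruitment_curve(thresholds, n_total: int | None = None, branch: str = "") -> RecruitmentCurve:
    """Build a recruitment curve from raw thresholds or ThresholdResults."""
    if len(thresholds) and isinstance(thresholds[0], ThresholdResult):
        branch = branch or thresholds[0].branch
        thresholds = [r.threshold for r in thresholds]
    thr = np.asarray(list(thresholds), dtype=float)
    return RecruitmentCurve(branch, thr, n_total if n_total is not None else len(thr))


def amplitude_for_recruitment(curve: RecruitmentCurve, level: float) -> float:
    """Smallest amplitude with recruitment ≥ level: the ⌈level·N⌉-th order
    statistic of the thresholds."""
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    k = int(np.ceil(level * curve.n_total))
    finite = curve.finite_thresholds
    if k > len(finite):
        raise ValueError(
            f"recruitment level {level} unattainable: max attainable is "
            f"{len(finite) / curve.n_total:.3f}"
        )
    return float(curve.thresholds[k - 1])


def roc_auc(target: RecruitmentCurve, nontargets: list[RecruitmentCurve]) -> float:
    """Area under target-vs-max-non-target recruitment, swept over amplitude.

    The sweep visits every distinct finite threshold; the staircase is
    completed with (0,0) and (1,1) endpoints and integrated with the
    trapezoidal rule.
    """
    if curve_is_empty(target):
        raise ValueError("target recruitment curve is empty")
    if not nontargets:
        raise ValueError("need at least one non-target recruitment curve")
    amps = np.unique(
        np.concatenate([target.finite_thresholds]
                       + [c.finite_thresholds for c in nontargets])
    )
    tpr = np.atleast_1d(target.recruitment(amps))
    fpr = np.max([np.atleast_1d(c.recruitment(amps)) for c in nontargets], axis=0)
    x = np.concatenate([[0.0], fpr, [1.0]])
    y = np.concatenate([[0.0], tpr, [1.0]])
    return float(np.trapezoid(y, x))


def curve_is_empty(curve: RecruitmentCurve) -> bool:
    return len(curve.thresholds) == 0


def charge_per_pulse(waveform: StimulusWaveform, amplitude: float) -> dict[str, float]:
    """Injected charge: per-polarity magnitudes and the net (balance) residual."""
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    qneg, qpos = waveform.abs_integral_by_sign()
    return {
        "cathodic_C": amplitude * qneg,
        "anodic_C": amplitude * qpos,
        "net_C": amplitude * waveform.integral(),
        "total_abs_C": amplitude * (qneg + qpos),
    }


def access_resistance(unit: UnitPotential) -> float:
    """Lumped access resistance implied by the FEM unit-current solution:
    mean potential over the active-electrode vertices minus mean over the
    reference vertices (0 for the grounded saline surface), per 1 A."""
    mesh = unit.mesh
    if unit.active_vertices is not None:
        act = unit.active_vertices
    else:
        act = np.unique(
            np.concatenate([mesh.tets[mesh.tets_of_region(r)]
                            for r in unit.source.active_regions])
        )
    v_act = float(unit.values[act].mean())
    if unit.source.is_monopolar:
        v_ref = 0.0
    elif unit.reference_vertices is not None:
        v_ref = float(unit.values[unit.reference_vertices].mean())
    else:
        ref = np.unique(
            np.concatenate(
                [mesh.tets[mesh.tets_of_region(r)] for r in unit.source.reference_regions]
            )
        )
        v_ref = float(unit.values[ref].mean())
    return (v_act - v_ref) / unit.source.current


def energy_per_pulse(
    waveform: StimulusWaveform, amplitude: float, unit: UnitPotential
) -> float:
    """E = amplitude² · ∫w(t)²dt · R_access (joules per pulse)."""
    return amplitude**2 * waveform.squared_integral() * access_resistance(unit)


@dataclass
class SelectivityReport:
    """Evaluation summary of one electrode configuration at one target."""

    target_branch: str
    configuration: str
    auc: float
    amplitude_80pct: float                 # A
    curves: dict[str, RecruitmentCurve]
    charge: dict[str, float] = dc_field(default_factory=dict)
    energy_J: float = float("nan")
    access_resistance_ohm: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "target_branch": self.target_branch,
            "configuration": self.configuration,
            "auc": self.auc,
            "amplitude_80pct_A": self.amplitude_80pct,
            "access_resistance_ohm": self.access_resistance_ohm,
            "energy_J": self.energy_J,
            "charge": self.charge,
            "branches": {
                name: {
                    "n": c.n_total,
                    "thresholds_A": [None if not np.isfinite(t) else float(t)
                                     for t in c.thresholds],
                }
                for name, c in self.curves.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def evaluate_configuration(
    name: str,
    target_branch: str,
    curves: dict[str, RecruitmentCurve],
    waveform: StimulusWaveform,
    unit: UnitPotential | None = None,
    level: float = 0.8,
) -> SelectivityReport:
    """Assemble the per-configuration report (AUC, 80 % amplitude, charge,
    energy) from branch recruitment curves."""
    target = curves[target_branch]
    nontargets = [c for b, c in curves.items() if b != target_branch]
    auc = roc_auc(target, nontargets)
    a80 = amplitude_for_recruitment(target, level)
    rep = SelectivityReport(
        target_branch=target_branch,
        configuration=name,
        auc=auc,
        amplitude_80pct=a80,
        curves=curves,
        charge=charge_per_pulse(waveform, a80),
    )
    if unit is not None:
        rep.access_resistance_ohm = access_resistance(unit)
        rep.energy_J = energy_per_pulse(waveform, a80, unit)
    return rep
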
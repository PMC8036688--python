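"""Map-comparison metrics for validating simulated land-use maps.

Overall accuracy (OA), Cohen's kappa from the class confusion matrix,
and the Pontius figure of merit (FoM), the change-focused score

    FoM = B / (A + B + C + D)

with A = observed change simulated as persistence, B = observed change
simulated as the correct new class, C = observed change simulated as a
wrong class, and D = observed persistence simulated as change.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import ArgumentError
from .grids import N_CLASSES, LandUseMap


def _joint_active(a: LandUseMap, b: LandUseMap) -> np.ndarray:
    if a.shape != b.shape:
        raise ArgumentError("maps must share a shape")
    return a.active & b.active


def confusion_matrix(a: LandUseMap, b: LandUseMap) -> np.ndarray:
    """6×6 confusion counts over jointly active cells (rows: map a)."""
    act = _joint_active(a, b)
    m = np.zeros((N_CLASSES, N_CLASSES))
    np.add.at(m, (a.classes[act] - 1, b.classes[act] - 1), 1.0)
    return m


def overall_accuracy(a: LandUseMap, b: LandUseMap) -> float:
    """Share of jointly active cells with identical class."""
    act = _joint_active(a, b)
    n = int(act.sum())
    if n == 0:
        raise ArgumentError("maps share no active cells")
    return float((a.classes[act] == b.classes[act]).mean())


def kappa(a: LandUseMap, b: LandUseMap) -> float:
    """Cohen's kappa of the class confusion matrix.

    When expected agreement is 1 (both maps constant and equal) the
    coefficient is defined as 1.0 by convention.
    """
    m = confusion_matrix(a, b)
    n = m.sum()
    if n == 0:
        raise ArgumentError("maps share no active cells")
    po = np.trace(m) / n
    pe = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def figure_of_merit(
    obs_t0: LandUseMap, obs_t1: LandUseMap, sim_t1: LandUseMap
) -> float:
    """Figure of merit of a simulated map against observed change."""
    act = _joint_active(obs_t0, obs_t1) & sim_t1.active
    if obs_t0.shape != sim_t1.shape:
        raise ArgumentError("maps must share a shape")
    o0 = obs_t0.classes[act]
    o1 = obs_t1.classes[act]
    s1 = sim_t1.classes[act]
    obs_change = o0 != o1
    sim_change = o0 != s1
    A = int((obs_change & ~sim_change).sum())
    B = int((obs_change & sim_change & (s1 == o1)).sum())
    C = int((obs_change & sim_change & (s1 != o1)).sum())
    D = int((~obs_change & sim_change).sum())
    denom = A + B + C + D
    if denom == 0:
        warnings.warn(
            "no observed or simulated change; figure of merit defined as 0",
            stacklevel=2,
        )
        return 0.0
    return B / denom
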
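"""Non-compartmental exposure analysis for rich profiles.

Implements the linear-up/log-down trapezoidal AUC, "best fit" terminal
slope selection (maximise adjusted R^2 over all terminal windows of at
least three post-peak points, ties going to the wider window), and the
reference AUC/clearance used to validate single-sample model estimates:
``Cl_nca = dose / AUC_0-tau`` at steady state, with lambda_z
extrapolation to infinity for single-dose profiles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import Subject

__all__ = ["NCAResult", "auc_linuplogdown", "lambda_z_bestfit", "nca_reference"]

# adjusted-R^2 differences below this are treated as ties ("best fit" rule)
_R2_TIE_TOL = 1e-4


@dataclass
class NCAResult:
    subject_id: str
    occasion: str
    auc_0_tau: float
    cl_nca: float
    lambda_z: float | None
    adj_r2: float | None
    points_used: list
    auc_extrapolated: float | None = None
    flags: list = field(default_factory=list)


def auc_linuplogdown(times, concs) -> float:
    """Linear-up / log-down trapezoidal AUC.

    Rising (or flat) segments and segments touching a zero concentration
    use the linear trapezoid; strictly decreasing positive segments use
    the log trapezoid, which is exact for mono-exponential decline.
    """
    t = np.asarray(times, float)
    c = np.asarray(concs, float)
    if len(t) < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    auc = 0.0
    for i in range(len(t) - 1):
        c1, c2, dt = c[i], c[i + 1], t[i + 1] - t[i]
        if c2 < c1 and c2 > 0.0:
            auc += (c1 - c2) * dt / math.log(c1 / c2)
        else:
            auc += 0.5 * (c1 + c2) * dt
    return auc


def _adj_r2(x, y) -> tuple:
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, adj


def lambda_z_bestfit(times, concs):
    """Terminal-slope estimate with the "best fit" window rule.

    Considers every window of >= 3 positive-concentration points strictly
    after Cmax, fits log-linear regression, and keeps the window with the
    highest adjusted R^2 (ties resolved toward more points).  Returns
    ``(lambda_z, adj_r2, points_used)`` or ``(None, None, [])`` when no
    valid window exists.
    """
    t = np.asarray(times, float)
    c = np.asarray(concs, float)
    i_max = int(np.argmax(c))
    cand = [i for i in range(i_max + 1, len(t)) if c[i] > 0]
    if len(cand) < 3:
        return None, None, []
    best = None
    for start in range(len(cand) - 2):
        idx = cand[start:]
        slope, adj = _adj_r2(t[idx], np.log(c[idx]))
        if slope >= 0:
            continue
        if best is None or adj > best[1] + _R2_TIE_TOL:
            best = (-slope, adj, idx)
        # tie: earlier (wider) window already stored, keep it
    if best is None:
        return None, None, []
    return best[0], best[1], list(best[2])


def nca_reference(subject: Subject, occasion: str) -> NCAResult:
    """Model-free reference exposure for one rich profile.

    Steady-state occasions: ``AUC_0-tau`` by linear-up/log-down and
    ``Cl = dose / AUC_0-tau``; single-dose occasions extrapolate to
    infinity with lambda_z before taking ``Cl = dose / AUC_0-inf``.
    BLQ observations contribute zero concentration.
    """
    idx = subject.obs_in(occasion)
    if len(idx) < 5:
        raise ValueError(
            f"occasion {occasion!r} of subject {subject.id} has {len(idx)} points; "
            "rich-profile NCA needs >= 5 — use the model-based single-sample "
            "estimator for sparse data")
    reg = subject.regimens[occasion]
    t = subject.obs_time[idx]
    c = np.where(subject.obs_blq[idx], 0.0, subject.obs_conc[idx])
    c = np.maximum(c, 0.0)
    order = np.argsort(t)
    t, c = t[order], c[order]

    flags = []
    if t[0] == 0.0 and c[0] > c[-1] and reg.steady_state:
        flags.append("predose-above-trough")

    auc_tau = auc_linuplogdown(t, c)
    lam, adj, used = lambda_z_bestfit(t, c)
    auc_inf = None
    if reg.steady_state:
        cl = reg.dose / auc_tau
    else:
        if lam is None:
            # no usable terminal phase: fall back to the observed span
            flags.append("no-lambda-z; AUC to last observation used")
            cl = reg.dose / auc_tau
        else:
            auc_inf = auc_tau + c[-1] / lam
            cl = reg.dose / auc_inf
    return NCAResult(
        subject_id=subject.id, occasion=occasion, auc_0_tau=auc_tau,
        cl_nca=cl, lambda_z=lam, adj_r2=adj,
        points_used=[int(idx[order][i]) for i in used] if used else [],
        auc_extrapolated=auc_inf, flags=flags)
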
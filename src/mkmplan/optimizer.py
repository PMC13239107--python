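"""RBE-weighted spot-weight optimization and SOBP reference calibration.

The optimization variable space is the biological effect: per voxel
epsilon(w) = sum_s w_s d_s alpha_s + (sum_s w_s d_s sqrt(beta_s))^2, which is
smooth (quadratic) in the non-negative spot weights w.  The prescription is
converted to an effect target through the reference LQ, a squared underdose
penalty is applied on the PTV, a squared overdose penalty above 110% of the
prescription, plus optional OAR maximum-dose terms.  No plan normalization is
performed; objectives act on absolute dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .base_data import MachineModel
from .dose_engine import Beam, Phantom, influence_matrices
from .rbe_models import ReferenceRadiation


@dataclass(frozen=True)
class Prescription:
    """Clinical prescription and fractionation schedule.

    ``fractions_per_beam`` follows the per-beam fraction counts of the
    treatment schedule; the biological per-fraction prescription is the
    clinical dose divided by the clinical scaling factor.
    """

    clinical_per_fraction: float  # Gy(RBE)
    n_fractions: int
    beams_per_fraction: int
    fractions_per_beam: Tuple[int, ...]
    ref: ReferenceRadiation
    site: Optional[str] = None

    def __post_init__(self) -> None:
        if self.clinical_per_fraction <= 0 or self.n_fractions <= 0:
            raise ValueError("prescription doses and fractions must be positive")
        if sum(self.fractions_per_beam) != self.n_fractions * self.beams_per_fraction:
            raise ValueError(
                "per-beam fraction counts must sum to fractions x beams-per-fraction"
            )

    @property
    def biological_per_fraction(self) -> float:
        """Per-fraction biological (RBE-weighted, pre-scaling) dose in Gy."""
        return self.clinical_per_fraction / self.ref.clinical_factor

    @property
    def total_clinical(self) -> float:
        return self.clinical_per_fraction * self.n_fractions


@dataclass(frozen=True)
class ObjectiveSpec:
    """Quadratic planning objectives on the PTV and optional OAR terms."""

    ptv: str = "PTV"
    underdose_weight: float = 1.0
    overdose_factor: float = 1.10
    overdose_weight: float = 1.0
    oar_terms: Tuple[Tuple[str, float, float], ...] = ()  # (mask, max Gy(RBE), weight)

    def __post_init__(self) -> None:
        if self.overdose_factor <= 1.0:
            raise ValueError("overdose threshold factor must exceed 1")
        if min(self.underdose_weight, self.overdose_weight, 0.0) < 0:
            raise ValueError("objective weights must be non-negative")


def effect_target(ref: ReferenceRadiation, biological_dose: float) -> float:
    """LQ effect of the reference radiation at the given biological dose."""
    return ref.alpha_ref * biological_dose + ref.beta_ref * biological_dose**2


@dataclass
class _EffectProblem:
    """Preassembled voxel-effect machinery for one field."""

    m_d: object  # sparse (voxels x spots): dose
    m_a: object  # dose*alpha
    m_b: object  # dose*sqrt(beta)
    ptv_idx: np.ndarray
    eff_lo: float
    eff_hi: float
    w_under: float
    w_over: float
    oar_idx: List[np.ndarray] = field(default_factory=list)
    oar_eff: List[float] = field(default_factory=list)
    oar_w: List[float] = field(default_factory=list)

    def effect(self, w: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        lin = self.m_a @ w
        sq = self.m_b @ w
        return lin + sq**2, sq

    def cost_grad(self, w: np.ndarray) -> Tuple[float, np.ndarray]:
        eff, sq = self.effect(w)
        g_eff = np.zeros_like(eff)
        cost = 0.0

        e_ptv = eff[self.ptv_idx]
        under = np.maximum(0.0, self.eff_lo - e_ptv)
        over = np.maximum(0.0, e_ptv - self.eff_hi)
        n = max(len(self.ptv_idx), 1)
        cost += self.w_under * np.sum(under**2) / n
        cost += self.w_over * np.sum(over**2) / n
        g_ptv = (-2.0 * self.w_under * under + 2.0 * self.w_over * over) / n
        np.add.at(g_eff, self.ptv_idx, g_ptv)

        for idx, e_max, wt in zip(self.oar_idx, self.oar_eff, self.oar_w):
            e_oar = eff[idx]
            over_o = np.maximum(0.0, e_oar - e_max)
            m = max(len(idx), 1)
            cost += wt * np.sum(over_o**2) / m
            np.add.at(g_eff, idx, 2.0 * wt * over_o / m)

        grad = self.m_a.T @ g_eff + 2.0 * (self.m_b.T @ (g_eff * sq))
        return float(cost), np.asarray(grad)


def build_problem(
    phantom: Phantom,
    beam: Beam,
    machine: MachineModel,
    model: str,
    prescription: Prescription,
    objective: ObjectiveSpec,
) -> _EffectProblem:
    m_d, m_a, m_b = influence_matrices(phantom, beam, machine, model)
    if objective.ptv not in phantom.masks:
        raise ValueError(f"phantom has no mask named {objective.ptv!r}")
    ptv_idx = np.flatnonzero(phantom.masks[objective.ptv].ravel())
    reach = np.asarray((m_d @ np.ones(m_d.shape[1]))).ravel()[ptv_idx]
    if not np.any(reach > 0):
        raise ValueError("infeasible geometry: no spot reaches the target")
    d_p = prescription.biological_per_fraction
    ref = prescription.ref
    prob = _EffectProblem(
        m_d,
        m_a,
        m_b,
        ptv_idx,
        effect_target(ref, d_p),
        effect_target(ref, objective.overdose_factor * d_p),
        objective.underdose_weight,
        objective.overdose_weight,
    )
    for name, max_clinical, wt in objective.oar_terms:
        idx = np.flatnonzero(phantom.masks[name].ravel())
        prob.oar_idx.append(idx)
        prob.oar_eff.append(effect_target(ref, max_clinical / ref.clinical_factor))
        prob.oar_w.append(wt)
    return prob


def objective_cost(
    weights: np.ndarray, problem: _EffectProblem
) -> Tuple[float, np.ndarray]:
    """Scalar planning cost and its gradient with respect to spot weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("spot weights must be non-negative")
    return problem.cost_grad(w)


@dataclass
class OptimizationResult:
    weights: np.ndarray
    cost: float
    n_iterations: int
    converged: bool
    cost_history: List[float]


def optimize_field(
    phantom: Phantom,
    beam: Beam,
    machine: MachineModel,
    model: str,
    prescription: Prescription,
    objective: ObjectiveSpec | None = None,
    max_iter: int = 500,
    problem: _EffectProblem | None = None,
    w0: np.ndarray | None = None,
) -> OptimizationResult:
    """Optimize non-negative spot weights of one field (L-BFGS-B).

    Weights are initialised uniformly at the level that matches the mean
    target effect under uniform scaling; iterates are capped at ``max_iter``
    (typical convergence within a few hundred iterations).
    """
    objective = objective or ObjectiveSpec()
    if problem is None:
        problem = build_problem(phantom, beam, machine, model, prescription, objective)

    if w0 is None:
        ones = np.ones(problem.m_d.shape[1])
        eff_unit, _ = problem.effect(ones)
        mean_eff = float(np.mean(eff_unit[problem.ptv_idx]))
        if mean_eff <= 0:
            raise ValueError("infeasible geometry: no spot reaches the target")
        # solve a*s + b*s^2 = eff_lo for the uniform scale s
        a = float(np.mean((problem.m_a @ ones)[problem.ptv_idx]))
        b = float(np.mean((problem.m_b @ ones)[problem.ptv_idx]) ** 2)
        s = (np.sqrt(a**2 + 4 * b * problem.eff_lo) - a) / (2 * b) if b > 0 else problem.eff_lo / a
        w0 = np.full(problem.m_d.shape[1], s)

    history: List[float] = []

    # optimize in units of the initial weight level so gradients are O(1)
    scale = max(float(np.max(w0)), 1e-30)

    def fun(u):
        c, g = problem.cost_grad(u * scale)
        history.append(c)
        return c, g * scale

    res = minimize(
        fun,
        np.asarray(w0, dtype=float) / scale,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(w0),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )
    return OptimizationResult(
        np.maximum(res.x, 0.0) * scale,
        float(res.fun),
        int(res.nit),
        bool(res.success),
        history,
    )


# ---------------------------------------------------------------------------
# SOBP reference calibration
# ---------------------------------------------------------------------------


def calibrate_reference(
    machine: MachineModel,
    model: str,
    sobp_width_cm: float = 6.0,
    range_cm: float = 21.0,
    clinical_factor: float = 2.41,
    target_biological_gy: float = 2.0,
) -> ReferenceRadiation:
    """Derive (alpha_ref, beta_ref) from the midpoint of a flat SOBP.

    Optimizes the energy-layer weights of a 1-D depth SOBP (broad field:
    lateral spread integrates out, so the IDD is the depth profile) to a
    flat biological effect across [range - width, range], then returns the
    mixed-field LQ coefficients at the SOBP midpoint.  The mixing ratios,
    and hence the calibration, are invariant to the chosen effect level.
    """
    ranges = machine.ranges_cm
    lo, hi = range_cm - sobp_width_cm, range_cm
    usable = [
        e
        for e in machine.entries
        if lo - 1.0 <= e.peak_depth_cm <= hi + 0.3
    ]
    if len(usable) < 3 or max((e.peak_depth_cm for e in usable), default=0) < hi - 0.5:
        raise ValueError(
            f"machine range insufficient for a {sobp_width_cm} cm SOBP at {range_cm} cm"
        )
    z = np.arange(0.0, hi + 3.0, 0.05)
    idd = np.stack(
        [np.interp(z, e.depth_cm, e.idd, left=0.0, right=0.0) for e in usable]
    )
    alpha = np.stack([np.interp(z, e.depth_cm, e.alpha[model]) for e in usable])
    sqrt_beta = np.stack([np.interp(z, e.depth_cm, e.sqrt_beta[model]) for e in usable])

    in_sobp = (z >= lo) & (z <= hi)
    # flat-effect target: alpha/beta of the plateau follow from the model's
    # own coefficients, so target the effect of the requested biological dose
    # computed with mid-plateau coefficients of the deepest layer
    a_mid = float(alpha[-1][np.argmin(np.abs(z - (lo + hi) / 2))])
    b_mid = float(sqrt_beta[-1][np.argmin(np.abs(z - (lo + hi) / 2))]) ** 2
    eff_t = a_mid * target_biological_gy + b_mid * target_biological_gy**2

    def cost_grad(w):
        d = w @ idd
        lin = w @ (idd * alpha)
        sq = w @ (idd * sqrt_beta)
        eff = lin + sq**2
        resid = (eff - eff_t) * in_sobp
        cost = float(np.sum(resid**2))
        g_eff = 2.0 * resid
        grad = (idd * alpha) @ g_eff + 2.0 * (idd * sqrt_beta) @ (g_eff * sq)
        return cost, grad

    w0 = np.full(len(usable), eff_t / max(float((np.ones(len(usable)) @ idd)[in_sobp].mean()), 1e-12) / a_mid)
    scale = max(float(np.max(w0)), 1e-30)

    def scaled(u):
        c, g = cost_grad(u * scale)
        return c, g * scale

    res = minimize(
        scaled,
        w0 / scale,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(usable),
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    w = np.maximum(res.x, 0.0) * scale
    mid = int(np.argmin(np.abs(z - (lo + hi) / 2.0)))
    d_mid = w * idd[:, mid]
    if d_mid.sum() <= 0:
        raise ValueError("SOBP optimization failed: no dose at midpoint")
    a_ref = float(np.sum(d_mid * alpha[:, mid]) / d_mid.sum())
    sb_ref = float(np.sum(d_mid * sqrt_beta[:, mid]) / d_mid.sum())
    return ReferenceRadiation(a_ref, sb_ref**2, clinical_factor)
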
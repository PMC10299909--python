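"""Three-parameter logistic potency fits and the operational model of agonism.

The operational model is

    Y = Basal + (Em - Basal) / (1 + (10^logKA + 10^log[A]) / (10^logtau * 10^log[A]))

with efficacy tau = R_T/K_E. Efficacy is linear in receptor density, so a
ligand's tau measured on a cell line expressing the receptor at a different
level can be rescaled to a reference expression (tau_C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitFailure, ValidationError
from .synthetic import DoseResponseSet

__all__ = [
    "OperationalModel",
    "LogisticFit",
    "OperationalFit",
    "PanelOperationalFit",
    "EfficacyEstimate",
    "eval_operational",
    "eval_logistic",
    "fit_logistic",
    "fit_operational",
    "fit_operational_panel",
    "correct_efficacy_for_expression",
]


@dataclass(frozen=True)
class OperationalModel:
    basal: float
    em: float
    log_ka: float  # log10 molar functional dissociation constant
    log_tau: float  # log10 efficacy

    def __post_init__(self):
        if not self.em > self.basal:
            raise ValidationError("em must exceed basal")
        for name in ("basal", "em", "log_ka", "log_tau"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


def eval_operational(model: OperationalModel, log_a):
    """System response at log10 molar agonist concentration(s)."""
    la = np.asarray(log_a, dtype=float)
    ka = 10.0**model.log_ka
    a = 10.0**la
    tau = 10.0**model.log_tau
    out = model.basal + (model.em - model.basal) / (1.0 + (ka + a) / (tau * a))
    return out if out.ndim else float(out)


def eval_logistic(top: float, bottom: float, p_ec50: float, log_a):
    """Three-parameter logistic (Hill slope fixed at 1) over log10 molar conc."""
    la = np.asarray(log_a, dtype=float)
    out = bottom + (top - bottom) / (1.0 + 10.0 ** (-(p_ec50 + la)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    top: float
    bottom: float
    p_ec50: float
    se: dict
    rss: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "p_ec50": self.p_ec50,
            "se": self.se,
            "rss": self.rss,
            "n_obs": self.n_obs,
        }


@dataclass
class OperationalFit:
    model: OperationalModel
    se: dict
    rss: float
    n_obs: int
    log_ka_fixed: bool
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "basal": self.model.basal,
            "em": self.model.em,
            "log_ka": self.model.log_ka,
            "log_tau": self.model.log_tau,
            "se": self.se,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "log_ka_fixed": self.log_ka_fixed,
            "warnings": list(self.warnings),
        }


@dataclass
class PanelOperationalFit:
    """Shared-Em/Basal fit across a ligand panel with per-ligand KA and tau."""

    basal: float
    em: float
    per_ligand: dict  # ligand -> {"log_ka": float, "log_tau": float}
    se: dict
    rss: float
    n_obs: int
    warnings: list = field(default_factory=list)

    def model_for(self, ligand: str) -> OperationalModel:
        p = self.per_ligand[ligand]
        return OperationalModel(self.basal, self.em, p["log_ka"], p["log_tau"])


@dataclass
class EfficacyEstimate:
    log_tau: float
    log_tau_se: float
    log_tau_c: float
    log_tau_c_se: float
    reference_expression: float
    receptor_expression: float
    convention: str


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _extract_xy(data) -> tuple[np.ndarray, np.ndarray]:
    df = data.data if isinstance(data, DoseResponseSet) else pd.DataFrame(data)
    return df["log_conc_m"].to_numpy(float), df["response"].to_numpy(float)


def _check_dynamic_range(y: np.ndarray, what: str) -> None:
    scale = max(float(np.max(np.abs(y))), 1.0)
    if (np.max(y) - np.min(y)) < 1e-9 * scale:
        raise FitFailure(f"{what}: data have zero dynamic range", {"range": float(np.ptp(y))})


def _se_from_res(res, n: int) -> tuple[np.ndarray, np.ndarray]:
    """SEs and the parameter correlation matrix from the final Jacobian."""
    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    s = np.where(s > s.max() * 1e-12, s, np.inf)
    cov = vt.T @ np.diag(1.0 / s**2) @ vt
    dof = max(n - res.x.size, 1)
    cov = cov * 2.0 * res.cost / dof
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    denom = np.outer(se, se)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / denom, 0.0)
    return se, corr


def fit_logistic(data) -> LogisticFit:
    """Least-squares Top/Bottom/pEC50 with the Hill slope fixed at 1."""
    la, y = _extract_xy(data)
    if np.unique(la).size < 5:
        raise ValidationError("fit_logistic needs >= 5 distinct concentrations")
    _check_dynamic_range(y, "fit_logistic")

    def resid(x):
        return eval_logistic(x[0], x[1], x[2], la) - y

    best = None
    for pec0 in np.linspace(-la.max(), -la.min(), 5):
        res = least_squares(
            resid,
            x0=[float(np.max(y)), float(np.min(y)), pec0],
            xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=5000,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailure("logistic fit did not converge", {})
    se, _ = _se_from_res(best, la.size)
    return LogisticFit(
        top=float(best.x[0]), bottom=float(best.x[1]), p_ec50=float(best.x[2]),
        se={"top": float(se[0]), "bottom": float(se[1]), "p_ec50": float(se[2])},
        rss=float(2.0 * best.cost), n_obs=int(la.size),
    )


def fit_operational(data, log_ka_fixed: float | None = None) -> OperationalFit:
    """Fit Basal/Em/logKA/logtau to one dose-response set.

    When ``log_ka_fixed`` is given (the usual case: KA constrained to the
    binding-assay pKi), only Basal, Em and logtau are free. Basal is bounded
    below at zero. A near-unity logKA/logtau correlation is flagged.
    """
    la, y = _extract_xy(data)
    _check_dynamic_range(y, "fit_operational")
    ymax, ymin = float(np.max(y)), float(np.min(y))

    if log_ka_fixed is not None:

        def resid(x):
            basal, em, ltau = x
            return eval_operational(OperationalModel(basal, em, log_ka_fixed, ltau), la) - y

        best = None
        for ltau0 in (-1.0, 0.0, 1.0):
            res = least_squares(
                resid,
                x0=[max(ymin, 1e-9), ymax + 0.05 * (ymax - ymin), ltau0],
                bounds=([0.0, -np.inf, -12.0], [np.inf, np.inf, 12.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=5000,
            )
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitFailure("operational fit did not converge", {"log_ka_fixed": log_ka_fixed})
        se, _ = _se_from_res(best, la.size)
        model = OperationalModel(float(best.x[0]), float(best.x[1]), float(log_ka_fixed), float(best.x[2]))
        return OperationalFit(
            model=model,
            se={"basal": float(se[0]), "em": float(se[1]), "log_ka": 0.0, "log_tau": float(se[2])},
            rss=float(2.0 * best.cost), n_obs=int(la.size), log_ka_fixed=True,
        )

    def resid(x):
        basal, em, lka, ltau = x
        return eval_operational(OperationalModel(basal, em, lka, ltau), la) - y

    best = None
    for lka0 in np.linspace(la.min(), la.max(), 4):
        res = least_squares(
            resid,
            x0=[max(ymin, 1e-9), ymax + 0.05 * (ymax - ymin), lka0, 0.0],
            bounds=([0.0, -np.inf, la.min() - 8, -12.0], [np.inf, np.inf, la.max() + 8, 12.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=5000,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailure("operational fit did not converge", {})
    se, corr = _se_from_res(best, la.size)
    warns = []
    if abs(corr[2, 3]) > 0.999:
        warns.append("logKA and logtau are jointly unidentifiable (|corr| > 0.999); constrain KA")
    model = OperationalModel(float(best.x[0]), float(best.x[1]), float(best.x[2]), float(best.x[3]))
    return OperationalFit(
        model=model,
        se={"basal": float(se[0]), "em": float(se[1]), "log_ka": float(se[2]), "log_tau": float(se[3])},
        rss=float(2.0 * best.cost), n_obs=int(la.size), log_ka_fixed=False, warnings=warns,
    )


def fit_operational_panel(
    panel: Mapping[str, DoseResponseSet],
    log_ka_fixed: Mapping[str, float],
    ) -> PanelOperationalFit:
    """Global operational fit over a ligand panel sharing Em and Basal.

    Each ligand contributes its own logtau (logKA constrained per ligand);
    Em and Basal are global parameters of the cell line/assay.
    """
    ligands = list(panel)
    if not ligands:
        raise ValidationError("empty ligand panel")
    missing = [l for l in ligands if l not in log_ka_fixed]
    if missing:
        raise ValidationError(f"log_ka_fixed missing for ligands: {missing}")
    xs, ys = {}, {}
    for lig in ligands:
        xs[lig], ys[lig] = _extract_xy(panel[lig])
    y_all = np.concatenate([ys[l] for l in ligands])
    _check_dynamic_range(y_all, "fit_operational_panel")
    ymax, ymin = float(np.max(y_all)), float(np.min(y_all))

    def resid(x):
        basal, em = x[0], x[1]
        out = []
        for i, lig in enumerate(ligands):
            m = OperationalModel(basal, em, log_ka_fixed[lig], x[2 + i])
            out.append(eval_operational(m, xs[lig]) - ys[lig])
        return np.concatenate(out)

    x0 = [max(ymin, 1e-9), ymax + 0.05 * (ymax - ymin)] + [0.0] * len(ligands)
    lb = [0.0, -np.inf] + [-12.0] * len(ligands)
    ub = [np.inf, np.inf] + [12.0] * len(ligands)
    res = least_squares(
        resid, x0=x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000
    )
    if not res.success:
        raise FitFailure("panel operational fit did not converge", {"status": res.status})
    n = y_all.size
    se, _ = _se_from_res(res, n)
    per = {
        lig: {"log_ka": float(log_ka_fixed[lig]), "log_tau": float(res.x[2 + i])}
        for i, lig in enumerate(ligands)
    }
    se_d = {"basal": float(se[0]), "em": float(se[1])}
    se_d.update({f"log_tau[{lig}]": float(se[2 + i]) for i, lig in enumerate(ligands)})
    return PanelOperationalFit(
        basal=float(res.x[0]), em=float(res.x[1]), per_ligand=per,
        se=se_d, rss=float(2.0 * res.cost), n_obs=int(n),
    )


def correct_efficacy_for_expression(
    log_tau: float,
    log_tau_se: float,
    expression_b: float,
    expression_a: float,
    convention: str = "normalize",
) -> EfficacyEstimate:
    """Rescale efficacy measured at receptor B to receptor A's expression level.

    tau is proportional to receptor density, so the default ("normalize")
    convention computes tau_C = tau_B * expression_A / expression_B. The
    inverse ratio is available as convention="literal". The SE is unchanged
    on the log scale (expression levels treated as exact).
    """
    if convention not in ("normalize", "literal"):
        raise ValidationError("convention must be 'normalize' or 'literal'")
    if not (expression_a > 0 and expression_b > 0):
        raise ValidationError("receptor expressions must be > 0 (identical units)")
    if log_tau_se < 0:
        raise ValidationError("log_tau_se must be >= 0")
    shift = math.log10(expression_a / expression_b)
    if convention == "literal":
        shift = -shift
    return EfficacyEstimate(
        log_tau=log_tau,
        log_tau_se=log_tau_se,
        log_tau_c=log_tau + shift,
        log_tau_c_se=log_tau_se,
        reference_expression=expression_a,
        receptor_expression=expression_b,
        convention=convention,
    )
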
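"""Radioligand binding models: one-site saturation, one/two-site competition,
and competitor potency conversion.

All dissociation/inhibition constants are carried and reported as negative
log10 molar (pKd, pIC50, pKi). Fits are bounded nonlinear least squares with
multi-start initialization; a failed or degenerate fit raises
:class:`~pharmsel.errors.FitFailure` carrying diagnostics, never returning
silent defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, FitFailure, ValidationError
from .synthetic import BindingCurveSet

__all__ = [
    "SaturationModel",
    "SaturationFit",
    "TwoSiteCompetitionModel",
    "CompetitionFit",
    "eval_saturation",
    "fit_saturation",
    "eval_two_site",
    "fit_competition",
    "cheng_prusoff",
    "aicc",
]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaturationModel:
    """One-site saturation binding: Y = Bmax*[A]/([A]+Kd) + NS*[A]."""

    b_max: float
    p_kd: float  # -log10 molar
    ns_slope: float = 0.0  # signal per molar

    def __post_init__(self):
        if self.b_max <= 0:
            raise ValidationError("b_max must be > 0")
        if self.ns_slope < 0:
            raise ValidationError("ns_slope must be >= 0")


@dataclass(frozen=True)
class TwoSiteCompetitionModel:
    """Two-site competition displacement curve over log10 competitor conc.

    Site 1 is the high-affinity site (log_ic50_high <= log_ic50_low);
    ``fraction_high`` is its proportion of binding sites.
    """

    top: float
    bottom: float
    log_ic50_high: float
    log_ic50_low: float
    fraction_high: float

    def __post_init__(self):
        if self.top < self.bottom:
            raise ValidationError("top must be >= bottom")
        if not 0.0 <= self.fraction_high <= 1.0:
            raise ValidationError("fraction_high must lie in [0, 1]")
        if self.log_ic50_high > self.log_ic50_low:
            raise ValidationError("log_ic50_high must be <= log_ic50_low (site 1 = high affinity)")


def eval_saturation(model: SaturationModel, conc):
    """Specific plus nonspecific binding at radioligand concentration(s) in molar."""
    a = np.asarray(conc, dtype=float)
    if np.any(a < 0):
        raise DomainError("radioligand concentration must be >= 0")
    kd = 10.0 ** (-model.p_kd)
    out = model.b_max * a / (a + kd) + model.ns_slope * a
    return out if out.ndim else float(out)


def eval_two_site(model: TwoSiteCompetitionModel, log_b):
    """Displacement signal at log10 molar competitor concentration(s)."""
    lb = np.asarray(log_b, dtype=float)
    span = model.top - model.bottom
    f1 = model.fraction_high
    occ = f1 / (1.0 + 10.0 ** (lb - model.log_ic50_high)) + (1.0 - f1) / (
        1.0 + 10.0 ** (lb - model.log_ic50_low)
    )
    out = span * occ + model.bottom
    return out if out.ndim else float(out)


def cheng_prusoff(ic50: float, radioligand_conc: float, radioligand_kd: float) -> float:
    """Convert a competitor IC50 to pKi given radioligand conc and Kd (all molar)."""
    if ic50 <= 0 or radioligand_conc <= 0 or radioligand_kd <= 0:
        raise DomainError("cheng_prusoff requires strictly positive molar inputs")
    ki = ic50 / (1.0 + radioligand_conc / radioligand_kd)
    return -math.log10(ki)


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a Gaussian least-squares fit."""
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class SaturationFit:
    model: SaturationModel
    se: dict
    rss: float
    n_obs: int
    aicc: float
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "b_max": self.model.b_max,
            "p_kd": self.model.p_kd,
            "ns_slope": self.model.ns_slope,
            "se": self.se,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "aicc": self.aicc,
            "warnings": list(self.warnings),
        }


@dataclass
class CompetitionFit:
    model_kind: str  # "one_site" | "two_site"
    model: TwoSiteCompetitionModel
    se: dict
    rss: float
    n_obs: int
    aicc: float
    p_ki_high: float | None = None
    p_ki_low: float | None = None
    warnings: list = field(default_factory=list)
    alternative: "CompetitionFit | None" = None  # the rejected model in auto mode

    @property
    def p_ic50_high(self) -> float:
        return -self.model.log_ic50_high

    @property
    def p_ic50_low(self) -> float:
        return -self.model.log_ic50_low

    def to_dict(self) -> dict:
        d = {
            "model": self.model_kind,
            "top": self.model.top,
            "bottom": self.model.bottom,
            "p_ic50_high": self.p_ic50_high,
            "p_ic50_low": self.p_ic50_low,
            "fraction_high": self.model.fraction_high,
            "p_ki_high": self.p_ki_high,
            "p_ki_low": self.p_ki_low,
            "se": self.se,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "aicc": self.aicc,
            "warnings": list(self.warnings),
        }
        return d


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _as_frame(data) -> pd.DataFrame:
    return data.data if isinstance(data, BindingCurveSet) else pd.DataFrame(data)


def _param_se(res, n: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    s = np.where(s > s.max() * 1e-12, s, np.inf)
    cov = vt.T @ np.diag(1.0 / s**2) @ vt
    dof = max(n - res.x.size, 1)
    sigma2 = 2.0 * res.cost / dof
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.diag(cov) * sigma2)


def fit_saturation(total, nonspecific) -> SaturationFit:
    """Globally fit total + nonspecific saturation data sharing the NS slope.

    ``total`` and ``nonspecific`` each provide columns log_conc_m, signal;
    concentration grids need not match. Parameters: Bmax, pKd, NS.
    """
    tot, ns = _as_frame(total), _as_frame(nonspecific)
    a_tot = 10.0 ** tot["log_conc_m"].to_numpy(float)
    y_tot = tot["signal"].to_numpy(float)
    a_ns = 10.0 ** ns["log_conc_m"].to_numpy(float)
    y_ns = ns["signal"].to_numpy(float)
    if np.unique(a_tot).size < 4:
        raise ValidationError("fit_saturation needs >= 4 distinct radioligand concentrations")

    scale = float(np.max(np.abs(y_tot))) or 1.0
    if (np.max(y_tot) - np.min(y_tot)) < 1e-9 * scale:
        raise FitFailure(
            "total-binding data have zero dynamic range",
            {"signal_range": float(np.max(y_tot) - np.min(y_tot))},
        )

    ns0 = float(np.polyfit(a_ns, y_ns, 1)[0]) if a_ns.size >= 2 else 0.0
    ns0 = max(ns0, 0.0)
    bmax0 = max(float(np.max(y_tot) - ns0 * np.max(a_tot)), 1e-6 * scale)
    pkd0 = -float(np.median(tot["log_conc_m"]))

    def resid(x):
        bmax, pkd, nsl = x
        kd = 10.0**-pkd
        r1 = bmax * a_tot / (a_tot + kd) + nsl * a_tot - y_tot
        r2 = nsl * a_ns - y_ns
        return np.concatenate([r1, r2])

    res = least_squares(
        resid,
        x0=[bmax0, pkd0, ns0],
        bounds=([1e-12, 0.0, 0.0], [np.inf, 15.0, np.inf]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12, max_nfev=5000,
    )
    if not res.success:
        raise FitFailure("saturation fit did not converge", {"status": res.status, "message": res.message})
    n = a_tot.size + a_ns.size
    se = _param_se(res, n)
    rss = float(2.0 * res.cost)
    model = SaturationModel(b_max=float(res.x[0]), p_kd=float(res.x[1]), ns_slope=float(res.x[2]))
    return SaturationFit(
        model=model,
        se={"b_max": float(se[0]), "p_kd": float(se[1]), "ns_slope": float(se[2])},
        rss=rss,
        n_obs=n,
        aicc=aicc(max(rss, 1e-300), n, 3),
    )


def _fit_one_site(lb: np.ndarray, y: np.ndarray):
    top0, bot0 = float(np.max(y)), float(np.min(y))
    starts = np.linspace(lb.min(), lb.max(), 5)

    def resid(x):
        top, bot, lic = x
        return (top - bot) / (1.0 + 10.0 ** (lb - lic)) + bot - y

    best = None
    for lic0 in starts:
        res = least_squares(
            resid,
            x0=[top0, bot0, lic0],
            bounds=([-np.inf, -np.inf, lb.min() - 6], [np.inf, np.inf, lb.max() + 6]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12, max_nfev=5000,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    return best


def _fit_two_site(lb: np.ndarray, y: np.ndarray):
    top0, bot0 = float(np.max(y)), float(np.min(y))
    span = lb.max() - lb.min()
    grid = np.linspace(lb.min(), lb.max(), 5)

    def resid(x):
        top, bot, lic1, lic2, f1 = x
        occ = f1 / (1.0 + 10.0 ** (lb - lic1)) + (1.0 - f1) / (1.0 + 10.0 ** (lb - lic2))
        return (top - bot) * occ + bot - y

    best = None
    for lic1 in grid:
        for dlic in (0.5, span / 2 if span > 1 else 1.0, 3.0):
            res = least_squares(
                resid,
                x0=[top0, bot0, lic1, min(lic1 + dlic, lb.max() + 6), 0.5],
                bounds=(
                    [-np.inf, -np.inf, lb.min() - 6, lb.min() - 6, 0.0],
                    [np.inf, np.inf, lb.max() + 6, lb.max() + 6, 1.0],
                ),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12, max_nfev=5000,
            )
            if res.success and (best is None or res.cost < best.cost):
                best = res
    return best


def _competition_fit_from_res(kind, res, n, radioligand_conc, radioligand_kd) -> CompetitionFit:
    warns = []
    if kind == "one_site":
        top, bot, lic = res.x
        se_raw = _param_se(res, n)
        model = TwoSiteCompetitionModel(
            top=float(top), bottom=float(bot), log_ic50_high=float(lic),
            log_ic50_low=float(lic), fraction_high=1.0,
        )
        se = {"top": float(se_raw[0]), "bottom": float(se_raw[1]), "log_ic50_high": float(se_raw[2])}
        k = 3
    else:
        top, bot, lic1, lic2, f1 = res.x
        se_raw = _param_se(res, n)
        se = {
            "top": float(se_raw[0]),
            "bottom": float(se_raw[1]),
            "log_ic50_high": float(se_raw[2]),
            "log_ic50_low": float(se_raw[3]),
            "fraction_high": float(se_raw[4]),
        }
        # Eq. is label-symmetric: relabel so site 1 is the high-affinity one.
        if lic1 > lic2:
            lic1, lic2, f1 = lic2, lic1, 1.0 - f1
            se["log_ic50_high"], se["log_ic50_low"] = se["log_ic50_low"], se["log_ic50_high"]
        if f1 <= 1e-9 or f1 >= 1.0 - 1e-9:
            warns.append("fraction_high pinned at a bound; two-site model likely over-parameterized")
        model = TwoSiteCompetitionModel(
            top=float(top), bottom=float(bot), log_ic50_high=float(lic1),
            log_ic50_low=float(lic2), fraction_high=float(f1),
        )
        k = 5
    rss = float(2.0 * res.cost)
    fit = CompetitionFit(
        model_kind=kind, model=model, se=se, rss=rss, n_obs=n,
        aicc=aicc(max(rss, 1e-300), n, k), warnings=warns,
    )
    if radioligand_conc is not None and radioligand_kd is not None:
        fit.p_ki_high = cheng_prusoff(10.0**model.log_ic50_high, radioligand_conc, radioligand_kd)
        fit.p_ki_low = cheng_prusoff(10.0**model.log_ic50_low, radioligand_conc, radioligand_kd)
    return fit


def fit_competition(
    data,
    sites: str = "auto",
    radioligand_conc: float | None = None,
    radioligand_kd: float | None = None,
) -> CompetitionFit:
    """Fit a one- or two-site competition curve; ``sites`` in {one, two, auto}.

    Auto mode fits both and keeps the lower-AICc model, recording the other
    under ``.alternative``. If the radioligand concentration and Kd (molar)
    are given, IC50s are converted to pKi via Cheng-Prusoff.
    """
    if sites not in ("one", "two", "auto"):
        raise ValidationError("sites must be 'one', 'two' or 'auto'")
    df = _as_frame(data)
    lb = df["log_conc_m"].to_numpy(float)
    y = df["signal"].to_numpy(float)
    if np.unique(lb).size < 6:
        raise ValidationError("fit_competition needs >= 6 distinct competitor concentrations")
    if (np.max(y) - np.min(y)) < 1e-9 * max(float(np.max(np.abs(y))), 1.0):
        raise FitFailure("competition data have zero dynamic range", {"signal_range": float(np.ptp(y))})

    n = lb.size
    fits: dict[str, CompetitionFit] = {}
    for kind, fitter in (("one_site", _fit_one_site), ("two_site", _fit_two_site)):
        if sites == "one" and kind == "two_site":
            continue
        if sites == "two" and kind == "one_site":
            continue
        res = fitter(lb, y)
        if res is None:
            raise FitFailure(f"{kind} competition fit did not converge", {"model": kind})
        fits[kind] = _competition_fit_from_res(kind, res, n, radioligand_conc, radioligand_kd)

    if sites == "one":
        return fits["one_site"]
    if sites == "two":
        return fits["two_site"]
    one, two = fits["one_site"], fits["two_site"]
    if two.aicc < one.aicc:
        two.alternative = one
        return two
    one.alternative = two
    return one
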
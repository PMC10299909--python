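"""Ground-truth synthetic data generators.

Every generator takes a frozen spec with an integer seed, draws replicate
noise from deterministically derived sub-streams, and attaches the true
parameters as metadata so downstream fits can be checked against ground
truth. With ``noise_sd=0`` the output equals the closed-form model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DoseResponseSpec",
    "BindingCurveSpec",
    "MarkovTraceSpec",
    "DoseResponseSet",
    "BindingCurveSet",
    "generate_dose_response",
    "generate_binding_curve",
    "generate_markov_trace",
    "wrap_degrees",
]


def wrap_degrees(x):
    """Wrap angles in degrees onto (-180, 180]."""
    w = np.asarray(x, dtype=float)
    w = -((-w + 180.0) % 360.0 - 180.0)
    return w


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _strictly_increasing(grid) -> bool:
    g = np.asarray(grid, dtype=float)
    return g.size > 0 and bool(np.all(np.diff(g) > 0))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSet:
    """Replicated (log10 molar concentration, response) observations.

    ``data`` columns: ligand, receptor, log_conc_m, response, replicate.
    ``meta`` carries ground-truth parameters when synthetic.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)


@dataclass
class BindingCurveSet:
    """Radioligand binding observations.

    ``data`` columns: log_conc_m, signal, replicate and, for saturation
    data, a ``series`` column distinguishing total from nonspecific binding.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseSpec:
    basal: float
    em: float
    log_ka: float
    log_tau: float
    conc_grid: tuple  # log10 molar, strictly increasing
    n_replicates: int = 3
    noise_sd: float = 0.0
    seed: int = 0
    ligand: str = "ligand"
    receptor: str = "receptor"

    def __post_init__(self):
        _check(self.em > self.basal, "em must exceed basal")
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(_strictly_increasing(self.conc_grid), "conc_grid must be strictly increasing")


def generate_dose_response(spec: DoseResponseSpec) -> DoseResponseSet:
    """Draw noisy responses from the operational model at known parameters."""
    from .operational import OperationalModel, eval_operational

    model = OperationalModel(
        basal=spec.basal, em=spec.em, log_ka=spec.log_ka, log_tau=spec.log_tau
    )
    grid = np.asarray(spec.conc_grid, dtype=float)
    clean = eval_operational(model, grid)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    rows = []
    for rep, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        noise = rng.normal(0.0, spec.noise_sd, size=grid.size) if spec.noise_sd > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "ligand": spec.ligand,
                    "receptor": spec.receptor,
                    "log_conc_m": grid,
                    "response": clean + noise,
                    "replicate": rep,
                }
            )
        )
    meta = {
        "generator": "dose_response",
        "truth": {
            "basal": spec.basal,
            "em": spec.em,
            "log_ka": spec.log_ka,
            "log_tau": spec.log_tau,
        },
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return DoseResponseSet(pd.concat(rows, ignore_index=True), meta)


# ---------------------------------------------------------------------------
# binding curves
# ---------------------------------------------------------------------------

BindingMode = Literal["saturation", "competition_one_site", "competition_two_site"]


@dataclass(frozen=True)
class BindingCurveSpec:
    mode: str
    conc_grid: tuple  # log10 molar: radioligand [A] (saturation) or competitor [B]
    noise_sd: float = 0.0
    seed: int = 0
    n_replicates: int = 1
    # saturation parameters
    bmax: float | None = None
    p_kd_radioligand: float | None = None
    ns_slope: float = 0.0
    # competition parameters
    top: float | None = None
    bottom: float | None = None
    p_ic50_high: float | None = None
    p_ic50_low: float | None = None
    fraction_high: float | None = None

    def __post_init__(self):
        _check(
            self.mode in ("saturation", "competition_one_site", "competition_two_site"),
            f"unknown mode {self.mode!r}",
        )
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(_strictly_increasing(self.conc_grid), "conc_grid must be strictly increasing")
        if self.mode == "saturation":
            _check(self.bmax is not None and self.bmax > 0, "saturation requires bmax > 0")
            _check(self.p_kd_radioligand is not None, "saturation requires p_kd_radioligand")
            _check(self.ns_slope >= 0, "ns_slope must be >= 0")
        else:
            _check(self.top is not None and self.bottom is not None, "competition requires top and bottom")
            _check(self.top > self.bottom, "top must exceed bottom")
            _check(self.p_ic50_high is not None, "competition requires p_ic50_high")
            if self.mode == "competition_one_site":
                _check(
                    self.p_ic50_low is None and self.fraction_high is None,
                    "two-site parameters supplied in one-site mode",
                )
            else:
                _check(self.p_ic50_low is not None, "two-site mode requires p_ic50_low")
                _check(self.fraction_high is not None, "two-site mode requires fraction_high")
                _check(0.0 <= self.fraction_high <= 1.0, "fraction_high must lie in [0, 1]")
                _check(
                    self.p_ic50_high >= self.p_ic50_low,
                    "high-affinity site must have p_ic50_high >= p_ic50_low",
                )


def _binding_clean_signal(spec: BindingCurveSpec, grid: np.ndarray):
    """Evaluate the noiseless model. Returns dict series -> signal array."""
    from .binding import SaturationModel, TwoSiteCompetitionModel, eval_saturation, eval_two_site

    if spec.mode == "saturation":
        model = SaturationModel(
            b_max=spec.bmax, p_kd=spec.p_kd_radioligand, ns_slope=spec.ns_slope
        )
        conc = 10.0**grid
        return {"total": eval_saturation(model, conc), "nonspecific": spec.ns_slope * conc}
    if spec.mode == "competition_one_site":
        model = TwoSiteCompetitionModel(
            top=spec.top,
            bottom=spec.bottom,
            log_ic50_high=-spec.p_ic50_high,
            log_ic50_low=-spec.p_ic50_high,
            fraction_high=1.0,
        )
    else:
        model = TwoSiteCompetitionModel(
            top=spec.top,
            bottom=spec.bottom,
            log_ic50_high=-spec.p_ic50_high,
            log_ic50_low=-spec.p_ic50_low,
            fraction_high=spec.fraction_high,
        )
    return {"competition": eval_two_site(model, grid)}


def generate_binding_curve(spec: BindingCurveSpec) -> BindingCurveSet:
    """Draw noisy binding signals from the selected model.

    Saturation mode emits paired ``total`` and ``nonspecific`` series (the
    input the global saturation fit expects); competition modes emit a single
    displacement series over the competitor grid.
    """
    grid = np.asarray(spec.conc_grid, dtype=float)
    clean = _binding_clean_signal(spec, grid)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates * len(clean))
    rows = []
    k = 0
    for series, signal in clean.items():
        for rep in range(1, spec.n_replicates + 1):
            rng = np.random.default_rng(streams[k])
            k += 1
            noise = rng.normal(0.0, spec.noise_sd, size=grid.size) if spec.noise_sd > 0 else 0.0
            rows.append(
                pd.DataFrame(
                    {
                        "log_conc_m": grid,
                        "signal": signal + noise,
                        "replicate": rep,
                        "series": series,
                    }
                )
            )
    truth = {
        f.name: getattr(spec, f.name)
        for f in spec.__dataclass_fields__.values()
        if f.name not in ("conc_grid", "seed", "noise_sd", "n_replicates")
        and getattr(spec, f.name) is not None
    }
    meta = {"generator": "binding_curve", "truth": truth, "noise_sd": spec.noise_sd, "seed": spec.seed}
    return BindingCurveSet(pd.concat(rows, ignore_index=True), meta)


# ---------------------------------------------------------------------------
# two-state Markov feature traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkovTraceSpec:
    """Two-state hidden chain emitting Gaussian trajectory features.

    ``open_state_emissions`` / ``closed_state_emissions`` map feature name to
    (mean, sd); dihedral features (wrapped to (-180, 180]) are those listed
    in ``dihedral_features`` or, if that is None, those whose name contains
    "chi" or "dihedral".
    """

    n_frames: int
    dt: float  # ns per frame
    p_open_to_closed: float
    p_closed_to_open: float
    open_state_emissions: Mapping[str, tuple]
    closed_state_emissions: Mapping[str, tuple]
    features: tuple
    burn_in_ns: float = 0.0
    seed: int = 0
    initial_state: str = "stationary"  # open | closed | stationary
    dihedral_features: tuple | None = None
    simulation_id: str = "sim"

    def __post_init__(self):
        _check(self.n_frames >= 1, "n_frames must be >= 1")
        _check(self.dt > 0, "dt must be > 0")
        for name, p in (("p_open_to_closed", self.p_open_to_closed), ("p_closed_to_open", self.p_closed_to_open)):
            _check(0.0 <= p <= 1.0, f"{name} must lie in [0, 1]")
        _check(self.n_frames * self.dt >= self.burn_in_ns, "trace shorter than burn_in_ns")
        _check(self.initial_state in ("open", "closed", "stationary"), "bad initial_state")
        if self.initial_state == "stationary":
            _check(
                self.p_open_to_closed + self.p_closed_to_open > 0,
                "stationary initial state undefined for a frozen chain; set initial_state",
            )
        for feat in self.features:
            for side, em in (("open", self.open_state_emissions), ("closed", self.closed_state_emissions)):
                _check(feat in em, f"missing {side}-state emission for feature {feat!r}")
                _check(em[feat][1] > 0, f"emission sd for {feat!r} ({side}) must be > 0")

    def is_dihedral(self, feature: str) -> bool:
        if self.dihedral_features is not None:
            return feature in self.dihedral_features
        return "chi" in feature or "dihedral" in feature

    @property
    def stationary_open_occupancy(self) -> float:
        denom = self.p_open_to_closed + self.p_closed_to_open
        if denom == 0:
            raise ValidationError("frozen chain has no unique stationary distribution")
        return self.p_closed_to_open / denom


def generate_markov_trace(spec: MarkovTraceSpec):
    """Simulate the hidden chain and emit per-frame features.

    Returns a :class:`pharmsel.trajstate.FeatureSeries` whose data frame
    includes a ``true_state`` column (1 = open) for oracle tests.
    """
    from .trajstate import FeatureSeries

    ss = np.random.SeedSequence(spec.seed).spawn(1 + len(spec.features))
    rng_chain = np.random.default_rng(ss[0])

    if spec.initial_state == "stationary":
        state0 = int(rng_chain.random() < spec.stationary_open_occupancy)
    else:
        state0 = 1 if spec.initial_state == "open" else 0

    u = rng_chain.random(spec.n_frames - 1) if spec.n_frames > 1 else np.empty(0)
    states = np.empty(spec.n_frames, dtype=np.int8)
    states[0] = state0
    for i in range(1, spec.n_frames):
        if states[i - 1] == 1:
            states[i] = 0 if u[i - 1] < spec.p_open_to_closed else 1
        else:
            states[i] = 1 if u[i - 1] < spec.p_closed_to_open else 0

    time = np.arange(spec.n_frames, dtype=float) * spec.dt
    cols = {"time_ns": time}
    open_mask = states == 1
    for feat, stream in zip(spec.features, ss[1:]):
        rng = np.random.default_rng(stream)
        mu_o, sd_o = spec.open_state_emissions[feat]
        mu_c, sd_c = spec.closed_state_emissions[feat]
        vals = rng.normal(np.where(open_mask, mu_o, mu_c), np.where(open_mask, sd_o, sd_c))
        if spec.is_dihedral(feat):
            vals = wrap_degrees(vals)
        cols[feat] = vals
    cols["true_state"] = states.astype(int)
    meta = {
        "generator": "markov_trace",
        "truth": {
            "p_open_to_closed": spec.p_open_to_closed,
            "p_closed_to_open": spec.p_closed_to_open,
            "open_state_emissions": {k: list(v) for k, v in spec.open_state_emissions.items()},
            "closed_state_emissions": {k: list(v) for k, v in spec.closed_state_emissions.items()},
        },
        "burn_in_ns": spec.burn_in_ns,
        "seed": spec.seed,
    }
    return FeatureSeries(
        simulation_id=spec.simulation_id, data=pd.DataFrame(cols), meta=meta
    )
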
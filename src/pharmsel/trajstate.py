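"""Trajectory feature computation, threshold state classifiers and
occupancy/frequency estimation.

Conventions, fixed here because upstream tooling never states them:
all thresholds are strict inequalities and interval endpoints are excluded;
dihedrals are degrees on (-180, 180]; equilibration exclusion windows are
expressed in ns and converted through the frame time axis, so mixed frame
rates stay correct. Frames with time < the exclusion window are masked out
of every frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

__all__ = [
    "FeatureSeries",
    "StateSeries",
    "FrequencyEstimate",
    "ResidueMap",
    "DEFAULT_RESIDUE_MAPS",
    "FEATURE_DEF_BUILDERS",
    "standard_feature_defs",
    "compute_features",
    "distance",
    "dihedral",
    "classify_channel_open",
    "classify_active",
    "classify_tm6_outward",
    "classify_tail_vertical",
    "state_frequency",
    "moving_average",
    "grouped_fraction",
    "CHANNEL_OPEN_CHI1_RANGE",
    "ACTIVE_TM3_TM6_MIN_A",
    "TM6_OUTWARD_MIN_A",
    "TAIL_VERTICAL_MAX_A",
    "DEFAULT_EXCLUDE_NS",
    "TAIL_EXCLUDE_NS",
]

# classifier thresholds (strict) and equilibration windows
CHANNEL_OPEN_CHI1_RANGE = (-50.0, 100.0)  # degrees, open interval
ACTIVE_TM3_TM6_MIN_A = 10.0
TM6_OUTWARD_MIN_A = 20.7
TAIL_VERTICAL_MAX_A = 8.9
DEFAULT_EXCLUDE_NS = 50.0
TAIL_EXCLUDE_NS = 100.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureSeries:
    """Per-frame named features over a uniform, strictly increasing time axis.

    ``data`` holds a ``time_ns`` column plus one column per feature
    (distances in angstroms, dihedrals in degrees on (-180, 180]).
    """

    simulation_id: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if "time_ns" not in self.data.columns:
            raise ValidationError("FeatureSeries requires a time_ns column")
        t = self.time
        if t.size and not np.all(np.diff(t) > 0):
            raise DataError("FeatureSeries time axis must be strictly increasing")

    @property
    def time(self) -> np.ndarray:
        return self.data["time_ns"].to_numpy(float)

    @property
    def feature_names(self) -> list:
        return [c for c in self.data.columns if c not in ("time_ns", "true_state")]

    def feature(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise ValidationError(f"feature {name!r} not present in series {self.simulation_id!r}")
        return self.data[name].to_numpy(float)


@dataclass
class StateSeries:
    """Boolean per-frame labels for one named state plus an eligibility mask."""

    simulation_id: str
    state: str
    time: np.ndarray
    values: np.ndarray  # bool labels
    mask: np.ndarray  # True = frame eligible (past equilibration)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.time) == len(self.values) == len(self.mask)):
            raise ValidationError("StateSeries arrays must have equal length")


@dataclass
class FrequencyEstimate:
    simulation_id: str
    state: str
    fraction: float | None  # None = no eligible frames (missing, not zero)
    n_frames_used: int
    group: str | None = None


@dataclass(frozen=True)
class ResidueMap:
    """Maps Ballesteros-Weinstein positions to sequence residue numbers for a
    receptor subtype, plus the ligand mid-tail atom and ECL2 anchor residue."""

    subtype: str
    mapping: Mapping[str, int]  # BW position -> residue number
    ligand_tail_atom: str | None = None  # e.g. "LIG:C17"
    ecl2_residue: int | None = None

    def __post_init__(self):
        vals = list(self.mapping.values())
        if len(set(vals)) != len(vals):
            raise ValidationError("residue mapping must be injective")

    def resolve(self, bw: str) -> int:
        if bw not in self.mapping:
            raise ValidationError(f"BW position {bw} not mapped for subtype {self.subtype}")
        return self.mapping[bw]

    @classmethod
    def from_json(cls, path) -> "ResidueMap":
        d = json.loads(Path(path).read_text())
        return cls(
            subtype=d["subtype"],
            mapping=dict(d["mapping"]),
            ligand_tail_atom=d.get("ligand_tail_atom"),
            ecl2_residue=d.get("ecl2_residue"),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "subtype": self.subtype,
                    "mapping": dict(self.mapping),
                    "ligand_tail_atom": self.ligand_tail_atom,
                    "ecl2_residue": self.ecl2_residue,
                },
                indent=2,
            )
        )


# Residue numbers as printed for the M2 receptor; M4 ships only its printed
# ECL2 anchor. Other subtypes take user-supplied maps.
DEFAULT_RESIDUE_MAPS = {
    "M2": ResidueMap(
        subtype="M2",
        mapping={"5.43": 191, "6.56": 408, "4.57": 155, "6.55": 407},
        ecl2_residue=181,
    ),
    "M4": ResidueMap(subtype="M4", mapping={}, ecl2_residue=190),
}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def distance(p1, p2) -> np.ndarray:
    """Euclidean distance between two points or (n, 3) point arrays."""
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle (degrees, (-180, 180]) over four points.

    Praxeolitic construction: project bond vectors onto the plane normal to
    the central bond and take atan2 of the signed components.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang


def standard_feature_defs(rmap: ResidueMap) -> dict:
    """Build the standard feature definitions from a residue map.

    Each definition is ("distance", a1, a2) or ("dihedral", a1..a4) with atom
    labels "<residue>:<atom>". Only features whose residues are mapped are
    included.
    """
    defs = {}

    def ca(bw):
        return f"{rmap.resolve(bw)}:CA"

    def have(*bws):
        return all(bw in rmap.mapping for bw in bws)

    if have("5.43", "6.56"):
        defs["d_tm5_tm6"] = ("distance", ca("5.43"), ca("6.56"))
    if have("4.57", "6.55"):
        defs["d_tm4_tm6"] = ("distance", ca("4.57"), ca("6.55"))
    if have("3.46", "6.37"):
        defs["d_tm3_tm6_ic"] = ("distance", ca("3.46"), ca("6.37"))
    if "6.52" in rmap.mapping:
        r = rmap.resolve("6.52")
        defs["chi1_n652"] = ("dihedral", f"{r}:N", f"{r}:CA", f"{r}:CB", f"{r}:CG")
    if rmap.ligand_tail_atom is not None and rmap.ecl2_residue is not None:
        defs["d_tail_ecl2"] = ("distance", rmap.ligand_tail_atom, f"{rmap.ecl2_residue}:CA")
    return defs


FEATURE_DEF_BUILDERS = {"standard": standard_feature_defs}


def compute_features(
    frames: pd.DataFrame,
    feature_defs: Mapping[str, tuple],
    simulation_id: str = "sim",
    dt_ns: float | None = None,
) -> FeatureSeries:
    """Compute named geometric features from a multi-frame coordinate table.

    ``frames`` columns: frame, atom, x, y, z (angstroms); ``atom`` labels are
    matched exactly against the feature definitions. ``time_ns`` is taken
    from a time_ns column if present, else ``frame * dt_ns``.
    """
    required = {"frame", "atom", "x", "y", "z"}
    missing_cols = required - set(frames.columns)
    if missing_cols:
        raise DataError(f"coordinate table missing columns: {sorted(missing_cols)}")

    frame_ids = np.sort(frames["frame"].unique())
    coords: dict[tuple, np.ndarray] = {}
    for (fid, atom), grp in frames.groupby(["frame", "atom"]):
        coords[(fid, atom)] = grp[["x", "y", "z"]].to_numpy(float)[0]

    def get(fid, atom):
        try:
            return coords[(fid, atom)]
        except KeyError:
            raise DataError(f"frame {fid}: missing atom {atom!r}") from None

    cols: dict[str, list] = {name: [] for name in feature_defs}
    for fid in frame_ids:
        for name, defn in feature_defs.items():
            kind, *atoms = defn
            pts = [get(fid, a) for a in atoms]
            if kind == "distance":
                cols[name].append(float(distance(pts[0], pts[1])))
            elif kind == "dihedral":
                cols[name].append(float(dihedral(*pts)))
            else:
                raise ValidationError(f"unknown feature kind {kind!r}")

    if "time_ns" in frames.columns:
        time = (
            frames.drop_duplicates("frame").sort_values("frame")["time_ns"].to_numpy(float)
        )
    else:
        if dt_ns is None:
            raise ValidationError("dt_ns required when the coordinate table has no time_ns column")
        time = np.asarray(frame_ids, dtype=float) * dt_ns
    data = pd.DataFrame({"time_ns": time, **cols})
    return FeatureSeries(simulation_id=simulation_id, data=data)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def _exclusion_mask(time: np.ndarray, exclude_ns: float) -> np.ndarray:
    return time >= exclude_ns


def _classify(fs: FeatureSeries, feature: str, label_fn, state: str, exclude_ns: float) -> StateSeries:
    vals = fs.feature(feature)
    return StateSeries(
        simulation_id=fs.simulation_id,
        state=state,
        time=fs.time,
        values=label_fn(vals),
        mask=_exclusion_mask(fs.time, exclude_ns),
    )


def classify_channel_open(fs: FeatureSeries, exclude_ns: float = DEFAULT_EXCLUDE_NS) -> StateSeries:
    """TM5/TM6 channel open: chi1 of N6.52 strictly inside (-50, 100) degrees."""
    lo, hi = CHANNEL_OPEN_CHI1_RANGE
    return _classify(fs, "chi1_n652", lambda v: (v > lo) & (v < hi), "channel_open", exclude_ns)


def classify_active(fs: FeatureSeries, exclude_ns: float = DEFAULT_EXCLUDE_NS) -> StateSeries:
    """Receptor active: intracellular TM3-TM6 Ca distance strictly > 10 A."""
    return _classify(
        fs, "d_tm3_tm6_ic", lambda v: v > ACTIVE_TM3_TM6_MIN_A, "active", exclude_ns
    )


def classify_tm6_outward(fs: FeatureSeries, exclude_ns: float = DEFAULT_EXCLUDE_NS) -> StateSeries:
    """TM6 outward: TM4-TM6 Ca distance strictly > 20.7 A."""
    return _classify(
        fs, "d_tm4_tm6", lambda v: v > TM6_OUTWARD_MIN_A, "tm6_outward", exclude_ns
    )


def classify_tail_vertical(fs: FeatureSeries, exclude_ns: float = TAIL_EXCLUDE_NS) -> StateSeries:
    """Ligand tail vertical: mid-tail to ECL2 Ca distance strictly < 8.9 A.

    Uses the longer 100-ns equilibration window by default.
    """
    return _classify(
        fs, "d_tail_ecl2", lambda v: v < TAIL_VERTICAL_MAX_A, "tail_vertical", exclude_ns
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def state_frequency(
    states: Sequence[StateSeries],
    condition: Sequence[StateSeries] | None = None,
    group: str | None = None,
) -> list:
    """Per-simulation fraction of eligible frames in the target state.

    ``condition`` (e.g. the active-state labels, for "active-only" analyses)
    restricts the denominator to frames where it is True; it must align
    frame-for-frame with ``states``. A simulation with zero eligible frames
    yields fraction None (missing), never zero.
    """
    if not states:
        raise ValidationError("state_frequency needs >= 1 simulation")
    if condition is not None and len(condition) != len(states):
        raise ValidationError("condition list must align with states list")
    out = []
    for i, ss in enumerate(states):
        elig = ss.mask.copy()
        if condition is not None:
            cond = condition[i]
            if len(cond.values) != len(ss.values):
                raise ValidationError(
                    f"condition series length mismatch for simulation {ss.simulation_id!r}"
                )
            elig &= cond.values & cond.mask
        n = int(elig.sum())
        frac = float(ss.values[elig].mean()) if n else None
        out.append(
            FrequencyEstimate(
                simulation_id=ss.simulation_id,
                state=ss.state,
                fraction=frac,
                n_frames_used=n,
                group=group,
            )
        )
    return out


def moving_average(fs: FeatureSeries, window_ns: float = 30.0) -> FeatureSeries:
    """Centered moving mean over a time window, shrinking at the edges.

    Returns a new series; the input (raw) series is untouched.
    """
    t = fs.time
    if t.size >= 2:
        dt = float(np.min(np.diff(t)))
        if window_ns < dt:
            raise ValidationError("moving-average window is smaller than the frame spacing")
    half = window_ns / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    data = {"time_ns": t}
    for name in fs.feature_names:
        v = fs.feature(name)
        csum = np.concatenate([[0.0], np.cumsum(v)])
        data[name] = (csum[hi] - csum[lo]) / (hi - lo)
    return FeatureSeries(
        simulation_id=fs.simulation_id,
        data=pd.DataFrame(data),
        meta={**fs.meta, "smoothed_window_ns": window_ns},
    )


def grouped_fraction(
    states_target: Sequence[StateSeries],
    condition_on: Sequence[StateSeries],
    level: float = 0.68,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict:
    """Target-state fraction conditioned on another state being true/false.

    Frames from all simulations are split by the conditioning label, pooled
    within each split, and the target fraction is computed per split with a
    percentile bootstrap CI over frames. An empty split yields None.
    """
    from .stats import bootstrap_ci

    if len(states_target) != len(condition_on):
        raise ValidationError("states_target and condition_on must align")
    tgt_true, tgt_false = [], []
    for ss, cc in zip(states_target, condition_on):
        if len(ss.values) != len(cc.values):
            raise ValidationError("aligned series required")
        elig = ss.mask & cc.mask
        tgt_true.append(ss.values[elig & cc.values])
        tgt_false.append(ss.values[elig & ~cc.values])
    out = {}
    for label, chunks in (("condition_true", tgt_true), ("condition_false", tgt_false)):
        pooled = np.concatenate(chunks) if chunks else np.empty(0, dtype=bool)
        if pooled.size == 0:
            out[label] = None
            continue
        ci = bootstrap_ci(pooled.astype(float), level=level, n_boot=n_boot, seed=seed)
        out[label] = {
            "fraction": ci.mean,
            "ci_low": ci.ci_low,
            "ci_high": ci.ci_high,
            "n_frames": int(pooled.size),
        }
    return out
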
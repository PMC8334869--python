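"""Gait signal processing: filtering, events, angles, 101-point fields.

Kinematics are low-pass filtered at 10 Hz and ground reaction forces at
20 Hz (fourth-order Butterworth, applied forward-backward so the filters
are zero-phase; the effective order therefore doubles). Heel strike and
toe-off come from 20 N thresholds on the vertical force. All cycle
quantities are time-normalized from heel strike (0%) to the next
ipsilateral heel strike (100%) and interpolated to 1% steps (101
points).

The foot progression angle is the signed transverse-plane angle between
the heel-to-second-metatarsal axis and the gait direction (the line
between the heel-marker positions at two consecutive ipsilateral heel
strikes); in-toeing (internal rotation) is positive on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import least_squares

from .exceptions import EventError, GeometryError, SignalError
from .msk import Model, Posture, LEG_DOFS

__all__ = [
    "GaitCycleField",
    "filter_kinematics",
    "filter_grf",
    "detect_events",
    "foot_progression_angle",
    "time_normalize",
    "average_fields",
    "synthesize_markers",
    "inverse_kinematics",
    "GC_NODES",
]

GC_NODES = np.arange(101.0)  # % gait cycle


@dataclass
class GaitCycleField:
    """A k-component quantity on the 101-node gait-cycle grid."""

    components: list  # k channel names
    values: np.ndarray  # (101, k)
    subject_id: str = ""
    normalization: str = "none"  # none | per-body-mass | per-body-weight
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != 101:
            raise ValueError(
                f"gait-cycle field must have exactly 101 nodes, got "
                f"{self.values.shape[0]}"
            )
        if self.values.shape[1] != len(self.components):
            raise ValueError("component names do not match value columns")

    def __getitem__(self, component: str) -> np.ndarray:
        return self.values[:, self.components.index(component)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.components)
        df.insert(0, "node", GC_NODES.astype(int))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "GaitCycleField":
        cols = [c for c in df.columns if c != "node"]
        return cls(components=cols, values=df[cols].to_numpy(), **kw)

    def scaled(self, factor: float, normalization: str) -> "GaitCycleField":
        return GaitCycleField(
            components=list(self.components),
            values=self.values * factor,
            subject_id=self.subject_id,
            normalization=normalization,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _butter_filtfilt(series, rate: float, cutoff: float):
    if rate <= 2 * cutoff:
        raise ValueError(f"sampling rate {rate} Hz too low for {cutoff} Hz cutoff")
    x = np.asarray(series, dtype=float)
    was_1d = x.ndim == 1
    x = np.atleast_2d(x.T).T  # (T, k)
    b, a = sps.butter(4, cutoff / (rate / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[0] <= padlen:
        raise SignalError(
            f"series of length {x.shape[0]} shorter than filter warm-up ({padlen + 1})"
        )
    y = sps.filtfilt(b, a, x, axis=0)
    return y[:, 0] if was_1d else y


def filter_kinematics(series, rate: float):
    """Zero-phase fourth-order 10 Hz Butterworth low-pass."""
    return _butter_filtfilt(series, rate, 10.0)


def filter_grf(series, rate: float):
    """Zero-phase fourth-order 20 Hz Butterworth low-pass."""
    return _butter_filtfilt(series, rate, 20.0)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def detect_events(grf_vertical, rate: float, threshold: float = 20.0,
                  debounce: float = 0.05) -> dict:
    """Heel strikes and toe-offs from force thresholds.

    Heel strike = first sample of each suprathreshold (> threshold N)
    run; toe-off = first sample below threshold after a stance run.
    Runs (and the gaps between them) shorter than ``debounce`` seconds
    are ignored.

    Returns ``{"heel_strikes": [...], "toe_offs": [...]}`` as integer
    sample indices (0-based).
    """
    f = np.asarray(grf_vertical, dtype=float)
    above = f > threshold
    if not above.any():
        raise EventError("vertical GRF never exceeds the event threshold")
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [int(i) + 1 for i in edges if above[i + 1]]
    stops = [int(i) + 1 for i in edges if not above[i + 1]]
    if above[0]:
        starts = [0] + starts
    min_run = max(1, int(round(debounce * rate)))

    heel_strikes, toe_offs = [], []
    for s in starts:
        nxt = min((t for t in stops if t > s), default=len(f))
        if nxt - s >= min_run:
            heel_strikes.append(s)
            if nxt < len(f):
                following = min((s2 for s2 in starts if s2 > nxt), default=len(f))
                if following - nxt >= min_run:
                    toe_offs.append(nxt)
    if not heel_strikes:
        raise EventError("no stance phase longer than the debounce window")
    return {"heel_strikes": heel_strikes, "toe_offs": toe_offs}


# ---------------------------------------------------------------------------
# foot progression angle
# ---------------------------------------------------------------------------

def foot_progression_angle(heel, mt2, heel_strikes, side: str = "R") -> np.ndarray:
    """Signed transverse-plane foot progression angle (deg), in-toeing +.

    ``heel`` and ``mt2`` are (T, 3) world marker trajectories (Y up);
    ``heel_strikes`` are sample indices of consecutive ipsilateral heel
    strikes defining each cycle's gait direction.
    """
    heel = np.asarray(heel, dtype=float)
    mt2 = np.asarray(mt2, dtype=float)
    if len(heel_strikes) < 2:
        raise ValueError("two heel strikes required")
    out = np.full(heel.shape[0], np.nan)
    s = 1.0 if side == "R" else -1.0
    for h0, h1 in zip(heel_strikes[:-1], heel_strikes[1:]):
        gait = heel[h1] - heel[h0]
        w_d = gait[0] + 1j * gait[2]  # transverse plane x + i z
        if abs(w_d) < 1e-9:
            raise GeometryError("coincident heel-strike positions: gait direction undefined")
        seg = slice(h0, h1 + 1)
        f = mt2[seg] - heel[seg]
        w_f = f[:, 0] + 1j * f[:, 2]
        if np.any(np.abs(w_f) < 1e-9):
            raise GeometryError("degenerate foot axis (heel and MT2 coincide)")
        # internal rotation = clockwise from above on the right: w -> e^{-i a} w
        out[seg] = s * np.degrees(np.angle(w_d / w_f))
    return out


# ---------------------------------------------------------------------------
# time normalization
# ---------------------------------------------------------------------------

def time_normalize(series, events, components=None, **field_kw) -> GaitCycleField:
    """Linear interpolation of one cycle onto the 101-node grid.

    ``events`` is ``(start, end)`` in samples of the series' own rate
    (both inclusive, successive ipsilateral heel strikes).
    """
    if isinstance(series, pd.DataFrame):
        components = components or list(series.columns)
        x = series.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(series, dtype=float).T).T
        components = components or [f"c{i}" for i in range(x.shape[1])]
    start, end = int(events[0]), int(events[1])
    if end - start < 1 or end >= x.shape[0] + 1 or start < 0 or end >= x.shape[0]:
        raise SignalError("cycle must contain at least 2 samples inside the series")
    t = np.arange(start, end + 1, dtype=float)
    nodes = start + (end - start) * GC_NODES / 100.0
    vals = np.stack([np.interp(nodes, t, x[start : end + 1, j])
                     for j in range(x.shape[1])], axis=1)
    return GaitCycleField(components=components, values=vals, **field_kw)


def average_fields(fields) -> GaitCycleField:
    """Node-wise mean of same-shaped fields (per-subject trial average)."""
    fields = list(fields)
    if not fields:
        raise ValueError("no fields to average")
    comp = fields[0].components
    for f in fields:
        if f.components != comp:
            raise ValueError("fields have mismatching components")
    return GaitCycleField(
        components=list(comp),
        values=np.mean([f.values for f in fields], axis=0),
        subject_id=fields[0].subject_id,
        normalization=fields[0].normalization,
    )


# ---------------------------------------------------------------------------
# markers and inverse kinematics (optional round-trip path)
# ---------------------------------------------------------------------------

def _posture_from_frame(joint_angles: pd.DataFrame, i: int | slice) -> Posture:
    row = joint_angles.iloc[i]
    if isinstance(row, pd.DataFrame):
        return Posture(**{c: row[c].to_numpy() for c in joint_angles.columns})
    return Posture(**{c: float(row[c]) for c in joint_angles.columns})


def synthesize_markers(model: Model, joint_angles: pd.DataFrame) -> dict:
    """Forward-kinematic marker trajectories: name -> (T, 3) world (m)."""
    posture = _posture_from_frame(joint_angles, slice(None))
    fk = model.forward_kinematics(posture)
    return {
        name: model.point_world(seg, pt, fk, posture)
        for name, (seg, pt) in model.markers.items()
    }


def _check_marker_geometry(model: Model):
    by_seg = {}
    for name, (seg, pt) in model.markers.items():
        by_seg.setdefault(seg, []).append(pt)
    for seg, pts in by_seg.items():
        if len(pts) < 3:
            continue
        p = np.stack(pts) - np.mean(pts, axis=0)
        if np.linalg.matrix_rank(p, tol=1e-9) < 2:
            raise GeometryError(f"collinear marker cluster on segment {seg}")


def inverse_kinematics(
    model: Model,
    marker_trajectories: dict,
    weights: dict | None = None,
    x0: Posture | None = None,
) -> pd.DataFrame:
    """Per-frame weighted least-squares fit of model coordinates to markers.

    Returns a DataFrame of the 12 generalized coordinates. Marker
    trajectories are (T, 3) world positions; ``weights`` maps marker
    names to scalar weights (default 1).
    """
    _check_marker_geometry(model)
    names = [n for n in model.markers if n in marker_trajectories]
    if len(names) < 3:
        raise GeometryError("need at least 3 tracked markers")
    obs = np.stack([np.asarray(marker_trajectories[n], dtype=float) for n in names],
                   axis=1)  # (T, M, 3)
    wts = np.array([1.0 if weights is None else weights.get(n, 1.0) for n in names])
    coords = ["pelvis_tx", "pelvis_ty", "pelvis_tz", "pelvis_tilt", "pelvis_list",
              "pelvis_rotation"] + list(LEG_DOFS)
    scale = np.array([1.0, 1.0, 1.0] + [50.0] * 9)  # deg coords step bigger

    def resid(q, target):
        posture = Posture(**dict(zip(coords, q * scale)))
        fk = model.forward_kinematics(posture)
        mdl_pts = np.stack(
            [model.point_world(model.markers[n][0], model.markers[n][1], fk, posture)
             for n in names]
        )
        return ((mdl_pts - target) * wts[:, None]).ravel()

    T = obs.shape[0]
    out = np.empty((T, len(coords)))
    q = np.array(
        [getattr(x0 or Posture(pelvis_ty=float(np.nanmean(obs[0, :, 1]))), c)
         for c in coords]
    ) / scale
    for i in range(T):
        sol = least_squares(resid, q, args=(obs[i],), method="lm", xtol=1e-12,
                            ftol=1e-12)
        q = sol.x
        out[i] = q * scale
    return pd.DataFrame(out, columns=coords)
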
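"""Frame-wise RULA scoring of joint-angle streams.

The Rapid Upper Limb Assessment combines posture-band scores for the upper
arm, lower arm and wrist (Table A), and for the neck, trunk and legs
(Table B), adds muscle-use and force/load points, and maps the two composite
scores through Table C onto a grand score of 1-7 (7: investigate and
implement change immediately).

Conventions fixed here (and documented because the original worksheet leaves
them open for automated use):

* band boundaries are closed on the lower-risk side — a flexion of exactly
  20 deg scores the milder band;
* the reported wrist outcome is the *combined* wrist score,
  ``wrist_posture + wrist_twist`` (maximum 6); Table A keeps the two as
  separate indices as in the printed worksheet;
* twist/side-bend adjustments for neck and trunk use symmetric
  ``|angle| > 10 deg`` thresholds by default;
* the force/load score defaults to 0 (hand-held dental instruments are
  light and used intermittently);
* legs default to "supported" (seated work).

All thresholds live in :class:`RulaThresholds` and the muscle-use automation
knobs in :class:`StaticWindowConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .motion_io import MotionRecording, TIME_COLUMN

__all__ = [
    "TABLE_A",
    "TABLE_B",
    "TABLE_C",
    "RulaThresholds",
    "StaticWindowConfig",
    "RulaFrameScore",
    "RulaInputError",
    "score_upper_arm",
    "score_lower_arm",
    "score_wrist",
    "score_neck",
    "score_trunk",
    "score_legs",
    "table_a",
    "table_b",
    "table_c",
    "muscle_use_score",
    "derive_flags",
    "score_frame",
    "score_channel_arrays",
    "score_recording",
    "SCORE_COLUMNS",
]


class RulaInputError(ValueError):
    """Invalid posture input (non-finite angle, out-of-range index)."""


# Table A: upper arm (1-6) x lower arm (1-3) x wrist posture (1-4) x wrist
# twist (1-2) -> 1-9.  Transcribed from the published RULA worksheet.
TABLE_A = np.array(
    [
        [  # upper arm 1
            [[1, 2], [2, 2], [2, 3], [3, 3]],
            [[2, 2], [2, 2], [3, 3], [3, 3]],
            [[2, 3], [3, 3], [3, 3], [4, 4]],
        ],
        [  # upper arm 2
            [[2, 3], [3, 3], [3, 4], [4, 4]],
            [[3, 3], [3, 3], [3, 4], [4, 4]],
            [[3, 4], [4, 4], [4, 4], [5, 5]],
        ],
        [  # upper arm 3
            [[3, 3], [4, 4], [4, 4], [5, 5]],
            [[3, 4], [4, 4], [4, 4], [5, 5]],
            [[4, 4], [4, 4], [4, 5], [5, 5]],
        ],
        [  # upper arm 4
            [[4, 4], [4, 4], [4, 5], [5, 5]],
            [[4, 4], [4, 4], [4, 5], [5, 5]],
            [[4, 4], [4, 5], [5, 5], [6, 6]],
        ],
        [  # upper arm 5
            [[5, 5], [5, 5], [5, 6], [6, 7]],
            [[5, 6], [6, 6], [6, 7], [7, 7]],
            [[6, 6], [6, 7], [7, 7], [7, 8]],
        ],
        [  # upper arm 6
            [[7, 7], [7, 7], [7, 8], [8, 9]],
            [[8, 8], [8, 8], [8, 9], [9, 9]],
            [[9, 9], [9, 9], [9, 9], [9, 9]],
        ],
    ],
    dtype=np.int64,
)

# Table B: neck (1-6) x trunk (1-6) x legs (1-2) -> 1-9.
TABLE_B = np.array(
    [
        [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]],
        [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]],
        [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]],
        [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]],
        [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]],
        [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]],
    ],
    dtype=np.int64,
)

# Table C: score C (rows 1..8+, saturated) x score D (cols 1..7+) -> 1-7.
TABLE_C = np.array(
    [
        [1, 2, 3, 3, 4, 5, 5],
        [2, 2, 3, 4, 4, 5, 5],
        [3, 3, 3, 4, 4, 5, 6],
        [3, 3, 3, 4, 5, 6, 6],
        [4, 4, 4, 5, 6, 7, 7],
        [4, 4, 5, 6, 6, 7, 7],
        [5, 5, 6, 6, 7, 7, 7],
        [5, 5, 6, 7, 7, 7, 7],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class RulaThresholds:
    """Angle thresholds for the worksheet's categorical adjustments."""

    abduction_deg: float = 45.0  # upper arm counted as abducted beyond this
    wrist_neutral_deg: float = 1.0  # |flexion| band counted as neutral wrist
    wrist_deviation_deg: float = 10.0
    neck_twist_deg: float = 10.0
    neck_side_bend_deg: float = 10.0
    trunk_neutral_deg: float = 5.0  # "sitting well supported" neutral band
    trunk_twist_deg: float = 10.0
    trunk_side_bend_deg: float = 10.0


@dataclass(frozen=True)
class StaticWindowConfig:
    """Automation of the worksheet's muscle-use rule.

    A frame earns the +1 muscle-use point when the driving posture was held
    statically for ``window_s`` (every driving angle stayed within
    ``hold_tolerance_deg`` over the full trailing window) or when the step
    score crossed bands at least ``repetition_threshold_per_min`` times per
    minute within the trailing window (evaluated on the available prefix
    when the recording is younger than the window).
    """

    window_s: float = 60.0
    hold_tolerance_deg: float = 5.0
    repetition_threshold_per_min: float = 4.0

    def __post_init__(self):
        if not (
            self.window_s > 0
            and self.hold_tolerance_deg > 0
            and self.repetition_threshold_per_min > 0
        ):
            raise RulaInputError("StaticWindowConfig values must be strictly positive")


@dataclass(frozen=True)
class RulaFrameScore:
    """All step scores and the final grand score for one frame, one side."""

    side: str
    upper_arm: int
    lower_arm: int
    wrist_posture: int
    wrist_twist: int
    wrist_combined: int
    table_a: int
    muscle_a: int
    force_a: int
    score_c: int
    neck: int
    trunk: int
    legs: int
    table_b: int
    muscle_b: int
    force_b: int
    score_d: int
    final: int


def _check_finite(*angles: float) -> None:
    for a in angles:
        if not np.isfinite(a):
            raise RulaInputError(f"non-finite angle: {a!r}")


# ---------------------------------------------------------------------------
# vectorised band scoring (scalar wrappers below)

def _upper_arm_vec(flexion, abducted, shoulder_raised, supported):
    f = np.asarray(flexion, dtype=float)
    base = np.where(
        np.abs(f) <= 20.0,
        1,
        np.where(f <= 45.0, 2, np.where(f <= 90.0, 3, 4)),
    )
    base = np.where(f < -20.0, 2, base)
    score = (
        base
        + np.asarray(shoulder_raised, dtype=np.int64)
        + np.asarray(abducted, dtype=np.int64)
        - np.asarray(supported, dtype=np.int64)
    )
    return np.clip(score, 1, 6)


def _lower_arm_vec(flexion, across_midline):
    f = np.asarray(flexion, dtype=float)
    base = np.where((f >= 60.0) & (f <= 100.0), 1, 2)
    return np.clip(base + np.asarray(across_midline, dtype=np.int64), 1, 3)


def _wrist_vec(flexion, deviation, twist_endrange, thr: RulaThresholds):
    f = np.asarray(flexion, dtype=float)
    dev = np.asarray(deviation, dtype=float)
    base = np.where(
        np.abs(f) <= thr.wrist_neutral_deg, 1, np.where(np.abs(f) <= 15.0, 2, 3)
    )
    posture = np.clip(base + (dev > thr.wrist_deviation_deg).astype(np.int64), 1, 4)
    twist = np.where(np.asarray(twist_endrange, dtype=bool), 2, 1)
    return posture, twist, posture + twist


def _neck_vec(flexion, rotation, side_bend, thr: RulaThresholds):
    f = np.asarray(flexion, dtype=float)
    base = np.where(f < 0.0, 4, np.where(f <= 10.0, 1, np.where(f <= 20.0, 2, 3)))
    score = (
        base
        + (np.abs(np.asarray(rotation, float)) > thr.neck_twist_deg).astype(np.int64)
        + (np.abs(np.asarray(side_bend, float)) > thr.neck_side_bend_deg).astype(np.int64)
    )
    return np.clip(score, 1, 6)


def _trunk_vec(flexion, rotation, side_bend, supported, thr: RulaThresholds):
    f = np.asarray(flexion, dtype=float)
    sup = np.asarray(supported, dtype=bool)
    base = np.where(
        (np.abs(f) <= thr.trunk_neutral_deg) & sup,
        1,
        np.where(f <= 20.0, 2, np.where(f <= 60.0, 3, 4)),
    )
    score = (
        base
        + (np.abs(np.asarray(rotation, float)) > thr.trunk_twist_deg).astype(np.int64)
        + (np.abs(np.asarray(side_bend, float)) > thr.trunk_side_bend_deg).astype(np.int64)
    )
    return np.clip(score, 1, 6)


# ---------------------------------------------------------------------------
# public scalar step operations

def score_upper_arm(
    flexion: float,
    abducted: bool = False,
    shoulder_raised: bool = False,
    supported: bool = False,
) -> int:
    """Worksheet step 1 (range 1-6)."""
    _check_finite(flexion)
    return int(_upper_arm_vec(flexion, abducted, shoulder_raised, supported))


def score_lower_arm(flexion: float, across_midline: bool = False) -> int:
    """Worksheet step 2 (range 1-3)."""
    _check_finite(flexion)
    return int(_lower_arm_vec(flexion, across_midline))


def score_wrist(
    flexion: float,
    deviation: float,
    twist_endrange: bool = False,
    thresholds: RulaThresholds = RulaThresholds(),
) -> tuple[int, int, int]:
    """Worksheet steps 3 and 4, plus their combined reporting score.

    Returns ``(wrist_posture 1-4, wrist_twist 1-2, combined 2-6)``.
    """
    _check_finite(flexion, deviation)
    if deviation < 0:
        raise RulaInputError("wrist deviation must be non-negative")
    p, t, c = _wrist_vec(flexion, deviation, twist_endrange, thresholds)
    return int(p), int(t), int(c)


def score_neck(
    flexion: float,
    rotation: float = 0.0,
    side_bend: float = 0.0,
    thresholds: RulaThresholds = RulaThresholds(),
) -> int:
    """Worksheet step 9 (range 1-6); extension scores the 4 band."""
    _check_finite(flexion, rotation, side_bend)
    return int(_neck_vec(flexion, rotation, side_bend, thresholds))


def score_trunk(
    flexion: float,
    rotation: float = 0.0,
    side_bend: float = 0.0,
    supported: bool = False,
    thresholds: RulaThresholds = RulaThresholds(),
) -> int:
    """Worksheet step 10 (range 1-6); 1 only when seated, well supported."""
    _check_finite(flexion, rotation, side_bend)
    return int(_trunk_vec(flexion, rotation, side_bend, supported, thresholds))


def score_legs(supported: bool = True) -> int:
    """Worksheet step 11: 1 if legs/feet supported and balanced, else 2."""
    return 1 if supported else 2


def _check_range(name: str, value, lo: int, hi: int) -> np.ndarray:
    arr = np.asarray(value, dtype=np.int64)
    if np.any(arr < lo) or np.any(arr > hi):
        raise RulaInputError(f"{name} must be in {lo}..{hi}")
    return arr


def table_a(upper_arm, lower_arm, wrist_posture, wrist_twist):
    """Exact lookup of the posture score A (1-9)."""
    ua = _check_range("upper_arm", upper_arm, 1, 6)
    la = _check_range("lower_arm", lower_arm, 1, 3)
    wp = _check_range("wrist_posture", wrist_posture, 1, 4)
    wt = _check_range("wrist_twist", wrist_twist, 1, 2)
    out = TABLE_A[ua - 1, la - 1, wp - 1, wt - 1]
    return int(out) if np.isscalar(upper_arm) else out


def table_b(neck, trunk, legs):
    """Exact lookup of the posture score B (1-9)."""
    n = _check_range("neck", neck, 1, 6)
    t = _check_range("trunk", trunk, 1, 6)
    lg = _check_range("legs", legs, 1, 2)
    out = TABLE_B[n - 1, t - 1, lg - 1]
    return int(out) if np.isscalar(neck) else out


def table_c(score_c, score_d):
    """Grand-score lookup with saturation (rows 8+, columns 7+) -> 1-7."""
    sc = _check_range("score_c", score_c, 1, 10**9)
    sd = _check_range("score_d", score_d, 1, 10**9)
    out = TABLE_C[np.minimum(sc, 8) - 1, np.minimum(sd, 7) - 1]
    return int(out) if np.isscalar(score_c) else out


# ---------------------------------------------------------------------------
# muscle use

def muscle_use_score(
    angles: np.ndarray,
    scores: np.ndarray,
    rate: float,
    cfg: StaticWindowConfig = StaticWindowConfig(),
) -> np.ndarray:
    """Per-frame 0/1 muscle-use points for one worksheet arm (A or B).

    ``angles``: (n_frames, n_channels) driving posture angles in degrees;
    ``scores``: the driving step-score series used for repetition counting.

    Static rule: 1 once every driving angle stayed within
    ``hold_tolerance_deg`` (max - min) over a full trailing window — a
    posture cannot count as held-for-a-minute before a minute has passed.
    Repetition rule: 1 when band crossings in the trailing window (prefix
    allowed) reach ``repetition_threshold_per_min`` scaled to the window
    length actually available.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim == 1:
        angles = angles[:, None]
    scores = np.asarray(scores, dtype=np.int64)
    n = angles.shape[0]
    if n < 1 or scores.shape[0] != n:
        raise RulaInputError("angle and score series must be non-empty, same length")

    win = max(int(round(cfg.window_s * rate)), 1)

    # static: trailing-window range (max - min) per channel, O(n) filters
    if n >= win:
        origin = (win - 1) // 2  # shift centered filter to a trailing window
        mx = ndimage.maximum_filter1d(angles, size=win, axis=0, mode="nearest", origin=origin)
        mn = ndimage.minimum_filter1d(angles, size=win, axis=0, mode="nearest", origin=origin)
        static = np.all(mx - mn <= cfg.hold_tolerance_deg, axis=1)
        static[: win - 1] = False  # needs a full window of history
    else:
        static = np.zeros(n, dtype=bool)

    # repetition: trailing band-crossing count against a prefix-scaled threshold
    changes = np.zeros(n, dtype=np.int64)
    changes[1:] = scores[1:] != scores[:-1]
    csum = np.concatenate([[0], np.cumsum(changes)])
    idx = np.arange(n)
    lo = np.maximum(idx + 1 - win, 0)
    count = csum[idx + 1] - csum[lo]
    avail_s = (idx + 1 - lo) / rate
    threshold = cfg.repetition_threshold_per_min * avail_s / 60.0
    repeated = count >= np.maximum(threshold, 1e-12)

    return (static | repeated).astype(np.int64)


# ---------------------------------------------------------------------------
# flag derivation

def derive_flags(frame: dict | pd.DataFrame, thresholds: RulaThresholds = RulaThresholds()):
    """Fill derivable posture flags, never overwriting supplied ones.

    Adds ``arm_abducted_flag_r/_l`` from the abduction angle (strict
    ``> abduction_deg``).  Twist/side-bend adjustments for neck and trunk
    are handled inside the scoring functions via angle thresholds.
    """
    out = frame.copy()
    for side in ("r", "l"):
        flag = f"arm_abducted_flag_{side}"
        angle = f"upper_arm_abduction_{side}"
        if flag not in out:
            if isinstance(out, pd.DataFrame):
                out[flag] = out[angle].to_numpy(float) > thresholds.abduction_deg
            else:
                out[flag] = out[angle] > thresholds.abduction_deg
    return out


# ---------------------------------------------------------------------------
# whole-frame and whole-recording scoring

def score_frame(
    frame: dict,
    side: str = "r",
    muscle_a: int = 0,
    muscle_b: int = 0,
    force_a: int = 0,
    force_b: int = 0,
    thresholds: RulaThresholds = RulaThresholds(),
) -> RulaFrameScore:
    """Score one frame's posture for one side through the full worksheet."""
    if side not in ("r", "l"):
        raise RulaInputError(f"side must be 'r' or 'l', got {side!r}")
    for name, val, hi in (
        ("muscle_a", muscle_a, 1),
        ("muscle_b", muscle_b, 1),
        ("force_a", force_a, 3),
        ("force_b", force_b, 3),
    ):
        _check_range(name, val, 0, hi)

    f = derive_flags(dict(frame), thresholds)
    s = f"_{side}"
    ua = score_upper_arm(
        f[f"upper_arm_flexion{s}"],
        abducted=bool(f[f"arm_abducted_flag{s}"]),
        shoulder_raised=bool(f[f"shoulder_raise_flag{s}"]),
        supported=bool(f[f"arm_supported_flag{s}"]),
    )
    la = score_lower_arm(f[f"lower_arm_flexion{s}"], bool(f[f"arm_across_midline_flag{s}"]))
    wp, wt, wc = score_wrist(
        f[f"wrist_flexion{s}"],
        f[f"wrist_deviation{s}"],
        bool(f[f"wrist_twist_endrange_flag{s}"]),
        thresholds,
    )
    neck = score_neck(f["neck_flexion"], f["neck_rotation"], f["neck_side_bend"], thresholds)
    trunk = score_trunk(
        f["trunk_flexion"],
        f["trunk_rotation"],
        f["trunk_side_bend"],
        bool(f.get("trunk_supported_flag", False)),
        thresholds,
    )
    legs = score_legs(bool(f.get("legs_supported_flag", True)))

    ta = table_a(ua, la, wp, wt)
    tb = table_b(neck, trunk, legs)
    sc = ta + muscle_a + force_a
    sd = tb + muscle_b + force_b
    final = table_c(sc, sd)
    return RulaFrameScore(
        side=side,
        upper_arm=ua,
        lower_arm=la,
        wrist_posture=wp,
        wrist_twist=wt,
        wrist_combined=wc,
        table_a=ta,
        muscle_a=int(muscle_a),
        force_a=int(force_a),
        score_c=sc,
        neck=neck,
        trunk=trunk,
        legs=legs,
        table_b=tb,
        muscle_b=int(muscle_b),
        force_b=int(force_b),
        score_d=sd,
        final=final,
    )


#: Columns of the per-frame score table emitted by :func:`score_recording`.
SCORE_COLUMNS = (
    TIME_COLUMN,
    "upper_arm_r", "lower_arm_r", "wrist_posture_r", "wrist_twist_r",
    "wrist_combined_r", "table_a_r", "muscle_a_r", "score_c_r", "final_r",
    "upper_arm_l", "lower_arm_l", "wrist_posture_l", "wrist_twist_l",
    "wrist_combined_l", "table_a_l", "muscle_a_l", "score_c_l", "final_l",
    "neck", "trunk", "legs", "table_b", "muscle_b", "score_d", "final",
)


def score_channel_arrays(
    channels: dict[str, np.ndarray],
    rate: float,
    static_cfg: StaticWindowConfig = StaticWindowConfig(),
    thresholds: RulaThresholds = RulaThresholds(),
    force_a: int = 0,
    force_b: int = 0,
) -> dict[str, np.ndarray]:
    """Array-level scoring core: channel arrays in, score arrays out.

    ``channels`` maps channel names (the motion-file dialect) to equal-length
    1-D arrays; a pre-computed ``arm_abducted_flag_r/_l`` is honoured, else
    the flag is derived from the abduction angle.  Returns the arrays behind
    :data:`SCORE_COLUMNS` (without the time column).  This is the engine
    behind :func:`score_recording`; use it directly when recordings are
    already in memory as arrays and the DataFrame wrapper is not needed.
    """
    neck = _neck_vec(
        channels["neck_flexion"], channels["neck_rotation"],
        channels["neck_side_bend"], thresholds,
    )
    trunk = _trunk_vec(
        channels["trunk_flexion"],
        channels["trunk_rotation"],
        channels["trunk_side_bend"],
        np.asarray(channels["trunk_supported_flag"], dtype=bool),
        thresholds,
    )
    legs = np.where(np.asarray(channels["legs_supported_flag"], dtype=bool), 1, 2)
    tb = TABLE_B[neck - 1, trunk - 1, legs - 1]
    axial_angles = np.column_stack(
        [channels[c] for c in ("neck_flexion", "neck_rotation", "neck_side_bend",
                               "trunk_flexion", "trunk_rotation", "trunk_side_bend")]
    )
    muscle_b = muscle_use_score(axial_angles, tb, rate, static_cfg)
    sd = tb + muscle_b + force_b

    out: dict[str, np.ndarray] = {}
    finals = {}
    for side in ("r", "l"):
        s = f"_{side}"
        abducted = channels.get(f"arm_abducted_flag{s}")
        if abducted is None:
            abducted = (
                np.asarray(channels[f"upper_arm_abduction{s}"], float)
                > thresholds.abduction_deg
            )
        ua = _upper_arm_vec(
            channels[f"upper_arm_flexion{s}"],
            np.asarray(abducted, dtype=bool),
            np.asarray(channels[f"shoulder_raise_flag{s}"], dtype=bool),
            np.asarray(channels[f"arm_supported_flag{s}"], dtype=bool),
        )
        la = _lower_arm_vec(
            channels[f"lower_arm_flexion{s}"],
            np.asarray(channels[f"arm_across_midline_flag{s}"], dtype=bool),
        )
        wp, wt, wc = _wrist_vec(
            channels[f"wrist_flexion{s}"],
            channels[f"wrist_deviation{s}"],
            np.asarray(channels[f"wrist_twist_endrange_flag{s}"], dtype=bool),
            thresholds,
        )
        ta = TABLE_A[ua - 1, la - 1, wp - 1, wt - 1]
        arm_angles = np.column_stack(
            [channels[c] for c in (f"upper_arm_flexion{s}", f"upper_arm_abduction{s}",
                                   f"lower_arm_flexion{s}", f"wrist_flexion{s}",
                                   f"wrist_deviation{s}")]
        )
        muscle_a = muscle_use_score(arm_angles, ta, rate, static_cfg)
        sc = ta + muscle_a + force_a
        final_side = TABLE_C[np.minimum(sc, 8) - 1, np.minimum(sd, 7) - 1]
        finals[side] = final_side
        out.update(
            {
                f"upper_arm{s}": ua,
                f"lower_arm{s}": la,
                f"wrist_posture{s}": wp,
                f"wrist_twist{s}": wt,
                f"wrist_combined{s}": wc,
                f"table_a{s}": ta,
                f"muscle_a{s}": muscle_a,
                f"score_c{s}": sc,
                f"final{s}": final_side,
            }
        )

    out.update(
        {
            "neck": neck,
            "trunk": trunk,
            "legs": legs,
            "table_b": tb,
            "muscle_b": muscle_b,
            "score_d": sd,
            "final": np.maximum(finals["r"], finals["l"]),
        }
    )
    return out


def score_recording(
    rec: MotionRecording,
    static_cfg: StaticWindowConfig = StaticWindowConfig(),
    thresholds: RulaThresholds = RulaThresholds(),
    force_a: int = 0,
    force_b: int = 0,
) -> pd.DataFrame:
    """Score every frame of a recording, both sides, fully vectorised.

    Returns one row per frame with the columns in :data:`SCORE_COLUMNS`.
    The per-frame ``final`` is the worse (maximum) of the two sides' grand
    scores; muscle use is detected automatically per worksheet arm (arm and
    wrist channels drive group A per side, neck and trunk channels group B).
    """
    if rec.n_frames < 1:
        raise RulaInputError("empty recording")
    channels = {c: rec.data[c].to_numpy() for c in rec.data.columns}
    arrays = score_channel_arrays(
        channels, rec.sampling_rate, static_cfg, thresholds, force_a, force_b
    )
    out = {TIME_COLUMN: np.asarray(channels[TIME_COLUMN], float), **arrays}
    return pd.DataFrame(out, columns=list(SCORE_COLUMNS))
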
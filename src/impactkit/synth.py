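"""Seeded synthetic cohorts for end-to-end pipeline testing.

The generator emulates the phenomenology of triggered mouthguard data
without external recordings:

* impacts — a 10–65 g half-sine pulse (8–30 ms, right-skewed amplitudes)
  within a 20-degree cone of the planted video sector axis, coherent
  low-band (20–80 Hz) angular velocity, and — on a fraction of draws —
  brief post-pulse high-frequency ringing (jaw/device clack): high
  sub-100 Hz spectral power with realistically contaminated time-domain
  shape;
* nonimpacts — brief 10–104 g high-band (120–350 Hz) spikes over a
  sustained sub-trigger mid-band jostle bout, a few-Hz body sway, and
  quadrature head-shake angular content: the spiky, oscillatory signals
  of dropped, chewed, or jostled devices, with genuine velocity change
  and head displacement;
* off-teeth recordings — nonimpact-like signals whose infrared reading is
  drawn from the low mixture mode.

Peak kinematics, velocity changes, pulse widths and peak wavelet
frequencies deliberately overlap between the classes, while
low-frequency (10–30 Hz) spectral power separates them — the structure
the detection method exists to exploit.

Infrared readings are bimodal with modes separated by six pooled standard
deviations.  Every impact gets a helmet-contact video interval offset by
a clock skew within +/-1 s; nonimpacts sit strictly inside long
no-contact/idle intervals; a few no-view confounder recordings are
planted to exercise the exclusion rules.  All draws derive from a single
seed, so cohorts are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groundtruth import DIRECTION_AXES
from .io import DT_S, N_SAMPLES, PRETRIGGER_SAMPLES, Recording, SensorCalibration, VideoLabel
from .neck import NeckModelParams

DIRECTIONS = tuple(DIRECTION_AXES)   # frontal, rear, left, right, top


@dataclass
class SynthConfig:
    n_impacts: int = 60
    n_nonimpacts: int = 60
    n_offteeth: int = 100
    n_noview: int = 3
    impact_amp_g: tuple[float, float] = (10.0, 65.0)
    nonimpact_amp_g: tuple[float, float] = (10.0, 104.0)
    #: exponential-tail scale above the 10 g trigger floor; reproduces the
    #: right-skewed peak-amplitude distributions (impacts mean ~22 g,
    #: median ~19 g; nonimpacts mean ~18.5 g, median ~16 g)
    impact_amp_scale_g: float = 12.0
    nonimpact_amp_scale_g: float = 8.5
    impact_band_hz: tuple[float, float] = (20.0, 80.0)
    nonimpact_band_hz: tuple[float, float] = (120.0, 350.0)
    #: nonimpact mid-band jostle bout: sustained sub-trigger oscillation
    #: whose rectified envelope keeps time-domain pulse widths and peak
    #: wavelet frequencies overlapping between the classes while staying
    #: below the 10 g trigger floor at low frequencies
    nonimpact_midband_hz: tuple[float, float] = (40.0, 90.0)
    nonimpact_mid_amp_g: tuple[float, float] = (1.5, 5.0)
    nonimpact_mid_sigma_ms: tuple[float, float] = (10.0, 25.0)
    #: slow whole-body sway present during noncontact activity
    body_motion_g: tuple[float, float] = (0.5, 3.0)
    body_motion_hz: tuple[float, float] = (3.0, 6.0)
    #: oblique-blow spread: impact pulse direction drawn uniformly within a
    #: cone of this half-angle about the video sector axis (kept well
    #: inside the 45-degree direction-consistency cone)
    impact_cone_deg: float = 20.0
    #: body sway retained during impacts: capped so the velocity-change
    #: vector of even the weakest pulse stays inside the direction cone
    impact_body_motion_g: tuple[float, float] = (0.05, 0.15)
    #: post-pulse high-frequency ringing (jaw/device clack) riding on a
    #: fraction of impacts; crest relative to the pulse peak
    impact_ringing_prob: float = 0.4
    impact_ringing_ratio: tuple[float, float] = (0.8, 1.35)
    impact_ringing_sigma_ms: tuple[float, float] = (0.8, 1.6)
    #: nonimpact angular jostle (head shake) in quadrature
    nonimpact_ang_jostle_rps: tuple[float, float] = (0.3, 3.0)
    impact_duration_ms: tuple[float, float] = (8.0, 30.0)
    nonimpact_spike_sigma_ms: tuple[float, float] = (0.3, 1.2)
    impact_ang_vel_rps: tuple[float, float] = (0.8, 12.3)
    impact_ang_vel_scale_rps: float = 4.5
    nonimpact_ang_vel_rps: tuple[float, float] = (0.05, 27.0)
    nonimpact_ang_vel_scale_rps: float = 2.6
    ir_mu_low: float = 100.0
    ir_mu_high: float = 220.0
    ir_sd_low: float = 20.0
    ir_sd_high: float = 20.0
    clock_skew_s: float = 1.0
    acc_noise_g: float = 0.5
    gyro_noise_rps: float = 0.2
    lever_arm_m: tuple[float, float, float] = (0.02, 0.0, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.impact_amp_g, self.nonimpact_amp_g,
                       self.impact_band_hz, self.nonimpact_band_hz,
                       self.impact_duration_ms):
            if not 0 < lo <= hi:
                raise ValueError("config ranges must be ordered and positive")
        if not (0 < self.impact_band_hz[1] < 500
                and 0 < self.nonimpact_band_hz[1] < 500):
            raise ValueError("frequency bands must lie within (0, 500) Hz")
        if min(self.n_impacts, self.n_nonimpacts, self.n_offteeth,
               self.n_noview) < 0:
            raise ValueError("counts must be nonnegative")


def synth_calibration(cfg: SynthConfig | None = None) -> SensorCalibration:
    """Identity device-to-anatomical calibration with the planted lever arm."""
    cfg = cfg or SynthConfig()
    return SensorCalibration(cog_lever_arm=np.asarray(cfg.lever_arm_m))


def synth_neck_params(cfg: SynthConfig | None = None) -> NeckModelParams:
    cfg = cfg or SynthConfig()
    return NeckModelParams(lever_arm=np.asarray(cfg.lever_arm_m))


def _perp_unit(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    v -= v @ axis * axis
    return v / np.linalg.norm(v)


def _skewed_amp(rng: np.random.Generator, bounds: tuple[float, float],
                scale: float) -> float:
    """Right-skewed amplitude: trigger floor + exponential tail, clipped."""
    lo, hi = bounds
    return lo + min(rng.exponential(scale), hi - lo)


def generate_recording(class_label: str, cfg: SynthConfig, seed: int,
                       recording_id: str = "r0", trigger_ts: int = 30,
                       direction: str | None = None,
                       ) -> tuple[Recording, dict]:
    """One seeded synthetic recording plus its planted-truth metadata.

    class_label is one of 'impact', 'nonimpact', 'off_teeth'.  Off-teeth
    recordings reuse the nonimpact signal model with a low-mode infrared
    draw.
    """
    if class_label not in ("impact", "nonimpact", "off_teeth"):
        raise ValueError(f"unknown synthetic class {class_label!r}")
    rng = np.random.default_rng(seed)
    t = (np.arange(N_SAMPLES) - PRETRIGGER_SAMPLES) * DT_S
    lin = rng.normal(0.0, cfg.acc_noise_g, (3, N_SAMPLES))
    ang = rng.normal(0.0, cfg.gyro_noise_rps, (3, N_SAMPLES))

    if class_label == "impact":
        direction = direction or str(rng.choice(DIRECTIONS))
        sector = DIRECTION_AXES[direction]
        # oblique blow: pulse direction uniform on the spherical cap about
        # the sector axis
        cos_min = np.cos(np.radians(cfg.impact_cone_deg))
        cos_t = rng.uniform(cos_min, 1.0)
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        phi = rng.uniform(0, 2 * np.pi)
        p1 = _perp_unit(sector, rng)
        p2 = np.cross(sector, p1)
        axis = cos_t * sector + sin_t * (np.cos(phi) * p1 + np.sin(phi) * p2)
        amp = _skewed_amp(rng, cfg.impact_amp_g, cfg.impact_amp_scale_g)
        dur = rng.uniform(*cfg.impact_duration_ms) * 1e-3
        # half-sine pulse opening just before the trigger so the 10 g
        # threshold is crossed at t = 0
        t0 = -2e-3
        window = (t >= t0) & (t <= t0 + dur)
        pulse = np.zeros(N_SAMPLES)
        pulse[window] = amp * np.sin(np.pi * (t[window] - t0) / dur)
        lin += axis[:, None] * pulse[None, :]
        w_amp = _skewed_amp(rng, cfg.impact_ang_vel_rps,
                            cfg.impact_ang_vel_scale_rps)
        w_freq = rng.uniform(*cfg.impact_band_hz)
        w_axis = _perp_unit(axis, rng)
        envelope = np.exp(-0.5 * ((t - (t0 + dur / 2)) / (dur / 2)) ** 2)
        ang += w_axis[:, None] * (w_amp * envelope
                                  * np.sin(2 * np.pi * w_freq * (t - t0)))[None, :]
        # a fraction of impacts carries brief post-pulse high-frequency
        # ringing (jaw / device clack) whose crest can top the pulse peak
        if rng.random() < cfg.impact_ringing_prob:
            r_ratio = rng.uniform(*cfg.impact_ringing_ratio)
            r_sigma = rng.uniform(*cfg.impact_ringing_sigma_ms) * 1e-3
            r_freq = rng.uniform(*cfg.nonimpact_band_hz)
            # crest snapped to a sample instant so the drawn crest ratio is
            # realised in the sampled series
            r_centre = round((t0 + dur + rng.uniform(3e-3, 15e-3)) * 1e3) * 1e-3
            r_axis = _perp_unit(np.array([0.0, 0.0, 1.0]), rng)
            r_env = np.exp(-0.5 * ((t - r_centre) / r_sigma) ** 2)
            lin += r_axis[:, None] * (r_ratio * amp * r_env
                                      * np.cos(2 * np.pi * r_freq
                                               * (t - r_centre)))[None, :]
        peak = amp
    else:
        direction = "none"
        axis = _perp_unit(np.array([0.0, 0.0, 1.0]), rng)
        amp = _skewed_amp(rng, cfg.nonimpact_amp_g, cfg.nonimpact_amp_scale_g)
        # spike train: 1-3 brief high-band bursts ...
        burst = np.zeros(N_SAMPLES)
        for _ in range(int(rng.integers(1, 4))):
            centre = rng.uniform(0.0, 60e-3)
            sigma = rng.uniform(*cfg.nonimpact_spike_sigma_ms) * 1e-3
            freq = rng.uniform(*cfg.nonimpact_band_hz)
            rel = rng.uniform(0.4, 1.0)
            burst += rel * np.exp(-0.5 * ((t - centre) / sigma) ** 2) \
                * np.sin(2 * np.pi * freq * (t - centre) + rng.uniform(0, 2 * np.pi))
        burst = burst / np.abs(burst).max()
        lin += axis[:, None] * (amp * burst)[None, :]
        # mid-band jostle bout in quadrature on the two perpendicular axes:
        # its magnitude envelope is a smooth 1.5-5 g bump of variable
        # duration, so pulse widths at half maximum and peak wavelet
        # frequencies overlap the impact class
        mid_amp = rng.uniform(*cfg.nonimpact_mid_amp_g)
        mid_freq = rng.uniform(*cfg.nonimpact_midband_hz)
        mid_sigma = rng.uniform(*cfg.nonimpact_mid_sigma_ms) * 1e-3
        mid_env = np.exp(-0.5 * ((t - rng.uniform(10e-3, 50e-3)) / mid_sigma) ** 2)
        p1 = _perp_unit(axis, rng)
        p2 = np.cross(axis, p1)
        phase = 2 * np.pi * mid_freq * t + rng.uniform(0, 2 * np.pi)
        lin += (mid_amp * mid_env)[None, :] \
            * (p1[:, None] * np.sin(phase)[None, :]
               + p2[:, None] * np.cos(phase)[None, :])
        w_amp = _skewed_amp(rng, cfg.nonimpact_ang_vel_rps,
                            cfg.nonimpact_ang_vel_scale_rps)
        w_freq = rng.uniform(*cfg.nonimpact_band_hz)
        w_axis = _perp_unit(axis, rng)
        w_env = np.exp(-0.5 * ((t - rng.uniform(0.0, 50e-3)) / 5e-3) ** 2)
        ang += w_axis[:, None] * (w_amp * w_env
                                  * np.sin(2 * np.pi * w_freq * t))[None, :]
        # head-shake jostle in quadrature: smooth angular magnitude bout
        j_amp = rng.uniform(*cfg.nonimpact_ang_jostle_rps)
        j_freq = rng.uniform(*cfg.nonimpact_midband_hz)
        j_sigma = rng.uniform(*cfg.nonimpact_mid_sigma_ms) * 1e-3
        j_env = np.exp(-0.5 * ((t - rng.uniform(10e-3, 50e-3)) / j_sigma) ** 2)
        q1 = _perp_unit(w_axis, rng)
        q2 = np.cross(w_axis, q1)
        j_phase = 2 * np.pi * j_freq * t + rng.uniform(0, 2 * np.pi)
        ang += (j_amp * j_env)[None, :] * (q1[:, None] * np.sin(j_phase)[None, :]
                                           + q2[:, None] * np.cos(j_phase)[None, :])
        peak = amp

    # slow whole-body motion (running / device manipulation): a few-Hz
    # quadrature sway giving real velocity change and head displacement;
    # weaker during impacts so the direction-consistency margin holds
    sway_range = (cfg.impact_body_motion_g if class_label == "impact"
                  else cfg.body_motion_g)
    body_amp = rng.uniform(*sway_range)
    body_freq = rng.uniform(*cfg.body_motion_hz)
    b1 = _perp_unit(np.array([1.0, 0.0, 0.0]), rng)
    b2 = np.cross(np.array([1.0, 0.0, 0.0]), b1)
    bphase = 2 * np.pi * body_freq * t + rng.uniform(0, 2 * np.pi)
    lin += body_amp * (b1[:, None] * np.sin(bphase)[None, :]
                       + b2[:, None] * np.cos(bphase)[None, :])

    # modes truncated at 2.5 sd: with the 6-pooled-sd default separation the
    # planted on/off-teeth truth is then decidable by construction (no draw
    # can straddle the mixture crossing)
    if class_label == "off_teeth":
        ir = cfg.ir_mu_low + cfg.ir_sd_low * np.clip(rng.standard_normal(), -2.5, 2.5)
    else:
        ir = cfg.ir_mu_high + cfg.ir_sd_high * np.clip(rng.standard_normal(), -2.5, 2.5)

    rec = Recording(recording_id=recording_id, subject_event_id="synth-event",
                    trigger_timestamp=int(trigger_ts), lin_acc_device=lin,
                    ang_vel_device=ang, ir_reading=float(ir))
    truth = {"recording_id": recording_id, "class": class_label,
             "direction": direction, "peak_g": float(peak),
             "trigger_ts": int(trigger_ts)}
    return rec, truth


def generate_cohort(cfg: SynthConfig | None = None
                    ) -> tuple[list[Recording], list[VideoLabel], pd.DataFrame]:
    """Seeded cohort on a timeline with matching video labels.

    Returns (recordings, video labels, truth table).  The truth table's
    ``in_ground_truth`` column marks the rows the selection rules should
    recover: all impacts and nonimpacts; off-teeth and no-view confounder
    recordings are planted to be excluded.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    roles = (["impact"] * cfg.n_impacts + ["nonimpact"] * cfg.n_nonimpacts
             + ["off_teeth"] * cfg.n_offteeth + ["noview"] * cfg.n_noview)
    rng.shuffle(roles)

    recordings: list[Recording] = []
    labels: list[VideoLabel] = []
    truth_rows: list[dict] = []
    spacing = 30   # seconds between events: keeps +/-2 s dilations disjoint
    for k, role in enumerate(roles):
        ts = spacing * (k + 1)
        rid = f"rec{k:04d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if role == "impact":
            rec, truth = generate_recording("impact", cfg, sub_seed, rid, ts)
            skew = rng.uniform(-cfg.clock_skew_s, cfg.clock_skew_s)
            labels.append(VideoLabel(ts + skew - 0.4, ts + skew + 0.4,
                                     "helmet_contact", truth["direction"]))
            truth["in_ground_truth"] = True
            truth["label"] = "impact"
        elif role == "noview":
            rec, truth = generate_recording("nonimpact", cfg, sub_seed, rid, ts)
            labels.append(VideoLabel(ts - 5.0, ts + 5.0, "no_view"))
            truth["class"] = "noview_confounder"
            truth["in_ground_truth"] = False
            truth["label"] = ""
        else:
            rec, truth = generate_recording(role, cfg, sub_seed, rid, ts)
            category = "no_contact" if rng.random() < 0.5 else "idle"
            labels.append(VideoLabel(ts - 5.0, ts + 5.0, category))
            truth["in_ground_truth"] = role == "nonimpact"
            truth["label"] = "nonimpact" if role == "nonimpact" else ""
        recordings.append(rec)
        truth_rows.append(truth)
    columns = ["recording_id", "class", "direction", "peak_g", "trigger_ts",
               "in_ground_truth", "label"]
    truth = pd.DataFrame(truth_rows, columns=columns).set_index("recording_id")
    return recordings, sorted(labels, key=lambda lbl: lbl.start), truth
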
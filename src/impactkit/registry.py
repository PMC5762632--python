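"""Canonical feature registry.

Every feature the pipeline extracts has a fixed name and position.  The
registry is the single source of truth for the 411-slot feature vector:

* time-domain block (24): peak kinematics and FWHM impulse durations,
* PSD block (152): periodogram amplitudes on a 10 Hz grid,
* wavelet per-frequency block (152): time-max Morlet amplitudes,
* wavelet descriptor block (32): peak amplitude / frequency / timing /
  10%-bandwidth per channel,
* head-neck model block (51): linkage kinematics and coupling ratios.

The ordering is frozen; tables and serialized models carry the registry
version and are refused on mismatch.
"""

from __future__ import annotations

import hashlib

REGISTRY_VERSION = "impactkit-registry-1"

#: anatomical axes for linear channels (anterior-posterior, left-right,
#: inferior-superior) and the vector magnitude
LIN_CHANNELS = ("ap", "lr", "is", "mag")
#: anatomical planes for angular channels (rotations about AP, LR, IS)
ANG_CHANNELS = ("cor", "sag", "hor", "mag")

#: PSD / wavelet frequency grids in Hz (10 Hz bins; the angular grid stops
#: at 180 Hz, the gyroscope bandwidth being 184 Hz)
LIN_FREQS_HZ = tuple(range(10, 201, 10))   # 20 bins
ANG_FREQS_HZ = tuple(range(10, 181, 10))   # 18 bins

#: universal-joint + neck orientation angle names, in solver order
ANGLE_NAMES = ("uj_lr", "uj_is", "neck_ap", "neck_lr", "neck_is")

#: the three model points tracked by the linkage solver
POINT_NAMES = ("torso_base", "head_base", "head_cog")

#: coupling-ratio series: angular-acceleration plane paired with each of the
#: two linear axes normal to its rotation axis
RATIO_PAIRS = (
    ("cor", "lr"), ("cor", "is"),   # rotation about AP
    ("sag", "ap"), ("sag", "is"),   # rotation about LR
    ("hor", "ap"), ("hor", "lr"),   # rotation about IS
)


def time_domain_names() -> list[str]:
    names = []
    for quantity, channels in (
        ("peak_lin_acc", LIN_CHANNELS),
        ("delta_lin_vel", LIN_CHANNELS),
        ("peak_ang_acc", ANG_CHANNELS),
        ("delta_ang_vel", ANG_CHANNELS),
    ):
        names += [f"td_{quantity}_{ch}" for ch in channels]
    for sig, channels in (("lin_acc", LIN_CHANNELS), ("ang_acc", ANG_CHANNELS)):
        names += [f"td_fwhm_{sig}_{ch}" for ch in channels]
    return names


def psd_names() -> list[str]:
    names = [f"psd_lin_acc_{ch}_{f}hz" for ch in LIN_CHANNELS for f in LIN_FREQS_HZ]
    names += [f"psd_ang_acc_{ch}_{f}hz" for ch in ANG_CHANNELS for f in ANG_FREQS_HZ]
    return names


def wavelet_grid_names() -> list[str]:
    names = [f"wt_lin_acc_{ch}_{f}hz" for ch in LIN_CHANNELS for f in LIN_FREQS_HZ]
    names += [f"wt_ang_acc_{ch}_{f}hz" for ch in ANG_CHANNELS for f in ANG_FREQS_HZ]
    return names


def wavelet_descriptor_names() -> list[str]:
    names = []
    for sig, channels in (("lin_acc", LIN_CHANNELS), ("ang_acc", ANG_CHANNELS)):
        for ch in channels:
            for desc in ("peak_amp", "peak_freq", "peak_time_offset", "bandwidth10"):
                names.append(f"wtd_{sig}_{ch}_{desc}")
    return names


def model_names() -> list[str]:
    names = ["nm_signmatch_lr", "nm_signmatch_is"]
    names += [f"nm_peak_angle_{a}" for a in ANGLE_NAMES]
    names += [f"nm_peak_angvel_{a}" for a in ANGLE_NAMES]
    names += [f"nm_peak_angacc_{a}" for a in ANGLE_NAMES]
    for point in POINT_NAMES:
        for q in ("disp", "vel", "acc"):
            names.append(f"nm_peak_{q}_{point}")
    names += [f"nm_peak_disp_cog_{ax}" for ax in ("ap", "lr", "is")]
    names += [f"nm_peak_vel_cog_{ax}" for ax in ("ap", "lr", "is")]
    names.append("nm_peak_base_offset")
    for plane, axis in RATIO_PAIRS:
        for stat in ("mean", "std", "peak"):
            names.append(f"cr_{plane}_{axis}_{stat}")
    return names


BLOCKS: dict[str, tuple[str, ...]] = {
    "time_domain": tuple(time_domain_names()),
    "psd": tuple(psd_names()),
    "wavelet_grid": tuple(wavelet_grid_names()),
    "wavelet_descriptors": tuple(wavelet_descriptor_names()),
    "model": tuple(model_names()),
}

BLOCK_SIZES = {name: len(names) for name, names in BLOCKS.items()}

#: the canonical 411-name ordering
FEATURE_NAMES: tuple[str, ...] = tuple(n for names in BLOCKS.values() for n in names)

FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

N_FEATURES = len(FEATURE_NAMES)


def registry_hash() -> str:
    """SHA-256 of the newline-joined canonical name list (platform stable)."""
    return hashlib.sha256("\n".join(FEATURE_NAMES).encode()).hexdigest()


def validate_names(names) -> None:
    """Raise ``RegistryError`` unless *names* equals the canonical ordering."""
    names = list(names)
    if len(names) != N_FEATURES or list(FEATURE_NAMES) != names:
        raise RegistryError(
            f"feature names do not match registry {REGISTRY_VERSION} "
            f"({len(names)} columns, expected {N_FEATURES})"
        )


class RegistryError(ValueError):
    """Feature table / vector does not conform to the canonical registry."""
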
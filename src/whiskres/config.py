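"""Analysis configuration: every constant of the pipeline in one place.

Defaults equal the published values wherever one exists (20 ms pulse,
+-4 degree movement criterion, 3-25 Hz rate band-pass, 30 Hz angle
low-pass, kernel widths n = 8/20 on a 100-point support, first 15 stimuli,
250 ms low-frequency amplitude window, 1 s pre/post spectra).  A single
global seed fans out deterministically to per-module sub-seeds by stable
hashing of the consumer's name.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass

import yaml

__all__ = ["Config", "derive_seed"]


def derive_seed(seed: int, name: str) -> int:
    """Deterministic sub-seed (< 2**31) for module ``name``."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class Config:
    # sampling
    fs_hz: float = 1000.0
    # spike rate estimation
    kernel_widths: tuple[float, float] = (8.0, 20.0)
    kernel_support: int = 100
    rate_band_hz: tuple[float, float] = (3.0, 25.0)
    butter_order: int = 4
    # whisker kinematics
    angle_lowpass_hz: float = 30.0
    movement_threshold_deg: float = 4.0
    merge_gap_ms: float = 250.0
    # spectra
    cwt_fmin_hz: float = 1.0
    cwt_fmax_hz: float = 30.0
    cwt_df_hz: float = 0.1
    morlet_omega0: float = 6.0
    spectrum_normalization: str = "max"  # "max" | "area"
    # stimulation protocol
    pulse_ms: float = 20.0
    rest_ms: float = 10_000.0
    # stimulus response
    n_entrain_stimuli: int = 15
    low_freq_window_ms: float = 250.0
    post_stim_window_ms: float = 1000.0
    # randomness
    seed: int = 0

    def sub_seed(self, name: str) -> int:
        return derive_seed(self.seed, name)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["kernel_widths"] = list(d["kernel_widths"])
        d["rate_band_hz"] = list(d["rate_band_hz"])
        return d

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kernel_widths", "rate_band_hz"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
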
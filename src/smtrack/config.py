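"""Parameter containers shared across the pipeline.

Conventions used throughout the package:

* frames are 0-based;
* positions are continuous pixel coordinates with the origin at the centre
  of pixel (0, 0);
* nanometre quantities are obtained from pixel quantities through
  ``pixel_size_nm``;
* times are seconds unless a name says otherwise (bleach decay constants are
  per *exposure*, i.e. per frame, because the dye only bleaches while the
  laser is on).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "KineticParams",
    "ClassifierParams",
    "RunConfig",
    "PARAM_PROVENANCE",
]


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera/illumination settings of a tracking movie.

    ``interval_time`` is measured frame start to frame start; the laser is on
    for ``exposure_time`` at the beginning of each interval and off for the
    remaining dark time.
    """

    exposure_time: float = 0.01          # s
    interval_time: float = 0.2           # s, frame start to frame start
    n_frames: int = 600
    pixel_size_nm: float = 106.7
    image_shape: Tuple[int, int] = (512, 512)   # rows, cols
    nucleus_mask: Optional[np.ndarray] = None   # boolean, same shape as image

    def __post_init__(self) -> None:
        _require_positive("exposure_time", self.exposure_time)
        _require_positive("interval_time", self.interval_time)
        _require_positive("pixel_size_nm", self.pixel_size_nm)
        if self.exposure_time > self.interval_time:
            raise ValueError(
                "exposure_time must not exceed interval_time "
                f"({self.exposure_time} > {self.interval_time})"
            )
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError(f"image_shape must be 2D and >= 8 px, got {self.image_shape}")
        if self.nucleus_mask is not None and tuple(self.nucleus_mask.shape) != tuple(self.image_shape):
            raise ValueError("nucleus_mask shape must equal image_shape")

    @property
    def duration(self) -> float:
        """Total wall-clock duration of the movie in seconds."""
        return self.n_frames * self.interval_time

    @property
    def dark_time(self) -> float:
        return self.interval_time - self.exposure_time


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth photophysical and binding kinetics of the simulator.

    The molecule switches between free diffusion and chromatin binding; a
    binding event is non-specific (mean dwell ``T_ns``) with probability
    ``p_ns``, otherwise specific (mean dwell ``T_s``).  Photobleaching
    survival over exposures is bi-exponential with amplitude ``bleach_amp``
    on the fast decay.
    """

    D_free: float = 2.0                 # um^2/s, free-diffusion coefficient
    p_ns: float = 0.8                   # probability a binding event is non-specific
    p_s: float = 0.2
    T_ns: float = 0.5                   # s, mean non-specific dwell
    T_s: float = 5.0                    # s, mean specific dwell
    k_bind: float = 0.1                 # 1/s, binding rate of a free molecule
    bleach_amp: float = 0.5             # fraction on the fast bleach decay
    bleach_k1: float = 1.0 / 80.0       # per exposure
    bleach_k2: float = 1.0 / 300.0      # per exposure
    photons_per_frame: float = 500.0    # expected signal photons per exposure
    background_rate: float = 10.0       # photons per pixel per exposure
    psf_sigma_nm: float = 128.0         # Gaussian PSF width
    bound_jitter_nm: float = 30.0       # per-frame sd of a bound molecule
    p_miss: float = 0.1                 # per-frame detection-failure probability
                                        # (blinking / axial excursions; the reason
                                        # trackers fill single-frame gaps)

    def __post_init__(self) -> None:
        for name in ("T_ns", "T_s", "psf_sigma_nm"):
            _require_positive(name, getattr(self, name))
        for name in ("D_free", "k_bind", "bleach_k1", "bleach_k2",
                     "photons_per_frame", "background_rate", "bound_jitter_nm"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be >= 0 and finite, got {value!r}")
        if not (0.0 <= self.bleach_amp <= 1.0):
            raise ValueError(f"bleach_amp must be in [0, 1], got {self.bleach_amp}")
        if not (0.0 <= self.p_miss < 1.0):
            raise ValueError(f"p_miss must be in [0, 1), got {self.p_miss}")
        if abs(self.p_ns + self.p_s - 1.0) > 1e-9:
            raise ValueError(f"p_ns + p_s must equal 1, got {self.p_ns + self.p_s}")
        if self.T_s < self.T_ns:
            raise ValueError(
                f"ordering convention requires T_s >= T_ns, got {self.T_s} < {self.T_ns}"
            )

    @property
    def mean_bleach_exposures(self) -> float:
        """Expected number of exposures survived before photobleaching."""
        a = self.bleach_amp
        m1 = 1.0 / self.bleach_k1 if self.bleach_k1 > 0 else np.inf
        m2 = 1.0 / self.bleach_k2 if self.bleach_k2 > 0 else np.inf
        return a * m1 + (1.0 - a) * m2

    def stationary_occupancy(self) -> dict:
        """Stationary state occupancy of the free/bound_ns/bound_s chain.

        Solved from detailed balance of the three-state continuous-time
        chain: pi_ns = pi_free * k_bind * p_ns * T_ns (and likewise for the
        specific state).
        """
        w_free = 1.0
        w_ns = self.k_bind * self.p_ns * self.T_ns
        w_s = self.k_bind * self.p_s * self.T_s
        z = w_free + w_ns + w_s
        return {"free": w_free / z, "bound_ns": w_ns / z, "bound_s": w_s / z}


@dataclass(frozen=True)
class ClassifierParams:
    """Displacement thresholds defining a chromatin-bound track segment.

    Defaults follow the motion envelope of immobile histones: 220 nm maximum
    frame-to-frame displacement and 270 nm maximum two-frame displacement.
    ``n_min`` (minimum localizations per bound segment) depends on the frame
    interval; leave it ``None`` to have the pipeline compute it with
    :func:`smtrack.classify.choose_nmin`.
    """

    r_max1_nm: float = 220.0
    r_max2_nm: float = 270.0
    n_min: Optional[int] = None

    def __post_init__(self) -> None:
        _require_positive("r_max1_nm", self.r_max1_nm)
        if self.r_max2_nm < self.r_max1_nm:
            raise ValueError("r_max2_nm must be >= r_max1_nm")
        if self.n_min is not None and self.n_min < 2:
            raise ValueError(f"n_min must be >= 2, got {self.n_min}")


#: Which defaults come from the published protocol and which are package
#: decisions; written into saved configs so a run is self-documenting.
PARAM_PROVENANCE = {
    "acquisition.exposure_time": "paper",
    "acquisition.interval_time": "paper",
    "acquisition.n_frames": "paper",
    "acquisition.pixel_size_nm": "decision",
    "acquisition.image_shape": "decision",
    "kinetics.D_free": "decision",
    "kinetics.T_ns": "decision",
    "kinetics.T_s": "decision",
    "kinetics.p_ns": "decision",
    "kinetics.p_s": "decision",
    "kinetics.k_bind": "decision",
    "kinetics.bleach_amp": "decision",
    "kinetics.bleach_k1": "decision",
    "kinetics.bleach_k2": "decision",
    "kinetics.photons_per_frame": "decision",
    "kinetics.background_rate": "decision",
    "kinetics.psf_sigma_nm": "decision",
    "kinetics.bound_jitter_nm": "decision",
    "kinetics.p_miss": "decision",
    "classifier.r_max1_nm": "paper",
    "classifier.r_max2_nm": "paper",
    "classifier.n_min": "paper",
    "fitting.alpha": "decision",
    "seed": "decision",
}


@dataclass
class RunConfig:
    """Bundle of all parameter blocks plus seed and output directory.

    Round-trips losslessly through a flat ``section.key=value`` text file so
    every pipeline stage can record exactly what it ran with.
    """

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    kinetics: KineticParams = field(default_factory=KineticParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "."

    def to_file(self, path) -> None:
        lines = ["# smtrack run configuration (section.key=value)"]
        for section, obj in (("acquisition", self.acquisition),
                             ("kinetics", self.kinetics),
                             ("classifier", self.classifier)):
            for f in dataclasses.fields(obj):
                if f.name == "nucleus_mask":
                    continue
                value = getattr(obj, f.name)
                if isinstance(value, tuple):
                    value = "x".join(str(v) for v in value)
                key = f"{section}.{f.name}"
                prov = PARAM_PROVENANCE.get(key, "decision")
                lines.append(f"{key}={value}  # {prov}")
        lines.append(f"fitting.alpha={self.alpha}  # {PARAM_PROVENANCE['fitting.alpha']}")
        lines.append(f"seed={self.seed}  # decision")
        lines.append(f"output_dir={self.output_dir}  # decision")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()

        def block(section, klass):
            kwargs = {}
            for f in dataclasses.fields(klass):
                key = f"{section}.{f.name}"
                if key not in raw:
                    continue
                text = raw[key]
                if text == "None":
                    kwargs[f.name] = None
                elif f.name == "image_shape":
                    kwargs[f.name] = tuple(int(v) for v in text.split("x"))
                elif f.type in ("int", "Optional[int]") or f.name in ("n_frames", "n_min"):
                    kwargs[f.name] = int(text)
                else:
                    kwargs[f.name] = float(text)
            return klass(**kwargs)

        return cls(
            acquisition=block("acquisition", AcquisitionConfig),
            kinetics=block("kinetics", KineticParams),
            classifier=block("classifier", ClassifierParams),
            alpha=float(raw.get("fitting.alpha", 0.05)),
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir", "."),
        )
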
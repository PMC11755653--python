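"""Analysis configuration: frequency bands, wavelet and estimator settings.

The defaults reproduce the whole-night sleep-EEG connectivity analysis this
package implements: six frequency bands between 0.25 and 30 Hz, a Morlet
wavelet with scaling parameter ``w0 = 2*pi``, a 0.1 s synchronization time
step, and the significance levels used for the AHI correlation (0.05) and
the group comparison (0.001).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigurationError

TWO_PI = 2.0 * math.pi

#: Default analysis bands (name, f_low Hz, f_high Hz): slow activity, delta,
#: theta, alpha, and two beta sub-bands.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("slow", 0.25, 1.0),
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta1", 12.0, 20.0),
    ("beta2", 20.0, 30.0),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the synchronization analysis.

    Attributes
    ----------
    bands
        Ordered, non-overlapping ``(name, f_low, f_high)`` triples in Hz.
    w0
        Morlet scaling parameter (radians); ``2*pi`` puts the carrier at
        ``f`` Hz so the transform is parameterized directly by frequency.
    freq_points_per_band
        Linearly spaced frequency-grid points per band, endpoints included.
    wb_time_step
        Spacing of the synchronization time grid ``t0`` in seconds.
    smoothing_window
        Lower bound (seconds) on the centered moving-average window applied
        to the normalized cross spectrum before taking its modulus.  The
        effective window at frequency ``f`` is
        ``max(smoothing_window, min_cycles / f)``.
    min_cycles
        Minimum number of oscillation cycles the smoothing window must span.
    correlation_method
        ``"pearson"`` (default, matching the t-test inference) or
        ``"spearman"``.
    alpha_corr
        Significance level for the AHI correlation test.
    alpha_mw
        Significance level for the Mann-Whitney group comparison.
    cwt_prefactor
        Leading factor of the windowed wavelet integral: ``"sqrt"`` for
        ``sqrt(f)`` (default) or ``"linear"`` for ``f``.  The
        synchronization measure is invariant to this choice because the
        cross spectrum is normalized per (frequency, time) point.
    """

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    w0: float = TWO_PI
    freq_points_per_band: int = 32
    wb_time_step: float = 0.1
    smoothing_window: float = 2.0
    min_cycles: float = 8.0
    correlation_method: str = "pearson"
    alpha_corr: float = 0.05
    alpha_mw: float = 0.001
    cwt_prefactor: str = "sqrt"

    def __post_init__(self):
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self, fs: float | None = None) -> None:
        """Raise :class:`ConfigurationError` on any inconsistent setting."""
        if not self.bands:
            raise ConfigurationError("at least one band is required")
        prev_hi = 0.0
        for name, lo, hi in self.bands:
            if not (0.0 < lo < hi):
                raise ConfigurationError(f"band {name!r}: need 0 < f_low < f_high")
            if lo < prev_hi:
                raise ConfigurationError(f"band {name!r} overlaps the previous band")
            prev_hi = hi
        names = [b[0] for b in self.bands]
        if len(set(names)) != len(names):
            raise ConfigurationError("band names must be unique")
        if fs is not None and self.bands[-1][2] >= fs / 2:
            raise ConfigurationError(
                f"band {self.bands[-1][0]!r} reaches {self.bands[-1][2]} Hz, "
                f"at or above the Nyquist frequency {fs / 2} Hz"
            )
        if self.w0 <= 0:
            raise ConfigurationError("w0 must be positive")
        if self.freq_points_per_band < 2:
            raise ConfigurationError("freq_points_per_band must be >= 2")
        if self.wb_time_step <= 0:
            raise ConfigurationError("wb_time_step must be positive")
        if self.smoothing_window <= 0:
            raise ConfigurationError("smoothing_window must be positive")
        if self.min_cycles < 0:
            raise ConfigurationError("min_cycles must be non-negative")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ConfigurationError(
                f"unknown correlation_method {self.correlation_method!r}"
            )
        for alpha in (self.alpha_corr, self.alpha_mw):
            if not (0.0 < alpha < 1.0):
                raise ConfigurationError("significance levels must lie in (0, 1)")
        if self.cwt_prefactor not in ("sqrt", "linear"):
            raise ConfigurationError(
                f"unknown cwt_prefactor {self.cwt_prefactor!r}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def band_edges(self, name: str) -> tuple[float, float]:
        for bname, lo, hi in self.bands:
            if bname == name:
                return lo, hi
        raise ConfigurationError(f"unknown band {name!r}")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "bands": [list(b) for b in self.bands],
            "w0": self.w0,
            "freq_points_per_band": self.freq_points_per_band,
            "wb_time_step": self.wb_time_step,
            "smoothing_window": self.smoothing_window,
            "min_cycles": self.min_cycles,
            "correlation_method": self.correlation_method,
            "alpha_corr": self.alpha_corr,
            "alpha_mw": self.alpha_mw,
            "cwt_prefactor": self.cwt_prefactor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(tuple(b) for b in d["bands"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a configuration from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)
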
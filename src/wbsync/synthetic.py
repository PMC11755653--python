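"""Surrogate multichannel EEG with programmed phase coupling.

The generator targets exactly the quantity the analysis chain estimates:
phase locking between channel pairs within frequency bands.  Each band
component of a channel is a frequency-modulated oscillator

    x(t) = cos( Phi(t) + theta(t) ),

where ``Phi`` is a narrow-band carrier phase (instantaneous frequency
wandering smoothly inside the band) and ``theta`` is channel-specific
phase jitter.  A *coupled pair* of channels shares one carrier ``Phi``
(one latent driver per pair and band), and each member receives
independent Wiener-process jitter whose variance growth rate is scaled
by ``(1 - epsilon)``:

    theta_c(t) = sqrt(1 - epsilon) * B_c(t),   Var[B_c(t)] = D * t,

so ``epsilon = 1`` gives identical phases (synchronization strength 1)
and ``epsilon = 0`` gives a phase difference that diffuses without bound
(asymptotically independent phases, synchronization at the chance
floor).  Uncoupled channels carry private, jitter-free oscillators.
Because drivers are latent *per pair*, a channel can belong to at most
one coupled pair per band; the default scheme couples the eight
homologous left-right (interhemispheric) pairs, which are disjoint.

Cohorts draw each subject's apnea-hypopnea index from a group-specific
lognormal distribution (control median 2, clipped to [0, 15]; main
median 44, clipped to (15, 120]) and depress every programmed coupling
linearly with AHI, ``epsilon(AHI) = clip(eps + ahi_slope * AHI, 0, 1)``,
so the negative synchronization-severity correlations the analysis is
designed to detect are recoverable by construction.

All randomness derives from integer key tuples fed to
``numpy.random.default_rng``: the signal of a given channel depends only
on (seed, band, driver/channel index), never on which other channels or
subjects are generated, so cohorts are reproducible and channel subsets
are exact restrictions of the full montage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._edf import write_edf
from .config import DEFAULT_BANDS
from .errors import DomainError, ValidationError
from .recordings import CANONICAL_CHANNELS, Recording, group_from_ahi

__all__ = [
    "HOMOLOGOUS_PAIRS",
    "CouplingScheme",
    "SyntheticSubject",
    "CohortTable",
    "default_scheme",
    "generate_coupled_pair",
    "generate_recording",
    "generate_cohort",
]

#: The eight homologous (left-right symmetric) channel pairs of the montage.
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("C3", "C4"), ("P3", "P4"),
    ("O1", "O2"), ("F7", "F8"), ("T3", "T4"), ("T5", "T6"),
)

#: Baseline coupling strength of a programmed pair at AHI = 0.
DEFAULT_EPS0 = 0.95
#: Decline of coupling per AHI unit (events/hour) in the default cohort.
DEFAULT_AHI_SLOPE = -0.012
#: Variance growth rate of each channel's pair jitter at epsilon = 0,
#: rad^2 per second.
DEFAULT_PHASE_DIFFUSION = 2.5
#: Between-subject SD of each realized coupling strength (biological
#: heterogeneity); keeps cohort-level synchronization-severity
#: correlations at a realistic strength instead of near -1.
DEFAULT_COUPLING_JITTER_SD = 0.12
#: Additive white measurement noise (same units as the unit-amplitude
#: oscillators).
DEFAULT_NOISE_SD = 0.3

_AHI_CONTROL_MEDIAN = 2.0
_AHI_CONTROL_SIGMA = 0.8
_AHI_MAIN_MEDIAN = 44.0
_AHI_MAIN_SIGMA = 0.5
_AHI_MAX = 120.0


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _seed_tuple(seed) -> tuple[int, ...]:
    if np.isscalar(seed):
        return (int(seed),)
    return tuple(int(s) for s in seed)


@dataclass(frozen=True)
class CouplingScheme:
    """Programmed pairwise coupling per band.

    ``coupling`` maps a band name to ``{(ch_a, ch_b): epsilon}``; within a
    band the coupled pairs must be disjoint (one latent driver per pair).
    """

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    coupling: dict = field(default_factory=dict)
    ahi_slope: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    phase_diffusion: float = DEFAULT_PHASE_DIFFUSION
    coupling_jitter_sd: float = 0.0
    channels: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self):
        band_names = {b[0] for b in self.bands}
        for band, pairs in self.coupling.items():
            if band not in band_names:
                raise ValidationError(f"coupling refers to unknown band {band!r}")
            used = set()
            for (a, b), eps in pairs.items():
                if a not in self.channels or b not in self.channels:
                    raise ValidationError(f"unknown channel in pair ({a}, {b})")
                if a == b:
                    raise ValidationError("self-coupling is not allowed")
                if not (0.0 <= eps <= 1.0):
                    raise ValidationError(f"epsilon {eps} outside [0, 1]")
                if a in used or b in used:
                    raise ValidationError(
                        f"channel reused within band {band!r}: coupled pairs "
                        "must be disjoint")
                used.update((a, b))
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.phase_diffusion < 0:
            raise ValidationError("phase_diffusion must be non-negative")
        if self.coupling_jitter_sd < 0:
            raise ValidationError("coupling_jitter_sd must be non-negative")

    def epsilon_matrix(self, band: str) -> np.ndarray:
        """Symmetric coupling matrix for one band in canonical channel order."""
        n = len(self.channels)
        idx = {ch: k for k, ch in enumerate(self.channels)}
        eps = np.zeros((n, n))
        for (a, b), e in self.coupling.get(band, {}).items():
            eps[idx[a], idx[b]] = eps[idx[b], idx[a]] = e
        return eps

    def for_ahi(self, ahi: float,
                rng: np.random.Generator | None = None) -> "CouplingScheme":
        """Scheme realized for one subject.

        The AHI slope is applied, an optional per-(band, pair) Gaussian
        heterogeneity term of SD ``coupling_jitter_sd`` is added (when an
        ``rng`` is supplied), and the result is clipped to [0, 1].
        """
        coupling = {}
        for band, pairs in self.coupling.items():
            realized = {}
            for pair, e in pairs.items():
                e = e + self.ahi_slope * ahi
                if rng is not None and self.coupling_jitter_sd > 0:
                    e += self.coupling_jitter_sd * rng.standard_normal()
                realized[pair] = float(np.clip(e, 0.0, 1.0))
            coupling[band] = realized
        return replace(self, coupling=coupling, ahi_slope=0.0,
                       coupling_jitter_sd=0.0)


def default_scheme(eps0: float = DEFAULT_EPS0,
                   ahi_slope: float = DEFAULT_AHI_SLOPE,
                   bands=DEFAULT_BANDS,
                   pairs=HOMOLOGOUS_PAIRS,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   phase_diffusion: float = DEFAULT_PHASE_DIFFUSION,
                   coupling_jitter_sd: float = DEFAULT_COUPLING_JITTER_SD,
                   channels=CANONICAL_CHANNELS) -> CouplingScheme:
    """Homologous-pair coupling at strength ``eps0`` in every band."""
    coupling = {b[0]: {tuple(p): eps0 for p in pairs} for b in bands}
    return CouplingScheme(bands=tuple(bands), coupling=coupling,
                          ahi_slope=ahi_slope, noise_sd=noise_sd,
                          phase_diffusion=phase_diffusion,
                          coupling_jitter_sd=coupling_jitter_sd,
                          channels=tuple(channels))


# ---------------------------------------------------------------------------
# Oscillator primitives
# ---------------------------------------------------------------------------

def _carrier_phase(rng: np.random.Generator, n: int, fs: float,
                   f_center: float, bandwidth: float) -> np.ndarray:
    """Phase of a narrow-band FM carrier: f_inst wanders smoothly in-band."""
    wander = rng.standard_normal(n)
    # ~0.5 s correlation time; slow compared with every analysis band
    wander = gaussian_filter1d(wander, sigma=0.5 * fs, mode="reflect")
    sd = wander.std()
    if sd > 0:
        wander /= sd
    f_inst = f_center + (bandwidth / 4.0) * wander
    f_inst = np.clip(f_inst, f_center - bandwidth / 2.0,
                     f_center + bandwidth / 2.0)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return phase0 + 2.0 * np.pi * np.cumsum(f_inst) / fs


def _wiener(rng: np.random.Generator, n: int, fs: float,
            rate: float) -> np.ndarray:
    """Wiener process with Var[B(t)] = rate * t, sampled at fs."""
    if rate == 0.0:
        return np.zeros(n)
    return np.cumsum(rng.normal(0.0, np.sqrt(rate / fs), n))


def _band_params(lo: float, hi: float) -> tuple[float, float]:
    """(center frequency, FM bandwidth) used for a band's oscillators."""
    return (lo + hi) / 2.0, 0.5 * (hi - lo)


def generate_coupled_pair(f_center: float, bandwidth: float, epsilon: float,
                          duration: float, fs: float, seed,
                          noise_sd: float = 0.0,
                          phase_diffusion: float = DEFAULT_PHASE_DIFFUSION,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Two oscillators sharing a carrier, with (1 - epsilon)-scaled phase jitter.

    Returns two real signals of ``round(duration * fs)`` samples.  The
    same seed reproduces the signals bit for bit.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise DomainError("epsilon must lie in [0, 1]")
    if f_center - bandwidth / 2.0 <= 0 or f_center + bandwidth / 2.0 >= fs / 2.0:
        raise DomainError("band must lie strictly inside (0, fs/2)")
    if duration <= 0 or fs <= 0:
        raise DomainError("duration and fs must be positive")
    n = int(round(duration * fs))
    key = _seed_tuple(seed)
    phi = _carrier_phase(_rng(*key, 0), n, fs, f_center, bandwidth)
    rate = (1.0 - epsilon) * phase_diffusion
    signals = []
    for c in (1, 2):
        jitter = _wiener(_rng(*key, c), n, fs, rate)
        x = np.cos(phi + jitter)
        if noise_sd > 0:
            x = x + noise_sd * _rng(*key, 10 + c).standard_normal(n)
        signals.append(x)
    return signals[0], signals[1]


# ---------------------------------------------------------------------------
# Recordings and cohorts
# ---------------------------------------------------------------------------

def generate_recording(scheme: CouplingScheme, duration: float, fs: float,
                       seed, subject_id: str = "synthetic",
                       channels=None) -> Recording:
    """Generate a multichannel recording realizing ``scheme``.

    ``channels`` restricts the output montage; restricted channels carry
    exactly the signals they would in the full montage (randomness is
    keyed by canonical channel indices, not generation order).
    """
    if duration <= 0 or fs <= 0:
        raise DomainError("duration and fs must be positive")
    out_channels = tuple(channels) if channels is not None else scheme.channels
    unknown = [ch for ch in out_channels if ch not in scheme.channels]
    if unknown:
        raise ValidationError(f"channels not in the scheme montage: {unknown}")
    n = int(round(duration * fs))
    key = _seed_tuple(seed)
    canon_idx = {ch: k for k, ch in enumerate(scheme.channels)}
    signals = np.zeros((len(out_channels), n))

    for b, (band, lo, hi) in enumerate(scheme.bands):
        f_c, bw = _band_params(lo, hi)
        pairs = scheme.coupling.get(band, {})
        partner, eps_of = {}, {}
        for (a, c), e in pairs.items():
            partner[a], partner[c] = c, a
            eps_of[a] = eps_of[c] = e
        carriers: dict[int, np.ndarray] = {}
        for row, ch in enumerate(out_channels):
            k = canon_idx[ch]
            if ch in partner:
                # driver keyed by the pair's lower canonical index
                dk = min(k, canon_idx[partner[ch]])
                if dk not in carriers:
                    carriers[dk] = _carrier_phase(_rng(*key, b, 0, dk), n, fs,
                                                  f_c, bw)
                rate = (1.0 - eps_of[ch]) * scheme.phase_diffusion
                jitter = _wiener(_rng(*key, b, 1, k), n, fs, rate)
                signals[row] += np.cos(carriers[dk] + jitter)
            else:
                phi = _carrier_phase(_rng(*key, b, 2, k), n, fs, f_c, bw)
                signals[row] += np.cos(phi)
    if scheme.noise_sd > 0:
        for row, ch in enumerate(out_channels):
            k = canon_idx[ch]
            signals[row] += scheme.noise_sd * _rng(*key, 99, k).standard_normal(n)
    return Recording(subject_id=subject_id, signals=signals, fs=fs,
                     channel_labels=out_channels)


@dataclass
class SyntheticSubject:
    subject_id: str
    ahi: float
    group: str
    recording: Recording
    true_coupling: CouplingScheme


@dataclass
class CohortTable:
    """A generated cohort: subjects plus their programmed ground truth."""

    subjects: list
    scheme: CouplingScheme
    seed: int

    def manifest(self, paths: dict | None = None) -> pd.DataFrame:
        rows = [{"subject_id": s.subject_id,
                 "path": (paths or {}).get(s.subject_id, ""),
                 "ahi": s.ahi, "group": s.group} for s in self.subjects]
        return pd.DataFrame(rows)

    def ground_truth(self) -> dict:
        return {
            "seed": self.seed,
            "ahi_slope": self.scheme.ahi_slope,
            "subjects": [
                {"subject_id": s.subject_id, "ahi": s.ahi, "group": s.group,
                 "epsilon": {band: {f"{a}-{b}": e for (a, b), e in pairs.items()}
                             for band, pairs in s.true_coupling.coupling.items()}}
                for s in self.subjects
            ],
        }

    def to_edf(self, outdir) -> pd.DataFrame:
        """Write per-subject EDFs, manifest.csv and ground_truth.json to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for s in self.subjects:
            p = outdir / f"{s.subject_id}.edf"
            write_edf(p, s.recording.signals, s.recording.fs,
                      s.recording.channel_labels, patient_id=s.subject_id)
            paths[s.subject_id] = str(p)
        manifest = self.manifest(paths)
        manifest.to_csv(outdir / "manifest.csv", index=False)
        (outdir / "ground_truth.json").write_text(
            json.dumps(self.ground_truth(), indent=1))
        return manifest


def _draw_ahi(rng: np.random.Generator, group: str) -> float:
    if group == "control":
        v = rng.lognormal(np.log(_AHI_CONTROL_MEDIAN), _AHI_CONTROL_SIGMA)
        return float(np.clip(v, 0.0, 15.0))
    v = rng.lognormal(np.log(_AHI_MAIN_MEDIAN), _AHI_MAIN_SIGMA)
    return float(np.clip(v, 15.01, _AHI_MAX))


def generate_cohort(n_control: int, n_main: int, scheme: CouplingScheme,
                    seed: int, duration: float = 600.0, fs: float = 100.0,
                    channels=None) -> CohortTable:
    """Generate a cohort with AHI-dependent coupling decline.

    Control subjects come first in the returned table; each subject's
    signals depend only on (seed, subject index), independent of cohort
    size or generation order.
    """
    if n_control < 1 or n_main < 1:
        raise ValidationError("both groups need at least one subject")
    key = _seed_tuple(seed)
    subjects = []
    groups = ["control"] * n_control + ["main"] * n_main
    for idx, group in enumerate(groups):
        ahi = _draw_ahi(_rng(*key, 7, idx), group)
        assert group_from_ahi(ahi) == group
        realized = scheme.for_ahi(ahi, rng=_rng(*key, 9, idx))
        rec = generate_recording(realized, duration, fs,
                                 seed=(*key, 8, idx),
                                 subject_id=f"S{idx:03d}", channels=channels)
        subjects.append(SyntheticSubject(subject_id=f"S{idx:03d}", ahi=ahi,
                                         group=group, recording=rec,
                                         true_coupling=realized))
    return CohortTable(subjects=subjects, scheme=scheme,
                       seed=key[0] if len(key) == 1 else hash(key) & 0x7FFFFFFF)
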
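"""Synthetic running-cycle cohorts with known subject, condition and side structure.

Every angle waveform of a trial is assembled additively from

* a fixed population template (a smooth, cyclic Fourier shape per angle,
  loosely modelled on sagittal running kinematics — no physiological claim),
* a per-subject offset waveform (scale ``sigma_subject``), the stable
  individual movement signature,
* a per-subject x per-condition perturbation (scale ``delta_cond``) for every
  non-reference condition — small, but consistent across that subject's
  trials, which is what makes within-subject condition classification
  possible while across-subject condition classification stays at chance,
* a per-subject side-asymmetry waveform added to the right side only, scaled
  by ``alpha_neutral`` in the reference condition and ``alpha_splint``
  otherwise (splints symmetrize the gait, so ``alpha_neutral`` is the larger
  default), and
* smooth trial-to-trial noise (scale ``sigma_trial``), drawn independently
  per trial and side.

All random components are low-order Fourier series (harmonics 0..n_harmonics
with i.i.d. normal coefficients scaled so the pointwise variance equals the
requested scale squared), so trials are smooth and exactly cyclic like real
time-normalized kinematics; white noise would be unrealistically rough.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, InfeasibleDropError, ParameterError
from .waveform_prep import ANGLES, CONDITIONS, SIDES, TrialRecord, TrialSet

#: (offset deg, amplitude deg, phase rad) of the population template per angle.
#: Amplitudes roughly track sagittal range of motion during running: large for
#: foot/ankle/knee/hip, small for trunk and head segments.
_TEMPLATE_SHAPE: dict[str, tuple[float, float, float]] = {
    "foot": (-10.0, 35.0, 0.4),
    "ankle": (5.0, 25.0, 2.1),
    "knee": (35.0, 40.0, 3.6),
    "hip": (20.0, 22.0, 5.3),
    "pelvis": (10.0, 4.0, 1.0),
    "spine": (-5.0, 4.0, 2.5),
    "thorax": (4.0, 5.0, 4.0),
    "neck": (-8.0, 4.0, 0.7),
    "head": (2.0, 5.0, 5.9),
}


@dataclass(frozen=True)
class SynthConfig:
    """Cohort design and variance scales (all waveform scales in degrees)."""

    n_subjects: int = 20
    n_conditions: int = 4
    n_trials: int = 5
    n_angles: int = 9
    n_time: int = 201
    n_harmonics: int = 4
    sigma_subject: float = 4.0
    delta_cond: float = 1.5
    alpha_neutral: float = 1.5
    alpha_splint: float = 0.5
    sigma_trial: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_conditions": self.n_conditions,
            "n_trials": self.n_trials,
            "n_angles": self.n_angles,
            "n_harmonics": self.n_harmonics,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v!r}")
        if self.n_time < 2:
            raise ConfigurationError(f"n_time must be >= 2, got {self.n_time}")
        if self.n_angles > len(ANGLES):
            raise ConfigurationError(f"n_angles must be <= {len(ANGLES)}")
        scales = {
            "sigma_subject": self.sigma_subject,
            "delta_cond": self.delta_cond,
            "alpha_neutral": self.alpha_neutral,
            "alpha_splint": self.alpha_splint,
            "sigma_trial": self.sigma_trial,
        }
        for name, v in scales.items():
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be a finite scale >= 0, got {v!r}")

    @property
    def conditions(self) -> tuple[str, ...]:
        if self.n_conditions <= len(CONDITIONS):
            return CONDITIONS[: self.n_conditions]
        extra = tuple(f"Cond{i}" for i in range(len(CONDITIONS), self.n_conditions))
        return CONDITIONS + extra

    @property
    def angles(self) -> tuple[str, ...]:
        return ANGLES[: self.n_angles]


@dataclass
class SynthGroundTruth:
    """Noiseless generative components of a cohort, for parameter recovery."""

    config: SynthConfig
    template: np.ndarray  # (n_angles, n_time)
    subject_offsets: np.ndarray  # (S, n_angles, n_time)
    condition_effects: np.ndarray  # (S, C, n_angles, n_time); zero for reference
    asymmetry_shapes: np.ndarray  # (S, n_angles, n_time), unit scale
    asymmetry_magnitude: np.ndarray  # (C,)

    def noiseless_mean(self, subject: int, condition: int, side: str) -> np.ndarray:
        """Expected (noise-free) waveforms of one subject/condition/side."""
        w = (
            self.template
            + self.subject_offsets[subject]
            + self.condition_effects[subject, condition]
        )
        if side == "R":
            w = w + self.asymmetry_magnitude[condition] * self.asymmetry_shapes[subject]
        return w


def _fourier_template(cfg: SynthConfig) -> np.ndarray:
    t = np.linspace(0.0, 1.0, cfg.n_time)
    rows = []
    for a in cfg.angles:
        off, amp, phase = _TEMPLATE_SHAPE[a]
        rows.append(
            off
            + amp * (np.sin(2 * np.pi * t + phase) + 0.35 * np.sin(4 * np.pi * t + 2 * phase))
        )
    return np.asarray(rows)


def _smooth_noise(rng: np.random.Generator, scale: float, shape: tuple[int, ...], cfg: SynthConfig) -> np.ndarray:
    """Random cyclic waveforms with pointwise SD ``scale``.

    Harmonic 0 (a constant offset) plus harmonics 1..n_harmonics, with all
    coefficients i.i.d. N(0, scale^2 / (n_harmonics + 1)); the expected
    variance at every time point is then scale^2.
    """
    H = cfg.n_harmonics
    t = np.linspace(0.0, 1.0, cfg.n_time)
    sd = scale / np.sqrt(H + 1)
    c0 = rng.normal(0.0, sd, shape)[..., None]
    out = np.broadcast_to(c0, shape + (cfg.n_time,)).copy()
    for h in range(1, H + 1):
        # cos^2 + sin^2 = 1, so N(0, sd) cos/sin pairs add sd^2 pointwise variance
        a = rng.normal(0.0, sd, shape)[..., None]
        b = rng.normal(0.0, sd, shape)[..., None]
        out += a * np.cos(2 * np.pi * h * t) + b * np.sin(2 * np.pi * h * t)
    return out


def generate_cohort(config: SynthConfig) -> tuple[TrialSet, SynthGroundTruth]:
    """Draw a full labelled cohort plus its generative ground truth.

    The cohort has ``n_subjects x n_conditions x n_trials x 2 sides`` trials.
    The same config (including seed) always yields a bit-identical cohort.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    S, C, A = cfg.n_subjects, cfg.n_conditions, cfg.n_angles
    template = _fourier_template(cfg)
    subject_offsets = _smooth_noise(rng, cfg.sigma_subject, (S, A), cfg)
    condition_effects = np.zeros((S, C, A, cfg.n_time))
    if C > 1:
        condition_effects[:, 1:] = _smooth_noise(rng, cfg.delta_cond, (S, C - 1, A), cfg)
    asymmetry_shapes = _smooth_noise(rng, 1.0, (S, A), cfg)
    alpha = np.full(C, cfg.alpha_splint)
    alpha[0] = cfg.alpha_neutral
    truth = SynthGroundTruth(
        config=cfg,
        template=template,
        subject_offsets=subject_offsets,
        condition_effects=condition_effects,
        asymmetry_shapes=asymmetry_shapes,
        asymmetry_magnitude=alpha,
    )

    conditions = cfg.conditions
    n_female = int(round(0.25 * S))  # cohort sex mix mirrors a 5F/15M design
    sex = {f"S{s + 1:02d}": ("F" if s < n_female else "M") for s in range(S)}
    records: list[TrialRecord] = []
    speed: dict[tuple, float] = {}
    subject_speed = rng.normal(3.4, 0.25, S)  # recreational running pace, m/s
    for s in range(S):
        sid = f"S{s + 1:02d}"
        for c in range(C):
            for tr in range(1, cfg.n_trials + 1):
                for side in SIDES:
                    mean = truth.noiseless_mean(s, c, side)
                    noise = _smooth_noise(rng, cfg.sigma_trial, (A,), cfg)
                    angle_map = {a: mean[i] + noise[i] for i, a in enumerate(cfg.angles)}
                    if A < len(ANGLES):
                        # reduced-n_angles configs pad the remaining blocks with
                        # faint noise so block standardization stays defined
                        pad = _smooth_noise(rng, 1e-3, (len(ANGLES) - A,), cfg)
                        for k, a in enumerate(ANGLES[A:]):
                            angle_map[a] = pad[k]
                    rec = TrialRecord(
                        subject=sid,
                        condition=conditions[c],
                        side=side,
                        trial=tr,
                        angles=angle_map,
                    )
                    records.append(rec)
                    speed[rec.key] = float(
                        np.clip(subject_speed[s] + rng.normal(0.0, 0.05), 2.0, 6.0)
                    )
    trials = TrialSet(records, sex=sex, speed=speed, source="synthetic", seed=cfg.seed)
    return trials, truth


def drop_trials(trials: TrialSet, fraction: float, seed: int) -> TrialSet:
    """Remove a uniformly random subset while keeping every cell populated.

    ``fraction`` of the trials are removed, but at least one trial per
    subject x condition x side cell is always retained (one random trial per
    cell is protected, the remainder of the keep-quota is drawn uniformly).
    """
    if not 0 <= fraction < 1:
        raise ParameterError(f"fraction must be in [0, 1), got {fraction}")
    n = len(trials)
    if fraction == 0:
        return trials.subset(lambda t: True)
    keep = int(round(n * (1 - fraction)))
    cells: dict[tuple, list[int]] = {}
    for i, t in enumerate(trials):
        cells.setdefault((t.subject, t.condition, t.side), []).append(i)
    if keep < len(cells):
        raise InfeasibleDropError(
            f"keeping {keep} of {n} trials cannot cover all {len(cells)} "
            "subject x condition x side cells"
        )
    rng = np.random.default_rng(seed)
    protected = {idx[rng.integers(len(idx))] for idx in cells.values()}
    pool = np.array(sorted(set(range(n)) - protected))
    extra = keep - len(protected)
    chosen = set(rng.choice(pool, size=extra, replace=False)) if extra else set()
    kept_idx = sorted(protected | chosen)
    kept_keys = {trials.trials[i].key for i in kept_idx}
    return trials.subset(lambda t: t.key in kept_keys)
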
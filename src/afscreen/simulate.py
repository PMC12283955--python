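"""Synthetic fixtures: labeled R-R interval vectors and toy ECG traces.

The generator encodes the single physiological contrast the classifier relies
on: in atrial fibrillation the ventricular response is irregular, so the
distribution of R-R intervals is more spread (higher coefficient of
variation) than in sinus rhythm.  AF irregularity is modeled as i.i.d.
high-CV intervals — sufficient because the classifier sees only the interval
distribution — with lognormal intervals by default (positive, right-skewed)
and gamma as an alternative law for sensitivity checks.

A "hard" variant adds sinus-arrhythmia-like sinusoidal modulation (moderate
CV, serially correlated intervals) to mimic conditions that genuinely overlap
AF in dispersion, for tests that must not achieve perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import RRiVector, normalize
from .io import LabeledDataset, Recording

#: AF prevalence of a screening population: 383 AF / (383 + 6745) non-AF.
SCREENING_PREVALENCE = 383 / (383 + 6745)


@dataclass(frozen=True)
class ClassModel:
    """Interval-generating law for one rhythm class.

    ``cv`` (standard deviation / mean of the raw intervals) is the
    irregularity knob; shipped presets always give the AF class the larger cv.
    """

    label: int
    mean_rr: float = 0.8
    cv: float = 0.1
    interval_law: str = "lognormal"
    length_range: tuple = (20, 60)

    def __post_init__(self) -> None:
        if self.label not in (-1, +1):
            raise ValueError("label must be +1 (AF) or -1 (noAF)")
        if not self.mean_rr > 0:
            raise ValueError(f"mean_rr must be > 0, got {self.mean_rr}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if self.interval_law not in ("lognormal", "gamma"):
            raise ValueError(f"interval_law must be 'lognormal' or 'gamma', "
                             f"got {self.interval_law!r}")
        d_min, d_max = self.length_range
        if not (1 <= d_min <= d_max):
            raise ValueError(f"invalid length_range {self.length_range}")


def _draw_intervals(rng: np.random.Generator, model: ClassModel, d: int) -> np.ndarray:
    if model.cv == 0:
        return np.full(d, model.mean_rr)
    if model.interval_law == "lognormal":
        # moment-match: CV^2 = exp(s^2) - 1, mean = exp(m + s^2/2)
        s2 = np.log1p(model.cv ** 2)
        m = np.log(model.mean_rr) - s2 / 2
        return rng.lognormal(mean=m, sigma=np.sqrt(s2), size=d)
    shape = 1.0 / model.cv ** 2
    return rng.gamma(shape=shape, scale=model.mean_rr / shape, size=d)


def gen_rri(model: ClassModel, n_patients: int, seed: int,
            id_prefix: str | None = None, raw_label: str | None = None) -> list:
    """Draw ``n_patients`` labeled RRi vectors from a class model.

    Per patient: a length d uniform in ``length_range``, then d i.i.d.
    intervals from the law, then mean-1 normalization (through the real
    :func:`afscreen.features.normalize`, not a copy).  Deterministic for a
    fixed seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    raw = raw_label if raw_label is not None else ("AF" if model.label == 1 else "noAF")
    if id_prefix is None:
        id_prefix = f"{raw.lower()}-s{seed}"  # avoids id collisions between calls
    out = []
    d_min, d_max = model.length_range
    for i in range(n_patients):
        d = int(rng.integers(d_min, d_max + 1))
        delta = _draw_intervals(rng, model, d)
        out.append(normalize(delta, patient_id=f"{id_prefix}-{i:05d}",
                             binary_label=model.label, raw_label=raw))
    return out


def gen_modulated_rri(model: ClassModel, n_patients: int, seed: int,
                      mod_amplitude: float = 0.15, mod_period: float = 8.0,
                      id_prefix: str = "sa", raw_label: str = "SA") -> list:
    """Serially correlated vectors with sinusoidal (respiratory-like) modulation.

    Interval i is ``mean_rr * (1 + a sin(2 pi i / period + phase))`` times the
    model's i.i.d. noise — a sinus-arrhythmia surrogate whose dispersion can
    approach AF levels while remaining structured.
    """
    rng = np.random.default_rng(seed)
    d_min, d_max = model.length_range
    out = []
    for i in range(n_patients):
        d = int(rng.integers(d_min, d_max + 1))
        phase = rng.uniform(0, 2 * np.pi)
        carrier = 1.0 + mod_amplitude * np.sin(2 * np.pi * np.arange(d) / mod_period + phase)
        delta = _draw_intervals(rng, model, d) * carrier
        out.append(normalize(delta, patient_id=f"{id_prefix}-{i:05d}",
                             binary_label=model.label, raw_label=raw_label))
    return out


#: Shipped class-model presets. "easy" mirrors well-separated study conditions;
#: "hard" mixes in modulated sinus arrhythmia that overlaps AF in dispersion.
PRESETS = {
    "easy": {"noaf": ClassModel(label=-1, cv=0.05), "af": ClassModel(label=+1, cv=0.30)},
    "hard": {"noaf": ClassModel(label=-1, cv=0.05), "af": ClassModel(label=+1, cv=0.30),
             "sa": ClassModel(label=-1, cv=0.15)},
}


def gen_dataset(noaf_model: ClassModel, af_model: ClassModel,
                n_noaf: int, n_af: int, seed: int) -> LabeledDataset:
    """Merged, seeded-shuffled dataset with exact class counts."""
    if n_noaf < 1 or n_af < 1:
        raise ValueError("both class counts must be >= 1")
    items = (gen_rri(noaf_model, n_noaf, seed=seed, id_prefix="noaf")
             + gen_rri(af_model, n_af, seed=seed + 1, id_prefix="af"))
    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(len(items))
    return LabeledDataset(items=[items[i] for i in order],
                          label_map={"AF": +1, "noAF": -1})


def gen_preset_dataset(name: str, n_total: int, seed: int) -> LabeledDataset:
    """Dataset from a named preset.

    ``"paper-prevalence"`` uses the easy models at the screening prevalence
    (rounded count of positives); ``"hard"`` substitutes a third of the noAF
    class with modulated sinus-arrhythmia vectors.
    """
    if name == "paper-prevalence":
        n_af = int(round(n_total * SCREENING_PREVALENCE))
        n_af = max(n_af, 1)
        models = PRESETS["easy"]
        return gen_dataset(models["noaf"], models["af"], n_total - n_af, n_af, seed)
    if name == "easy":
        models = PRESETS["easy"]
        return gen_dataset(models["noaf"], models["af"],
                           n_total - n_total // 2, n_total // 2, seed)
    if name == "hard":
        models = PRESETS["hard"]
        n_af = n_total // 2
        n_sa = (n_total - n_af) // 3
        n_noaf = n_total - n_af - n_sa
        items = (gen_rri(models["noaf"], n_noaf, seed=seed, id_prefix="noaf")
                 + gen_rri(models["af"], n_af, seed=seed + 1, id_prefix="af")
                 + gen_modulated_rri(models["sa"], n_sa, seed=seed + 2))
        rng = np.random.default_rng(seed + 3)
        order = rng.permutation(len(items))
        return LabeledDataset(items=[items[i] for i in order],
                              label_map={"AF": +1, "noAF": -1, "SA": -1})
    raise ValueError(f"unknown preset {name!r}; choose from "
                     f"{sorted(PRESETS) + ['paper-prevalence']}")


def gen_ecg_trace(peak_times, fs: float, qrs_width: float = 0.02,
                  noise_sd: float = 0.0, seed: int = 0,
                  duration: float | None = None, rec_id: str = "trace",
                  raw_label: str = "") -> tuple:
    """Toy ECG: a Gaussian bump of width ``qrs_width`` at each peak time plus
    seeded white noise.  Returns ``(Recording, ground_truth_indices)``.

    Exists solely to exercise peak detection end-to-end with known truth;
    no P/T-wave morphology is attempted.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size and np.any(np.diff(peak_times) <= 0):
        raise ValueError("peak_times must be strictly increasing")
    if not fs > 0:
        raise ValueError("fs must be > 0")
    if duration is None:
        duration = (peak_times[-1] + 0.5) if peak_times.size else 1.0
    n = max(int(round(duration * fs)), 1)
    t = np.arange(n) / fs
    trace = np.zeros(n)
    for pt in peak_times:
        trace += np.exp(-((t - pt) ** 2) / (2 * qrs_width ** 2))
    if noise_sd > 0:
        trace += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    truth = np.round(peak_times * fs).astype(np.int64)
    rec = Recording(id=rec_id, samples=trace, fs=fs, raw_label=raw_label,
                    source="synthetic")
    return rec, truth
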
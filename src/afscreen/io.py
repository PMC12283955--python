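"""Reading ECG recordings and labels, collapsing rhythm labels to the binary
AF/noAF screening task, and reproducible stratified splitting.

Recordings arrive either as WFDB header/signal pairs (the format PhysioNet
distributes single-lead ECG corpora in) or as plain CSV tables.  A minimal
WFDB reader/writer for the common format-16 encoding is included so that no
binary fixtures are ever needed.  Extracted R-R interval vectors round-trip
through a simple CSV dialect so the kernel and SVM stages can run without the
raw signals.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import FormatError, LabelError

logger = logging.getLogger(__name__)

#: Sentinel value in a label map meaning "drop this item, but count it".
DISCARD = "DISCARD"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """One patient's raw single-lead ECG trace.

    Parameters
    ----------
    id : str
        Unique identifier within its dataset.
    samples : ndarray of float
        Amplitude values in arbitrary units; non-empty.
    fs : float
        Sampling frequency in Hz, strictly positive.
    raw_label : str
        Rhythm label in the source vocabulary (e.g. ``"AF"``, ``"Normal"``).
    source : str
        Corpus tag, e.g. ``"cinc"``, ``"sph"``, ``"synthetic"``.
    """

    id: str
    samples: np.ndarray
    fs: float
    raw_label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise FormatError(f"recording {self.id!r}: samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise FormatError(f"recording {self.id!r}: sampling frequency must be > 0, got {self.fs}")


@dataclass
class LabeledDataset:
    """A collection of recordings or RRi vectors with a raw-label -> {+1, -1, DISCARD} map.

    ``discarded`` records every item removed by label collapsing or filtering,
    so counts are always conserved:  ``len(items) + len(discarded)`` equals the
    original input size.
    """

    items: list
    label_map: dict = field(default_factory=dict)
    discarded: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def binary_label(self, item) -> int:
        """Binary label (+1 AF / -1 noAF) of ``item`` under ``label_map``."""
        attached = getattr(item, "binary_label", None)
        if attached in (+1, -1):
            return attached
        raw = getattr(item, "raw_label", None)
        if raw in self.label_map and self.label_map[raw] in (+1, -1):
            return self.label_map[raw]
        raise LabelError(f"no binary label for item {getattr(item, 'id', item)!r} (raw={raw!r})")

    @property
    def binary_labels(self) -> np.ndarray:
        return np.array([self.binary_label(it) for it in self.items], dtype=int)

    @property
    def raw_labels(self) -> list:
        return [getattr(it, "raw_label", "") for it in self.items]


@dataclass(frozen=True)
class SplitSpec:
    """Fractions, seed and stratification key for a train/validation/test split."""

    fractions: tuple = (0.6, 0.2, 0.2)
    seed: int = 0
    stratify_on: str = "raw_label"

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(not (0.0 < f < 1.0) for f in self.fractions):
            raise ValueError(f"each fraction must lie in (0, 1): {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1: {self.fractions}")
        if self.stratify_on not in ("raw_label", "binary_label"):
            raise ValueError("stratify_on must be 'raw_label' or 'binary_label'")


# ---------------------------------------------------------------------------
# Minimal WFDB support (header + format-16 signal files)
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{hea_path}: empty WFDB header")
    rec = lines[0].split()
    if len(rec) < 3:
        raise FormatError(f"{hea_path}: malformed WFDB record line {lines[0]!r}")
    name, n_sig = rec[0], int(rec[1])
    fs = float(rec[2].split("/")[0])
    n_samples = int(rec[3]) if len(rec) > 3 else None
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"{hea_path}: malformed signal line {ln!r}")
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, 0
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        signals.append({"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline})
    return name, n_sig, fs, n_samples, signals


def read_wfdb_record(path, label_table: dict | None = None,
                     channel: int = 0, source: str = "") -> Recording:
    """Read a WFDB record (``.hea`` + format-16 ``.dat``) as a :class:`Recording`.

    Only the requested channel (default: first) is returned, matching the
    single-lead analysis.  A multi-channel record triggers a logged warning.
    If ``label_table`` is omitted and a ``REFERENCE.csv`` (id,label) sits next
    to the record, the raw label is taken from there.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"{hea}: WFDB header not found")
    name, n_sig, fs, n_samples, signals = _parse_header(hea)
    if n_sig < 1:
        raise FormatError(f"{hea}: record declares no signals")
    if not 0 <= channel < n_sig:
        raise FormatError(f"{hea}: channel {channel} out of range (record has {n_sig})")
    if n_sig > 1:
        logger.warning("record %s has %d channels; using channel %d only", name, n_sig, channel)

    sig = signals[channel]
    if sig["fmt"] != "16":
        raise FormatError(f"{hea}: unsupported WFDB signal format {sig['fmt']!r} (only 16)")
    dat = hea.parent / sig["file"]
    if not dat.exists():
        raise FormatError(f"{dat}: WFDB signal file not found")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    # format 16 interleaves channels sample by sample
    n_in_file = len(signals)  # channels sharing this .dat (common layout: all)
    same_file = [i for i, s in enumerate(signals) if s["file"] == sig["file"]]
    n_in_file = len(same_file)
    if raw.size == 0 or raw.size % n_in_file:
        raise FormatError(f"{dat}: signal file empty or truncated")
    mat = raw.reshape(-1, n_in_file)
    col = same_file.index(channel)
    adc = mat[:, col].astype(float)
    if n_samples is not None:
        if len(adc) < n_samples:
            raise FormatError(f"{dat}: expected {n_samples} samples, found {len(adc)}")
        adc = adc[:n_samples]
    if adc.size == 0:
        raise FormatError(f"{dat}: record contains 0 samples")
    physical = (adc - sig["baseline"]) / sig["gain"]

    raw_label = ""
    if label_table is None:
        ref = hea.parent / "REFERENCE.csv"
        if ref.exists():
            tbl = pd.read_csv(ref, header=None, names=["id", "label"], dtype=str)
            label_table = dict(zip(tbl["id"], tbl["label"]))
    if label_table:
        raw_label = label_table.get(name, "")
    return Recording(id=name, samples=physical, fs=fs, raw_label=raw_label, source=source)


def write_wfdb_record(path, samples, fs: float, gain: float = 200.0) -> None:
    """Write ``samples`` (1-D, or 2-D ``(n, channels)``) as a format-16 WFDB record."""
    path = Path(path)
    arr = np.atleast_2d(np.asarray(samples, dtype=float))
    if arr.shape[0] == 1 and np.asarray(samples).ndim == 1:
        arr = arr.T
    n, n_sig = arr.shape
    adc = np.clip(np.round(arr * gain), -32768, 32767).astype("<i2")
    path.with_suffix(".dat").write_bytes(adc.reshape(-1).tobytes())
    lines = [f"{path.stem} {n_sig} {fs:g} {n}"]
    for _ in range(n_sig):
        lines.append(f"{path.stem}.dat 16 {gain:g}(0)/mV 16 0 0 0 0")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def read_csv_recordings(path, fs: float, source: str = "") -> list:
    """Read recordings from CSV.

    Two layouts are accepted: wide (columns ``id,label,samples`` with the
    amplitudes joined by ``;`` or whitespace inside the ``samples`` cell) and
    long (columns ``id,label,sample``, one row per sample, order preserved).
    """
    df = pd.read_csv(path, dtype={"id": str})
    cols = set(df.columns)
    if df.empty:
        warnings.warn(f"{path}: empty recordings CSV")
        return []
    recordings = []
    if {"id", "label", "samples"} <= cols:
        for _, row in df.iterrows():
            vals = np.array(str(row["samples"]).replace(";", " ").split(), dtype=float)
            recordings.append(Recording(id=str(row["id"]), samples=vals, fs=fs,
                                        raw_label=str(row["label"]), source=source))
    elif {"id", "label", "sample"} <= cols:
        for rid, grp in df.groupby("id", sort=False):
            recordings.append(Recording(id=str(rid), samples=grp["sample"].to_numpy(float),
                                        fs=fs, raw_label=str(grp["label"].iloc[0]),
                                        source=source))
    else:
        missing = {"id", "label", "samples (or sample)"} - cols
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return recordings


def write_rri_csv(path, vectors: Iterable) -> None:
    """Persist extracted RRi vectors as CSV (patient_id, raw_label, binary_label, values)."""
    rows = []
    for v in vectors:
        rows.append({
            "patient_id": v.patient_id,
            "raw_label": v.raw_label,
            "binary_label": "" if v.binary_label is None else v.binary_label,
            "values": ";".join(repr(float(x)) for x in v.values),
        })
    pd.DataFrame(rows, columns=["patient_id", "raw_label", "binary_label", "values"]).to_csv(
        path, index=False)


def read_rri_csv(path) -> list:
    """Load RRi vectors written by :func:`write_rri_csv`."""
    from .features import RRiVector  # local import avoids a cycle

    df = pd.read_csv(path, dtype={"patient_id": str, "raw_label": str})
    required = {"patient_id", "raw_label", "binary_label", "values"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    out = []
    for _, row in df.iterrows():
        lab = row["binary_label"]
        lab = None if pd.isna(lab) or lab == "" else int(lab)
        vals = np.array(str(row["values"]).split(";"), dtype=float)
        raw = "" if pd.isna(row["raw_label"]) else str(row["raw_label"])
        out.append(RRiVector(values=vals, patient_id=str(row["patient_id"]),
                             binary_label=lab, raw_label=raw))
    return out


# ---------------------------------------------------------------------------
# Label collapsing
# ---------------------------------------------------------------------------

# CinC distributes single-letter codes; accept both vocabularies.
_CINC_ALIASES = {"N": "Normal", "O": "Other", "A": "AF", "~": "Noisy",
                 "Other rhythm": "Other"}
_CINC_MAP = {"Normal": -1, "Other": -1, "AF": +1, "Noisy": DISCARD}
# SPH: AF denotes atrial fibrillation here (the corpus' own "AF" acronym means
# atrial flutter, renamed AFlut); every other rhythm label is noAF by design.
_SPH_POSITIVE = {"AF", "AFIB"}
_DIAGNOSTICK_MAP = {"AF": +1, "noAF": -1, "Unknown": DISCARD}

SCHEMES = ("cinc", "sph", "diagnostick", "passthrough")


def _collapse_one(raw: str, scheme: str):
    if scheme == "cinc":
        canon = _CINC_ALIASES.get(raw, raw)
        if canon not in _CINC_MAP:
            raise LabelError(f"unmapped CinC label {raw!r}")
        return _CINC_MAP[canon]
    if scheme == "sph":
        return +1 if raw in _SPH_POSITIVE else -1
    if scheme == "diagnostick":
        if raw not in _DIAGNOSTICK_MAP:
            raise LabelError(f"unmapped DiagnoStick label {raw!r}")
        return _DIAGNOSTICK_MAP[raw]
    if scheme == "passthrough":
        try:
            val = int(float(raw))
        except (TypeError, ValueError):
            val = None
        if val not in (+1, -1):
            raise LabelError(f"passthrough scheme requires labels +1/-1, got {raw!r}")
        return val
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def collapse_labels(dataset: LabeledDataset, scheme: str) -> LabeledDataset:
    """Collapse raw rhythm labels to the binary AF (+1) / noAF (-1) task.

    Items whose label maps to :data:`DISCARD` are moved to ``discarded`` (never
    silently dropped); the original ``raw_label`` is retained on every item for
    confusion-by-original-label reporting.  An unmapped label raises
    :class:`LabelError`.
    """
    retained, discarded, label_map = [], list(dataset.discarded), {}
    for item in dataset.items:
        raw = getattr(item, "raw_label", "")
        mapped = _collapse_one(raw, scheme)
        label_map[raw] = mapped
        if mapped == DISCARD:
            discarded.append({"id": getattr(item, "id", getattr(item, "patient_id", "?")),
                              "raw_label": raw, "reason": f"label discarded by scheme {scheme}"})
            continue
        item.binary_label = mapped  # Recording gains the attribute dynamically
        retained.append(item)
    if discarded:
        logger.info("collapse_labels(%s): discarded %d of %d items",
                    scheme, len(discarded) - len(dataset.discarded), len(dataset.items))
    return LabeledDataset(items=retained, label_map=label_map, discarded=discarded)


def write_discard_report(path, dataset: LabeledDataset) -> None:
    """Write the discarded-item sidecar report (id, raw_label, reason) as CSV."""
    pd.DataFrame(dataset.discarded, columns=["id", "raw_label", "reason"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: Sequence[float]) -> list:
    """Integer allocation of ``n`` items over splits: floors plus largest remainders,
    ties resolved toward the earlier split."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def stratified_split(dataset: LabeledDataset, spec: SplitSpec):
    """Deterministic stratified train/validation/test split.

    Within every stratum the items are shuffled with a seed-derived generator
    and allocated by largest-remainder rounding, so per-stratum proportions are
    honored up to integer rounding.  Strata are processed in sorted name order,
    making the result identical across runs and platforms.
    """
    key = (lambda it: getattr(it, "raw_label", "")) if spec.stratify_on == "raw_label" \
        else (lambda it: dataset.binary_label(it))
    strata: dict = {}
    for item in dataset.items:
        strata.setdefault(str(key(item)), []).append(item)

    rng = np.random.default_rng(spec.seed)
    parts = ([], [], [])
    for name in sorted(strata):
        members = strata[name]
        if len(members) < 3:
            raise ValueError(f"stratum {name!r} has {len(members)} item(s); "
                             f"need at least 3 to populate train/validation/test")
        perm = rng.permutation(len(members))
        counts = _largest_remainder(len(members), spec.fractions)
        start = 0
        for part, c in zip(parts, counts):
            part.extend(members[i] for i in perm[start:start + c])
            start += c
    return tuple(LabeledDataset(items=list(p), label_map=dict(dataset.label_map))
                 for p in parts)


def write_split_assignments(path, splits, names=("train", "validation", "test")) -> None:
    """Persist split membership as CSV (id, split) for exact reproducibility."""
    rows = [{"id": getattr(it, "id", getattr(it, "patient_id", "?")), "split": nm}
            for nm, ds in zip(names, splits) for it in ds.items]
    pd.DataFrame(rows, columns=["id", "split"]).to_csv(path, index=False)
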
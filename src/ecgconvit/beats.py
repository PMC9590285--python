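"""Beat extraction, AAMI label mapping and dataset splitting.

An ECG record arrives as a sampled voltage trace (nominally 360 Hz) plus an
annotation stream marking each R peak with a beat-type symbol.  This module
maps the symbols onto the five AAMI heartbeat classes, cuts a fixed
300-sample window centred on each annotated R peak, and produces the
train/validation/test partition used by the classifier (a random 8:2 split
into train+val vs test, then the same 8:2 split of the pool into train vs
val).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import wfdbio

WINDOW_LENGTH = 300
R_OFFSET = 150  # R peak sits at this in-window index (150 before, 150 after)
EXPECTED_FS = 360.0

#: MIT-BIH annotation symbol -> AAMI class.
AAMI_MAP = {
    "F": "F",
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "/": "Q", "f": "Q", "U": "Q",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
}


class UnmappedSymbolError(KeyError):
    """Annotation symbol has no AAMI class (non-beat or unsupported type)."""


class BeatFormatError(ValueError):
    """A beat file did not parse under the requested dialect."""


@dataclass
class AnnotatedRecord:
    """A single-channel ECG trace with (sample_index, symbol) annotations."""

    samples: np.ndarray
    fs: float
    annotations: list[tuple[int, str]]

    def validate(self) -> None:
        n = len(self.samples)
        prev = -1
        for idx, sym in self.annotations:
            if not 0 <= idx < n:
                raise ValueError(f"annotation index {idx} outside [0, {n})")
            if idx <= prev:
                raise ValueError("annotation indices must be strictly increasing")
            if len(sym) != 1:
                raise ValueError(f"annotation symbol must be one character, got {sym!r}")
            prev = idx


@dataclass
class BeatWindow:
    samples: np.ndarray  # exactly 300 amplitudes
    label: str           # AAMI class
    source_symbol: str   # original annotation character
    r_index: int = R_OFFSET

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (WINDOW_LENGTH,):
            raise ValueError(f"beat window must have {WINDOW_LENGTH} samples, "
                             f"got shape {self.samples.shape}")
        if self.label not in set(AAMI_MAP.values()):
            raise ValueError(f"label {self.label!r} is not an AAMI class")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train/val/test index sets (seed-deterministic)."""

    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train": self.train_ids.tolist(), "val": self.val_ids.tolist(),
            "test": self.test_ids.tolist(), "seed": self.seed}))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["train"], dtype=int), np.array(d["val"], dtype=int),
                   np.array(d["test"], dtype=int), d["seed"])


def map_to_aami(symbol: str) -> str:
    """Map one MIT-BIH annotation symbol to its AAMI class.

    Raises :class:`UnmappedSymbolError` for symbols outside the 15-entry
    beat-type table (rhythm changes, noise markers, ...).
    """
    if len(symbol) != 1:
        raise ValueError(f"expected a single character, got {symbol!r}")
    try:
        return AAMI_MAP[symbol]
    except KeyError:
        raise UnmappedSymbolError(symbol) from None


def extract_windows(record: AnnotatedRecord) -> tuple[list[BeatWindow], int]:
    """Cut one 300-sample window per mappable annotation.

    The window is ``[r - 150, r + 150)`` so the R peak sits at in-window
    index 150.  Annotations whose window would cross a record edge are
    skipped (not padded); the second return value counts them.  Non-beat
    symbols are ignored silently.
    """
    record.validate()
    if record.fs != EXPECTED_FS:
        warnings.warn(f"record sampling rate {record.fs} Hz differs from the "
                      f"expected {EXPECTED_FS:g} Hz; windows are cut in raw samples",
                      stacklevel=2)
    x = np.asarray(record.samples, dtype=float)
    windows: list[BeatWindow] = []
    skipped = 0
    for idx, sym in record.annotations:
        try:
            label = map_to_aami(sym)
        except UnmappedSymbolError:
            continue
        start = idx - R_OFFSET
        stop = start + WINDOW_LENGTH
        if start < 0 or stop > len(x):
            skipped += 1
            continue
        windows.append(BeatWindow(x[start:stop].copy(), label, sym))
    return windows, skipped


def split_dataset(n: int, seed: int) -> DatasetSplit:
    """Random 8:2 split into (train+val) vs test, then 8:2 of the pool.

    ``test = floor(0.2 n)``, ``val = floor(0.2 (n - test))``, train the rest;
    e.g. n=100 gives 64/16/20.  No stratification; deterministic per seed.
    """
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(np.floor(0.2 * n))
    n_val = int(np.floor(0.2 * (n - n_test)))
    test = perm[n - n_test:]
    val = perm[n - n_test - n_val: n - n_test]
    train = perm[: n - n_test - n_val]
    return DatasetSplit(np.sort(train), np.sort(val), np.sort(test), seed)


def windows_to_arrays(windows: list[BeatWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack BeatWindows into an (n, 300) matrix and a label vector."""
    if not windows:
        return np.empty((0, WINDOW_LENGTH)), np.array([], dtype=object)
    X = np.vstack([w.samples for w in windows])
    y = np.array([w.label for w in windows], dtype=object)
    return X, y


def write_csv_beats(path: str | Path, X: np.ndarray, y: np.ndarray,
                    synthetic: np.ndarray | None = None) -> None:
    """Write beats in the csv_beats dialect: columns ``s0..s299,symbol[,synthetic]``."""
    df = pd.DataFrame(np.asarray(X, dtype=float),
                      columns=[f"s{i}" for i in range(WINDOW_LENGTH)])
    df["symbol"] = np.asarray(y, dtype=object)
    if synthetic is not None:
        df["synthetic"] = np.asarray(synthetic).astype(int)
    df.to_csv(path, index=False)


def read_csv_beats(path: str | Path) -> list[BeatWindow]:
    """Read pre-cut beats from the csv_beats dialect."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise BeatFormatError(f"{path}: {exc}") from exc
    cols = [f"s{i}" for i in range(WINDOW_LENGTH)]
    missing = [c for c in cols if c not in df.columns]
    if missing or "symbol" not in df.columns:
        raise BeatFormatError(f"{path}: missing columns "
                              f"{missing[:3] + ([] if 'symbol' in df.columns else ['symbol'])}"
                              f" (expected s0..s{WINDOW_LENGTH - 1},symbol)")
    windows = []
    for i, row in df.iterrows():
        try:
            vals = row[cols].to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise BeatFormatError(f"{path}: row {i}: {exc}") from exc
        if np.isnan(vals).any():
            raise BeatFormatError(f"{path}: row {i} has missing sample values")
        sym = str(row["symbol"])
        label = sym if sym in set(AAMI_MAP.values()) else map_to_aami(sym)
        windows.append(BeatWindow(vals, label, sym))
    return windows


def read_record(path: str | Path, dialect: str = "wfdb"):
    """Load ECG data under the named dialect.

    ``wfdb`` expects a .hea path (or bare record name) and returns an
    :class:`AnnotatedRecord` built from the first signal channel plus the
    .atr annotation stream; ``csv_beats`` returns a list of pre-cut
    :class:`BeatWindow` objects.
    """
    path = Path(path)
    if dialect == "csv_beats":
        return read_csv_beats(path)
    if dialect != "wfdb":
        raise ValueError(f"unknown dialect {dialect!r}")
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    header = wfdbio.read_header(hea)
    signal = wfdbio.read_signal(hea.with_suffix(".dat"), header)
    atr = hea.with_suffix(".atr")
    annotations = wfdbio.read_annotations(atr) if atr.exists() else []
    record = AnnotatedRecord(signal[:, 0], header["fs"], annotations)
    if record.fs != EXPECTED_FS:
        warnings.warn(f"{hea.name}: sampling rate {record.fs} Hz differs from "
                      f"the expected {EXPECTED_FS:g} Hz", stacklevel=2)
    return record
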
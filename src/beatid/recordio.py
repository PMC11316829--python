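"""Record and dataset I/O.

Reads single-segment WFDB records (.hea text header, .dat signal in
formats 16 or 212, .atr beat annotations in the MIT annotation byte
format) into physical units, restricts annotation symbols to the beat
taxonomy used throughout the package, and serializes beat/image datasets
to a single HDF5 container with a canonical-JSON provenance hash.

The WFDB reader is deliberately minimal: it covers the layout used by the
MIT-BIH Arrhythmia Database (one or two leads, formats 212/16, one
annotator) and refuses anything it cannot parse rather than guessing.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from .synth import SUPPORTED_SYMBOLS, SynthRecord

__all__ = [
    "ECGRecord",
    "LabelCensus",
    "read_record",
    "map_labels",
    "BeatDataset",
    "save_dataset",
    "load_dataset",
    "write_annotation_text",
    "config_hash",
]

DATASET_VERSION = 1

# WFDB annotation code -> symbol (beat codes and common non-beat codes).
ANNOTATION_CODES = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}


@dataclass
class ECGRecord:
    """A subject's sampled signal with beat annotations."""

    subject_id: str
    signal: np.ndarray  # (n_samples, n_leads), mV
    fs: float
    ann_samples: np.ndarray  # sorted sample indices
    ann_symbols: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.signal.shape[0]
        if self.ann_samples.size and (
            self.ann_samples.min() < 0 or self.ann_samples.max() >= n
        ):
            raise ValueError("annotation sample index outside the record")

    def lead(self, index: int = 0) -> np.ndarray:
        return self.signal[:, index]

    @classmethod
    def from_synth(cls, rec: SynthRecord) -> "ECGRecord":
        return cls(
            subject_id=rec.subject_id,
            signal=rec.signal[:, None],
            fs=rec.fs,
            ann_samples=rec.ann_samples.copy(),
            ann_symbols=rec.ann_symbols.copy(),
        )


# ---------------------------------------------------------------------------
# WFDB reading


def _parse_header(hea_path: str) -> tuple[str, int, float, int, list[dict]]:
    with open(hea_path) as fh:
        lines = [
            ln.strip()
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    first = lines[0].split()
    name = first[0].split("/")[0]
    nsig = int(first[1])
    fs = float(first[2]) if len(first) > 2 else 250.0
    nsamp = int(first[3]) if len(first) > 3 else 0
    sigs = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        fmt_field = parts[1]
        fmt = int(fmt_field.split("x")[0].split(":")[0].split("+")[0])
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain = float(gain_part[: gain_part.index("(")])
            baseline = int(gain_part[gain_part.index("(") + 1 : gain_part.index(")")])
        else:
            gain = float(gain_part)
            baseline = int(parts[4]) if len(parts) > 4 else 0  # adczero
        if gain == 0:
            gain = 200.0
        sigs.append(
            {"file": parts[0], "format": fmt, "gain": gain, "baseline": baseline}
        )
    return name, nsig, fs, nsamp, sigs


def _read_dat(path: str, fmt: int, nsig: int, nsamp: int) -> np.ndarray:
    with open(path, "rb") as fh:
        raw = fh.read()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
        total = (adc.size // nsig) * nsig
        adc = adc[:total].reshape(-1, nsig)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        n_triplets = b.size // 3
        b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(n_triplets * 2, dtype=np.int32)
        flat[0::2] = first
        flat[1::2] = second
        total = (flat.size // nsig) * nsig
        adc = flat[:total].reshape(-1, nsig)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt} in {path}")
    if nsamp:
        adc = adc[:nsamp]
    return adc


def _read_atr(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse the MIT annotation byte format; returns (samples, symbols)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    words = np.frombuffer(raw, dtype="<u2")
    samples, symbols = [], []
    t = 0
    i = 0
    while i < words.size:
        word = int(words[i])
        code, delta = word >> 10, word & 0x3FF
        i += 1
        if code == 0 and delta == 0:  # EOF
            break
        if code == 59:  # SKIP: 4-byte interval, high word first
            if i + 1 >= words.size:
                raise ValueError(f"truncated SKIP in annotation file {path}")
            t += (int(words[i]) << 16) | int(words[i + 1])
            i += 2
        elif code == 63:  # AUX: delta = byte count, padded to even
            i += (delta + 1) // 2
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        else:
            t += delta
            samples.append(t)
            symbols.append(ANNOTATION_CODES.get(code, "?"))
    return np.asarray(samples, dtype=np.int64), np.asarray(symbols, dtype="<U1")


def read_record(path: str, annotator: str = "atr") -> ECGRecord:
    """Read a WFDB record given its path without extension (or its .hea).

    The signal is returned in physical units (mV for ECG leads) and
    annotations sorted by sample index.
    """
    base = path[:-4] if path.endswith(".hea") else path
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"missing header file: {hea}")
    name, nsig, fs, nsamp, sigs = _parse_header(hea)
    dat_files = {s["file"] for s in sigs}
    if len(dat_files) != 1:
        raise ValueError("multi-file signal records are not supported")
    fmts = {s["format"] for s in sigs}
    if len(fmts) != 1:
        raise ValueError("mixed signal formats are not supported")
    dat = os.path.join(os.path.dirname(base), dat_files.pop())
    if not os.path.exists(dat):
        raise FileNotFoundError(f"missing signal file: {dat}")
    adc = _read_dat(dat, fmts.pop(), nsig, nsamp)
    gain = np.array([s["gain"] for s in sigs])
    baseline = np.array([s["baseline"] for s in sigs])
    physical = (adc - baseline) / gain

    atr = base + "." + annotator
    if os.path.exists(atr):
        ann_samples, ann_symbols = _read_atr(atr)
    else:
        ann_samples = np.empty(0, dtype=np.int64)
        ann_symbols = np.empty(0, dtype="<U1")
    order = np.argsort(ann_samples, kind="stable")
    keep = (
        (ann_samples[order] >= 0) & (ann_samples[order] < physical.shape[0])
        if ann_samples.size
        else np.empty(0, dtype=bool)
    )
    return ECGRecord(
        subject_id=name,
        signal=physical,
        fs=fs,
        ann_samples=ann_samples[order][keep],
        ann_symbols=ann_symbols[order][keep],
    )


# ---------------------------------------------------------------------------
# label taxonomy


@dataclass
class LabelCensus:
    kept: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return sum(self.kept.values())

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def map_labels(
    ann_samples: np.ndarray,
    ann_symbols: np.ndarray,
    allowed: frozenset[str] = SUPPORTED_SYMBOLS,
) -> tuple[np.ndarray, np.ndarray, LabelCensus]:
    """Keep annotations within the study taxonomy; census everything.

    Dropping is not an error — the census reports kept and dropped counts
    per symbol, and kept + dropped always equals the input count.
    """
    ann_samples = np.asarray(ann_samples)
    ann_symbols = np.asarray(ann_symbols, dtype="<U1")
    census = LabelCensus()
    mask = np.zeros(ann_symbols.size, dtype=bool)
    for i, sym in enumerate(ann_symbols):
        s = str(sym)
        if s in allowed:
            mask[i] = True
            census.kept[s] = census.kept.get(s, 0) + 1
        else:
            census.dropped[s] = census.dropped.get(s, 0) + 1
    return ann_samples[mask], ann_symbols[mask], census


def write_annotation_text(record: ECGRecord, path: str) -> None:
    """WFDB-style annotation listing: elapsed seconds, sample, symbol."""
    with open(path, "w") as fh:
        for s, sym in zip(record.ann_samples, record.ann_symbols):
            fh.write(f"{s / record.fs:12.3f} {int(s):9d} {sym}\n")


# ---------------------------------------------------------------------------
# dataset container


def config_hash(config: dict) -> str:
    """SHA-256 over the canonical (sorted-key) JSON form of a config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class BeatDataset:
    """Segments or images with aligned labels and subject ids."""

    X: np.ndarray  # (n, W) segments or (n, H, W, 3) images, float32
    labels: np.ndarray  # (n,) health-state symbols
    subjects: np.ndarray  # (n,) subject ids
    fs: float
    kind: str = "segments"  # "segments" | "images"
    r_index: int = -1  # R position in each window, for kind="segments"
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.subjects) == n):
            raise ValueError("misaligned dataset arrays")

    def __len__(self) -> int:
        return int(self.X.shape[0])

    @property
    def provenance_hash(self) -> str:
        return config_hash(self.config)

    def select(self, mask: np.ndarray) -> "BeatDataset":
        return BeatDataset(
            X=self.X[mask],
            labels=self.labels[mask],
            subjects=self.subjects[mask],
            fs=self.fs,
            kind=self.kind,
            r_index=self.r_index,
            config=dict(self.config),
        )


def save_dataset(ds: BeatDataset, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ds.X.astype(np.float32))
        f.create_dataset("labels", data=ds.labels.astype("S4"))
        f.create_dataset("subjects", data=ds.subjects.astype("S32"))
        f.attrs["version"] = DATASET_VERSION
        f.attrs["fs"] = ds.fs
        f.attrs["kind"] = ds.kind
        f.attrs["r_index"] = ds.r_index
        f.attrs["config_json"] = json.dumps(ds.config, sort_keys=True)
        f.attrs["config_hash"] = ds.provenance_hash


def load_dataset(path: str) -> BeatDataset:
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("version", -1))
            if version != DATASET_VERSION:
                raise ValueError(
                    f"dataset version {version} unsupported "
                    f"(expected {DATASET_VERSION}): {path}"
                )
            return BeatDataset(
                X=f["X"][()],
                labels=f["labels"][()].astype("<U4"),
                subjects=f["subjects"][()].astype("<U32"),
                fs=float(f.attrs["fs"]),
                kind=str(f.attrs["kind"]),
                r_index=int(f.attrs["r_index"]),
                config=json.loads(f.attrs["config_json"]),
            )
    except OSError as exc:
        raise OSError(f"cannot read dataset file {path}: {exc}") from exc
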
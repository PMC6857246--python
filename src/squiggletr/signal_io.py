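"""Raw-signal input/output, z-scale normalization and windowing.

Reads raw current series from fast5 (HDF5, single- or multi-read layout) or
from a plain-text fallback format, converts DAC units to pA when calibration
metadata is present, and provides the z-normalized overlapping windows that
the flank search aligns against.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


class SignalIOError(IOError):
    """Unreadable signal file or missing signal dataset."""


class DegenerateSignalError(ValueError):
    """Constant (zero-variance) signal cannot be z-normalized."""


@dataclass
class RawRead:
    """A raw current series for one sequencing read."""

    read_id: str
    samples: np.ndarray
    sample_rate: float | None = None
    strand_hint: str = "unknown"
    calibrated: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise SignalIOError(f"read {self.read_id}: empty signal")
        if not np.all(np.isfinite(self.samples)):
            raise SignalIOError(f"read {self.read_id}: non-finite samples")


@dataclass
class NormalizedSignal:
    """A z-scored signal slice plus its origin in the parent read."""

    z: np.ndarray
    read_id: str = ""
    offset: int = 0


def znormalize(x, read_id: str = "", offset: int = 0) -> NormalizedSignal:
    """z-scale a series: subtract the mean, divide by the population sd.

    Population sd (divide by n) is used; the choice only rescales DTW costs
    uniformly.  Raises :class:`DegenerateSignalError` on constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateSignalError("need at least 2 samples to z-normalize")
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError("constant or non-finite series")
    return NormalizedSignal(z=(x - x.mean()) / sd, read_id=read_id, offset=offset)


def window_signal(x, window_len: int, step: int, read_id: str = "") -> list[NormalizedSignal]:
    """Split a series into overlapping, independently z-normalized windows.

    Windows start at 0, step, 2*step, ...; a final shorter window covering the
    tail is appended when the tail is at least ``window_len/2`` long.  Constant
    windows are skipped with a log entry.  A series shorter than
    ``window_len/2`` yields an empty list.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if not 1 <= step <= window_len:
        raise ValueError("step must satisfy 1 <= step <= window_len")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < window_len / 2:
        return []
    offsets = list(range(0, max(n - window_len, 0) + 1, step))
    if n >= window_len:
        tail_start = offsets[-1] + step
        if tail_start < n and n - tail_start >= window_len / 2:
            offsets.append(tail_start)
    else:
        offsets = [0]
    out: list[NormalizedSignal] = []
    for off in offsets:
        chunk = x[off:off + window_len]
        try:
            out.append(znormalize(chunk, read_id=read_id, offset=off))
        except DegenerateSignalError:
            logger.info("skipping constant window at offset %d of read %s", off, read_id)
    return out


def restore_clean_amplitude(z: np.ndarray) -> np.ndarray:
    """Rescale a z-scored signal so its *noise-free* part has unit variance.

    z-normalization divides by the total standard deviation, noise included,
    which shrinks the clean squiggle amplitude by 1/sqrt(1 + sigma^2) relative
    to a noise-free reference and biases alignment toward spuriously
    compressed matches.  Within one k-mer dwell the level is constant, so
    adjacent-sample differences are (mostly) pure noise; their median
    absolute value gives a robust noise estimate provided dwells span
    several samples (callers gate on the expected dwell).
    """
    z = np.asarray(z, dtype=float)
    if z.size < 8:
        return z
    diffs = np.abs(np.diff(z))
    sigma = np.median(diffs) / (0.6745 * np.sqrt(2.0))
    noise_var = min(sigma * sigma, 0.8)
    return z / np.sqrt(max(1.0 - noise_var, 0.2))


# ---------------------------------------------------------------------------
# plain-text fallback format

def write_signal_text(read: RawRead, path) -> None:
    """Write a read as ``# read_id=...`` header plus one float per line."""
    with open(path, "w") as fh:
        fh.write(f"# read_id={read.read_id}\n")
        if read.sample_rate:
            fh.write(f"# sample_rate={read.sample_rate}\n")
        for v in read.samples:
            fh.write(f"{float(v)!r}\n")


def read_signal_text(path) -> list[RawRead]:
    """Read the plain-text fallback: one-column floats with an optional
    ``# read_id=`` header, or a TSV with ``read_id`` and ``sample`` columns."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first and "read_id" in first:
        if "sample" not in first.split():
            raise SignalIOError(f"{path}: TSV lacks a 'sample' column")
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        reads = []
        for rid, grp in df.groupby("read_id", sort=False):
            reads.append(RawRead(read_id=str(rid), samples=grp["sample"].to_numpy(float)))
        return reads
    read_id = path.stem
    sample_rate = None
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").strip().partition("=")
                if key.strip() == "read_id":
                    read_id = val.strip()
                elif key.strip() == "sample_rate":
                    sample_rate = float(val)
                continue
            values.append(float(line))
    if not values:
        raise SignalIOError(f"{path}: no samples found")
    return [RawRead(read_id=read_id, samples=np.asarray(values), sample_rate=sample_rate)]


# ---------------------------------------------------------------------------
# fast5 (HDF5)

def _calibrate(raw: np.ndarray, attrs) -> tuple[np.ndarray, bool]:
    try:
        rng = float(attrs["range"])
        digitisation = float(attrs["digitisation"])
        offset = float(attrs["offset"])
    except (KeyError, TypeError):
        return raw.astype(float), False
    return (raw.astype(float) + offset) * rng / digitisation, True


def _reads_from_fast5(path) -> list[RawRead]:
    import h5py

    reads: list[RawRead] = []
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SignalIOError(f"cannot open HDF5 file {path}: {exc}") from exc
    with f:
        if "Raw" in f:  # single-read layout: /Raw/Reads/Read_*/Signal
            group = f["Raw/Reads"]
            for name in group:
                node = group[name]
                if "Signal" not in node:
                    raise SignalIOError(f"{path}: read {name} lacks Signal dataset")
                raw = node["Signal"][...]
                rid = node.attrs.get("read_id", name)
                rid = rid.decode() if isinstance(rid, bytes) else str(rid)
                attrs = f["UniqueGlobalKey/channel_id"].attrs if "UniqueGlobalKey/channel_id" in f else {}
                samples, calibrated = _calibrate(raw, attrs)
                rate = attrs.get("sampling_rate") if attrs else None
                reads.append(RawRead(read_id=rid, samples=samples,
                                     sample_rate=float(rate) if rate is not None else None,
                                     calibrated=calibrated))
        else:  # multi-read layout: /read_<id>/Raw/Signal
            for name in f:
                node = f[name]
                if "Raw" not in node or "Signal" not in node["Raw"]:
                    raise SignalIOError(f"{path}: group {name} lacks Raw/Signal")
                raw = node["Raw/Signal"][...]
                rid = node["Raw"].attrs.get("read_id", name.removeprefix("read_"))
                rid = rid.decode() if isinstance(rid, bytes) else str(rid)
                attrs = node["channel_id"].attrs if "channel_id" in node else {}
                samples, calibrated = _calibrate(raw, attrs)
                rate = attrs.get("sampling_rate") if attrs else None
                reads.append(RawRead(read_id=rid, samples=samples,
                                     sample_rate=float(rate) if rate is not None else None,
                                     calibrated=calibrated))
    if not any(r.calibrated for r in reads):
        logger.info("%s: no calibration attributes; passing raw DAC values through", path)
    return reads


def write_fast5(reads: list[RawRead], path, sample_rate: float = 4000.0) -> None:
    """Write reads in the multi-read fast5 layout (no calibration: pA stored)."""
    import h5py

    with h5py.File(path, "w") as f:
        for read in reads:
            grp = f.create_group(f"read_{read.read_id}/Raw")
            grp.create_dataset("Signal", data=read.samples)
            grp.attrs["read_id"] = read.read_id


_TEXT_SUFFIXES = {".txt", ".tsv", ".signal", ".csv"}
_FAST5_SUFFIXES = {".fast5", ".hdf5", ".h5"}


def read_fast5(path) -> list[RawRead]:
    """Read raw signals from a fast5 file, a text fallback file, or a
    directory of either.  An empty directory yields an empty list."""
    path = Path(path)
    if path.is_dir():
        reads: list[RawRead] = []
        for child in sorted(path.iterdir()):
            if child.suffix.lower() in _TEXT_SUFFIXES | _FAST5_SUFFIXES:
                try:
                    reads.extend(read_fast5(child))
                except (SignalIOError, ValueError) as exc:
                    logger.warning("skipping %s: %s", child, exc)
        return reads
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return read_signal_text(path)
    return _reads_from_fast5(path)
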
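"""PSG input/output and preprocessing.

Covers the plumbing between recorded data and the classifiers: a 16-bit EDF
(European Data Format) reader/writer, polyphase resampling to the common
128 Hz analysis rate with anti-alias filtering, stage-label harmonization
across scoring standards (R&K stages 3 and 4 merge into N3; movement time
is reassigned), epoch-grid conversion between 20- and 30-s scoring, and
epoching of continuous signals.

EDF files are written with one data record per second; physical units must
be microvolt ('uV') and other units are rejected rather than silently
scaled.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import resample_poly

from .core import STAGES, Channel, Hypnogram, Recording

logger = logging.getLogger(__name__)

#: Default mapping from channel role to EDF signal label.
DEFAULT_CHANNEL_LABELS: dict[str, str] = {
    "EEG": "C3A2",
    "EOG_L": "EOGL",
    "EOG_R": "EOGR",
    "EMG": "EMG",
}

TARGET_FS_HZ = 128.0


# ---------------------------------------------------------------------------
# EDF codec (16-bit, one data record per second)
# ---------------------------------------------------------------------------


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} longer than {width} bytes")
    return b.ljust(width)


def write_edf(recording: Recording, path: Union[str, Path]) -> None:
    """Write a recording as 16-bit EDF with one data record per second.

    All channels must have integer sampling rates and a whole number of
    seconds of data. Per-channel physical ranges are chosen symmetric around
    zero from the data so quantization error is at most range/2^16.
    """
    path = Path(path)
    fses = []
    for ch in recording.channels:
        fs = ch.fs_hz
        if abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"EDF writer requires integer sampling rates, got {fs}")
        fses.append(int(round(fs)))
    n_records = {ch.samples.size // fs for ch, fs in zip(recording.channels, fses)}
    for ch, fs in zip(recording.channels, fses):
        if ch.samples.size % fs:
            raise ValueError(f"channel {ch.label}: duration is not a whole number of seconds")
    if len(n_records) != 1:
        raise ValueError("all channels must have the same duration")
    n_rec = n_records.pop()
    ns = len(recording.channels)

    phys_ranges = []
    digitized = []
    for ch in recording.channels:
        pmax = float(np.max(np.abs(ch.samples))) if ch.samples.size else 1.0
        pmax = max(pmax, 1.0) * 1.0000001  # keep extremes inside the range
        # digitize against the value as written in the header (6 significant
        # digits), otherwise writer and reader scales disagree; round up so
        # the written range still covers the data
        data_max = pmax
        pmax = float(f"{pmax:.6g}"[:8])
        while pmax < data_max:
            pmax = float(f"{pmax * 1.00002:.6g}"[:8])
        scale = 32767.0 / pmax
        digitized.append(np.clip(np.round(ch.samples * scale), -32767, 32767).astype("<i2"))
        phys_ranges.append(pmax)

    header = b"".join(
        [
            _pad("0", 8),
            _pad("synthetic subject", 80),
            _pad("somnostage recording", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    fields = [
        b"".join(_pad(ch.label, 16) for ch in recording.channels),
        b"".join(_pad("", 80) for _ in recording.channels),
        b"".join(_pad("uV", 8) for _ in recording.channels),
        b"".join(_pad(f"{-p:.6g}"[:8], 8) for p in phys_ranges),
        b"".join(_pad(f"{p:.6g}"[:8], 8) for p in phys_ranges),
        b"".join(_pad("-32767", 8) for _ in recording.channels),
        b"".join(_pad("32767", 8) for _ in recording.channels),
        b"".join(_pad("", 80) for _ in recording.channels),
        b"".join(_pad(str(fs), 8) for fs in fses),
        b"".join(_pad("", 32) for _ in recording.channels),
    ]
    with open(path, "wb") as f:
        f.write(header)
        for block in fields:
            f.write(block)
        for r in range(n_rec):
            for dig, fs in zip(digitized, fses):
                f.write(dig[r * fs : (r + 1) * fs].tobytes())


def _read_edf_raw(path: Path) -> tuple[list[str], list[np.ndarray], list[float], list[str]]:
    """Parse an EDF file: labels, per-channel samples (physical), rates, units."""
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: not a valid EDF file (truncated header)")
        n_rec = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig = f.read(256 * ns)

        def field(offset: int, width: int, k: int) -> str:
            start = offset * ns + width * k
            return sig[start : start + width].decode("ascii").strip()

        # cumulative field offsets: label 0, transducer 16, phys dim 96,
        # phys min 104, phys max 112, dig min 120, dig max 128,
        # prefiltering 136, samples-per-record 216, reserved 224
        labels = [field(0, 16, k) for k in range(ns)]
        units = [field(96, 8, k) for k in range(ns)]
        pmin = [float(field(104, 8, k)) for k in range(ns)]
        pmax = [float(field(112, 8, k)) for k in range(ns)]
        dmin = [float(field(120, 8, k)) for k in range(ns)]
        dmax = [float(field(128, 8, k)) for k in range(ns)]
        spr = [int(field(216, 8, k)) for k in range(ns)]
        rec_len = sum(spr)
        data = np.frombuffer(f.read(n_rec * rec_len * 2), dtype="<i2")
    data = data.reshape(n_rec, rec_len)
    samples: list[np.ndarray] = []
    rates: list[float] = []
    offset = 0
    for k in range(ns):
        dig = data[:, offset : offset + spr[k]].reshape(-1).astype(np.float64)
        gain = (pmax[k] - pmin[k]) / (dmax[k] - dmin[k])
        samples.append((dig - dmin[k]) * gain + pmin[k])
        rates.append(spr[k] / rec_dur)
        offset += spr[k]
    return labels, samples, rates, units


def read_edf(
    path: Union[str, Path],
    channel_labels: Optional[dict[str, str]] = None,
) -> Recording:
    """Read the four analysis channels from an EDF file.

    ``channel_labels`` maps channel roles (EEG, EOG_L, EOG_R, EMG) to the
    EDF signal labels to extract; defaults to the montage written by the
    synthetic generator. A requested label that is absent raises a
    channel-not-found error listing the labels present in the file; units
    other than microvolt are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channel_labels = dict(channel_labels or DEFAULT_CHANNEL_LABELS)
    labels, samples, rates, units = _read_edf_raw(path)
    channels = []
    for role, wanted in channel_labels.items():
        if wanted not in labels:
            raise KeyError(f"channel {wanted!r} not found in {path.name}; available labels: {labels}")
        k = labels.index(wanted)
        if units[k].lower() not in ("uv", "µv", "μv"):
            raise ValueError(f"channel {wanted!r} has physical dimension {units[k]!r}; expected uV")
        channels.append(Channel(role, wanted, samples[k], rates[k]))
    return Recording(channels=channels)


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------


def write_hypnogram_csv(hypnogram: Hypnogram, path: Union[str, Path]) -> None:
    """Write ``epoch_index,stage`` rows (0-based indices)."""
    with open(path, "w", encoding="utf-8") as f:
        f.write("epoch_index,stage\n")
        for i, s in enumerate(hypnogram.stages):
            f.write(f"{i},{s}\n")


def read_hypnogram_csv(path: Union[str, Path], epoch_len_s: int) -> Hypnogram:
    stages = []
    with open(path, encoding="utf-8") as f:
        header = f.readline()
        if not header.lower().startswith("epoch_index"):
            raise ValueError(f"{path}: expected 'epoch_index,stage' header")
        for line in f:
            line = line.strip()
            if line:
                _, stage = line.split(",")
                stages.append(stage)
    return Hypnogram(stages, epoch_len_s)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_to(recording: Recording, target_fs: float = TARGET_FS_HZ) -> Recording:
    """Resample all channels to ``target_fs`` (downsampling only).

    Uses polyphase rational resampling with the built-in anti-alias
    low-pass, the standard way to accommodate data recorded at different
    rates. Channels already at the target rate pass through unchanged;
    upsampling is refused.
    """
    channels = []
    for ch in recording.channels:
        if abs(ch.fs_hz - target_fs) < 1e-9:
            channels.append(ch)
            continue
        if ch.fs_hz < target_fs:
            raise ValueError(
                f"channel {ch.label}: cannot upsample {ch.fs_hz} Hz to {target_fs} Hz; "
                "only downsampling to the common rate is supported"
            )
        frac = Fraction(target_fs / ch.fs_hz).limit_denominator(1000)
        out = resample_poly(ch.samples, frac.numerator, frac.denominator)
        expected = int(round(ch.samples.size * target_fs / ch.fs_hz))
        out = out[:expected] if out.size >= expected else np.pad(out, (0, expected - out.size))
        channels.append(Channel(ch.role, ch.label, out, target_fs))
    return Recording(channels=channels)


# ---------------------------------------------------------------------------
# Label harmonization
# ---------------------------------------------------------------------------

_RK_MAP = {"W": "W", "1": "N1", "2": "N2", "3": "N3", "4": "N3", "R": "R"}
_AASM_SET = set(STAGES)


def harmonize_labels(
    raw_labels: Sequence[str],
    source_standard: str = "AASM",
    mt_rule: str = "neighbour_majority",
) -> list[str]:
    """Map raw stage labels onto the harmonized (W, N1, N2, N3, R) alphabet.

    R&K labels merge stages 3 and 4 into N3; AASM labels pass through.
    Movement time ('MT'), which neither dataset scores but a reader must
    accept, is reassigned to the majority stage of its flanking non-MT
    epochs (ties and MT-only sequences fall back to W).
    """
    if source_standard not in ("RK", "AASM"):
        raise ValueError(f"unknown scoring standard {source_standard!r}")
    out: list[Optional[str]] = []
    for i, lab in enumerate(raw_labels):
        lab = str(lab)
        if lab == "MT":
            out.append(None)
            continue
        if source_standard == "RK":
            if lab not in _RK_MAP:
                raise ValueError(f"unknown R&K label {lab!r} at epoch {i}")
            out.append(_RK_MAP[lab])
        else:
            if lab not in _AASM_SET:
                raise ValueError(f"unknown AASM label {lab!r} at epoch {i}")
            out.append(lab)
    if mt_rule != "neighbour_majority":
        raise ValueError(f"unknown MT rule {mt_rule!r}")
    # Resolve MT epochs from the nearest non-MT neighbours on each side.
    resolved: list[str] = []
    n = len(out)
    for i, lab in enumerate(out):
        if lab is not None:
            resolved.append(lab)
            continue
        prev_ = next((out[j] for j in range(i - 1, -1, -1) if out[j] is not None), None)
        next_ = next((out[j] for j in range(i + 1, n) if out[j] is not None), None)
        votes = [v for v in (prev_, next_) if v is not None]
        if not votes:
            resolved.append("W")
        elif len(votes) == 2 and votes[0] != votes[1]:
            resolved.append("W")  # tie between the flanks is conservative wake
        else:
            resolved.append(votes[0])
    return resolved


# ---------------------------------------------------------------------------
# Epoch-grid conversion and epoching
# ---------------------------------------------------------------------------


def convert_epoch_length(hypnogram: Hypnogram, target_epoch_len_s: int) -> Hypnogram:
    """Re-grid a hypnogram between 20- and 30-s epochs.

    Each target epoch takes the stage with the largest time overlap against
    the source grid; ties break toward the earlier source epoch. The total
    span is preserved to within one target epoch (a trailing partial target
    epoch is kept when it overlaps at least half an epoch of source data).
    """
    if target_epoch_len_s not in (20, 30):
        raise ValueError("target epoch length must be 20 or 30 s")
    src = hypnogram.epoch_len_s
    tgt = target_epoch_len_s
    if src == tgt:
        return Hypnogram(list(hypnogram.stages), tgt, hypnogram.lights_off, hypnogram.lights_on)
    total_s = len(hypnogram) * src
    n_target = int(round(total_s / tgt))
    stages: list[str] = []
    for i in range(n_target):
        t0, t1 = i * tgt, (i + 1) * tgt
        overlap: dict[str, float] = {}
        order: dict[str, int] = {}
        j0 = int(t0 // src)
        j1 = min(int(np.ceil(t1 / src)), len(hypnogram))
        for j in range(j0, j1):
            ov = min(t1, (j + 1) * src) - max(t0, j * src)
            if ov <= 0:
                continue
            s = hypnogram.stages[j]
            overlap[s] = overlap.get(s, 0.0) + ov
            order.setdefault(s, j)
        # max overlap; ties toward the stage seen in the earlier source epoch
        stages.append(max(overlap, key=lambda s: (overlap[s], -order[s])))
    return Hypnogram(stages, tgt)


def epoch_view(recording: Recording, epoch_len_s: int) -> list[dict[str, np.ndarray]]:
    """Split a recording into per-epoch channel blocks.

    Returns one dict per epoch mapping channel role to its ``fs *
    epoch_len`` samples. A trailing partial epoch is dropped with a logged
    warning.
    """
    durations = {c.duration_s for c in recording.channels}
    duration = min(durations)
    n_epochs = int(duration // epoch_len_s)
    dropped = duration - n_epochs * epoch_len_s
    if dropped > 1e-9:
        logger.warning("dropping trailing partial epoch: %.1f s of signal unused", dropped)
    out = []
    for i in range(n_epochs):
        block = {}
        for ch in recording.channels:
            n = int(round(ch.fs_hz * epoch_len_s))
            block[ch.role] = ch.samples[i * n : (i + 1) * n]
        out.append(block)
    return out
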
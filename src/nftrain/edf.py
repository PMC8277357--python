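"""EDF (European Data Format) reading and writing for Recordings.

Writing uses a self-contained plain-EDF encoder (ASCII headers, 1-second
data records, 16-bit samples scaled per channel to the physical range).
Reading goes through MNE, which also serves as an independent check that
the files we write are standard-conforming. Physical units are µV.
"""

from __future__ import annotations

import datetime as dt
import re
import warnings
from pathlib import Path

import numpy as np

from .errors import EDFError
from .recording import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767

#: Filename convention for cohort files: subj01_pre_eo.edf etc.
_NAME_RE = re.compile(r"(?P<subject>[^_]+)_(?P<phase>pre|post)_(?P<cond>eo|ec)\.edf$")
_COND = {"eo": "eyes_open", "ec": "eyes_closed"}
_COND_SHORT = {v: k for k, v in _COND.items()}


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise EDFError(f"EDF header field too long: {text!r} > {width} bytes")
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a plain EDF file (µV, 1-s records).

    The sampling rate must be a whole number of samples per second and every
    sample finite. Samples are quantized to 16 bits over each channel's
    actual physical range; the round-trip error is at most half a
    quantization step.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise EDFError(f"EDF writer needs an integer sampling rate, got {fs}")
    names = list(rec.channels)
    data = [rec.channels[n] for n in names]
    for n, x in zip(names, data):
        if not np.all(np.isfinite(x)):
            raise EDFError(f"channel {n}: non-finite samples cannot be written")
    nrec = rec.n_samples // spr
    if nrec * spr != rec.n_samples:
        warnings.warn("signal length not a whole number of seconds; truncating")
    if nrec == 0:
        raise EDFError("recording shorter than one 1-s data record")

    pmins, pmaxs, scaled = [], [], []
    for x in data:
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        dig = np.round((x[: nrec * spr] - lo) * gain + _DIG_MIN).astype("<i2")
        pmins.append(lo)
        pmaxs.append(hi)
        scaled.append(dig)

    ns = len(names)
    start = dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(f"subject {rec.subject}", 80),
        _pad(f"{rec.phase} {rec.condition}", 80),
        _pad(start.strftime("%d.%m.%y"), 8),
        _pad(start.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(nrec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])

    def field(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    header += field(names, 16)
    header += field([""] * ns, 80)
    header += field(["uV"] * ns, 8)
    header += field([f"{v:.6g}"[:8] for v in pmins], 8)
    header += field([f"{v:.6g}"[:8] for v in pmaxs], 8)
    header += field([str(_DIG_MIN)] * ns, 8)
    header += field([str(_DIG_MAX)] * ns, 8)
    header += field([""] * ns, 80)
    header += field([str(spr)] * ns, 8)
    header += field([""] * ns, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(nrec):
            for dig in scaled:
                fh.write(dig[r * spr:(r + 1) * spr].tobytes())
    return path


def _check_size(path: Path) -> None:
    """Reject files whose size disagrees with the EDF header (truncation)."""
    size = path.stat().st_size
    if size < 256:
        raise EDFError(f"unreadable EDF {path}: shorter than the 256-byte header")
    with open(path, "rb") as fh:
        head = fh.read(256)
        try:
            header_bytes = int(head[184:192])
            nrec = int(head[236:244])
            ns = int(head[252:256])
        except ValueError as exc:
            raise EDFError(f"unreadable EDF {path}: malformed header") from exc
        fh.seek(256 + 216 * ns)
        spr_field = fh.read(8 * ns)
        try:
            spr = [int(spr_field[8 * i:8 * (i + 1)]) for i in range(ns)]
        except ValueError as exc:
            raise EDFError(f"unreadable EDF {path}: malformed signal headers") from exc
    expected = header_bytes + nrec * sum(spr) * 2
    if nrec >= 0 and size < expected:
        raise EDFError(
            f"unreadable EDF {path}: truncated ({size} bytes, expected {expected})"
        )


def read_edf(
    path: str | Path,
    subject: str | None = None,
    phase: str | None = None,
    condition: str | None = None,
) -> Recording:
    """Read an EDF file into a Recording (µV).

    subject/phase/condition default to the ``subj{N}_{pre|post}_{eo|ec}.edf``
    filename convention when not given.
    """
    import mne  # heavy import, deferred

    path = Path(path)
    if not path.exists():
        raise EDFError(f"unreadable EDF: {path} does not exist")
    m = _NAME_RE.search(path.name)
    if m:
        subject = subject or m["subject"]
        phase = phase or m["phase"]
        condition = condition or _COND[m["cond"]]
    if subject is None or phase is None or condition is None:
        raise EDFError(
            f"cannot infer subject/phase/condition from {path.name!r}; "
            "pass them explicitly"
        )
    _check_size(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed files
        raise EDFError(f"unreadable EDF {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE returns Volts for µV-dimensioned EEG
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    return Recording(
        subject=subject, phase=phase, condition=condition,
        channels=channels, fs=float(raw.info["sfreq"]),
    )


def cohort_filename(rec: Recording) -> str:
    """Canonical cohort filename: subj{N}_{pre|post}_{eo|ec}.edf."""
    return f"{rec.subject}_{rec.phase}_{_COND_SHORT[rec.condition]}.edf"


def write_cohort(recordings, out_dir: str | Path) -> list[Path]:
    """Write every recording of a cohort into out_dir; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [write_edf(rec, out_dir / cohort_filename(rec)) for rec in recordings]


def read_cohort(in_dir: str | Path) -> list[Recording]:
    """Read every conventionally named EDF file under in_dir."""
    in_dir = Path(in_dir)
    paths = sorted(p for p in in_dir.glob("*.edf") if _NAME_RE.search(p.name))
    if not paths:
        raise EDFError(f"no cohort EDF files found in {in_dir}")
    return [read_edf(p) for p in paths]
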
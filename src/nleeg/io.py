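"""Recording/event/table I/O and condition segmentation.

EEG recordings travel as :class:`Recording` (channels x samples, microvolts).
EDF (European Data Format) support is self-contained: the classic 16-bit
EDF layout -- a 256-byte fixed header, 256 bytes per signal of ASCII
metadata, then data records of little-endian int16 samples scaled between a
digital and a physical range -- is simple enough to read and write directly
with numpy. Tables (events, features, ratings) are UTF-8 TSV with a header
row, handled by pandas.

Sample indexing is 0-based and epoch slices are half-open
``[onset_sample, onset_sample + duration_samples)``; second-to-sample
conversion uses round-half-to-even so results are platform-stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    IntegrityError,
    UnsupportedLayoutError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The 19 scalp electrodes of the International 10-20 montage used throughout.
PAPER_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

#: Seven emotional sound stimuli plus the two resting states.
STIMULI = [
    "barking", "crying", "vomiting", "coughing", "scratching",
    "birdsong", "laughter",
]
REST_CONDITIONS = ["rest_open", "rest_closed"]
DEFAULT_VOCABULARY = STIMULI + REST_CONDITIONS

GROUPS = ["control", "schizophrenia", "mTBI", "stroke", "coma"]

FEATURE_COLUMNS = ["subject", "group", "condition", "channel", "feature", "value"]
FEATURE_KEY = ["subject", "condition", "channel", "feature"]
RATING_COLUMNS = ["subject", "group", "stimulus", "scale", "value"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_labels : list of str
        Unique labels, one per data row.
    subject_id, group : str
        Provenance; ``group`` is one of ``GROUPS`` or ``"unknown"``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValidationError(
                "Recording.data must be a channels x samples matrix with >= 2 samples"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("Recording.data contains non-finite values")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        labels = list(self.channel_labels)
        if len(labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(labels)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(set(labels)) != len(labels):
            raise ValidationError("channel labels must be unique")
        self.channel_labels = labels
        if self.group not in GROUPS and self.group != "unknown":
            raise ValidationError(f"unknown group {self.group!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


class EventTable:
    """Ordered stimulus/rest intervals relative to the start of a recording.

    Wraps a DataFrame with columns ``onset_s``, ``duration_s``, ``label``.
    Onsets must be non-negative and strictly increasing and intervals must
    not overlap or touch (the experimental design always leaves an
    inter-stimulus gap).
    """

    COLUMNS = ["onset_s", "duration_s", "label"]

    def __init__(self, table: pd.DataFrame, vocabulary: list[str] | None = None):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        df = table[self.COLUMNS].reset_index(drop=True).copy()
        df["onset_s"] = df["onset_s"].astype(float)
        df["duration_s"] = df["duration_s"].astype(float)
        df["label"] = df["label"].astype(str)
        if len(df):
            onsets = df["onset_s"].to_numpy()
            durs = df["duration_s"].to_numpy()
            if (onsets < 0).any():
                raise ValidationError("event onsets must be non-negative")
            if (durs <= 0).any():
                raise ValidationError("event durations must be positive")
            if not (np.diff(onsets) > 0).all():
                raise ValidationError("event onsets must be strictly increasing")
            ends = onsets + durs
            if (ends[:-1] >= onsets[1:]).any():
                raise ValidationError("event intervals overlap (no gap between events)")
            if vocabulary is not None:
                bad = sorted(set(df["label"]) - set(vocabulary))
                if bad:
                    raise ValidationError(f"labels outside declared vocabulary: {bad}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        return list(dict.fromkeys(self.table["label"]))


@dataclass
class ConditionFragment:
    """All epochs of one condition for one subject.

    ``epochs`` is a list of channels x samples arrays, one per presentation.
    """

    condition: str
    epochs: list[np.ndarray]
    fs: float
    subject_id: str = ""
    group: str = "unknown"
    channel_labels: list[str] = field(default_factory=list)

    @property
    def total_duration_s(self) -> float:
        return sum(e.shape[1] for e in self.epochs) / self.fs


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def seconds_to_sample(t_s: float, fs: float) -> int:
    """Convert seconds to a sample index by round-half-to-even."""
    return int(np.round(t_s * fs))


def segment(recording: Recording, events: EventTable) -> list[ConditionFragment]:
    """Cut a recording into per-condition fragments.

    Returns one :class:`ConditionFragment` per distinct event label (in
    order of first appearance); epochs are verbatim half-open sample slices
    of the recording, so no samples are shared between epochs.
    """
    n = recording.n_samples
    frags: dict[str, ConditionFragment] = {}
    for row in events.table.itertuples(index=False):
        if row.onset_s + row.duration_s > n / recording.fs + 0.5 / recording.fs:
            raise ValidationError(
                f"event at {row.onset_s:.3f}s + {row.duration_s:.3f}s extends past "
                f"the {n / recording.fs:.3f}s recording"
            )
        start = seconds_to_sample(row.onset_s, recording.fs)
        stop = start + seconds_to_sample(row.duration_s, recording.fs)
        if stop > n:
            raise ValidationError("event extends past the end of the recording")
        epoch = recording.data[:, start:stop]
        frag = frags.get(row.label)
        if frag is None:
            frags[row.label] = ConditionFragment(
                condition=row.label,
                epochs=[epoch],
                fs=recording.fs,
                subject_id=recording.subject_id,
                group=recording.group,
                channel_labels=list(recording.channel_labels),
            )
        else:
            frag.epochs.append(epoch)
    return list(frags.values())


# ---------------------------------------------------------------------------
# EDF read/write
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(path, recording: Recording) -> None:
    """Write a Recording as classic EDF with 1-second data records.

    Physical ranges are symmetric integers (ceil of the per-channel peak)
    so header round-trip is exact; the quantization step is therefore
    ``(phys_max - phys_min) / (dig_max - dig_min)`` per channel. The final
    record is zero-padded if the recording is not a whole number of seconds.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise UnsupportedLayoutError(f"EDF writer requires integer Hz, got {fs}")
    spr = int(round(fs))  # samples per 1-s record
    n_sig = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))

    pmax = np.ceil(np.abs(recording.data).max(axis=1))
    pmax = np.maximum(pmax, 1.0)  # guard all-zero channels

    header = b"".join([
        _ascii("0", 8),
        _ascii(recording.subject_id or "X", 80),
        _ascii(f"Startdate 01-JAN-2000 group={recording.group}"[:80], 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (1 + n_sig), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),
        _ascii(n_sig, 4),
    ])
    fields = [
        (recording.channel_labels, 16),
        (["" for _ in range(n_sig)], 80),          # transducer
        (["uV"] * n_sig, 8),                       # physical dimension
        ([f"{-p:.0f}" for p in pmax], 8),
        ([f"{p:.0f}" for p in pmax], 8),
        ([str(_DIG_MIN)] * n_sig, 8),
        ([str(_DIG_MAX)] * n_sig, 8),
        (["" for _ in range(n_sig)], 80),          # prefiltering
        ([str(spr)] * n_sig, 8),
        (["" for _ in range(n_sig)], 32),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for values, width in fields
    )

    scale = (pmax - (-pmax)) / (_DIG_MAX - _DIG_MIN)
    padded = np.zeros((n_sig, n_records * spr))
    padded[:, : recording.n_samples] = recording.data
    digital = np.round((padded + pmax[:, None]) / scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records: per record, all samples of signal 0, then signal 1, ...
        fh.write(
            digital.reshape(n_sig, n_records, spr)
            .transpose(1, 0, 2)
            .tobytes()
        )


def _read_field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6}


def read_edf(path, channels: list[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a Recording (microvolts).

    Parameters
    ----------
    channels : list of str, optional
        Label whitelist. By default the 19 standard 10-20 scalp labels are
        kept when present (extra channels such as EOG or polygraphy are
        ignored with a logged notice); if none of them match, all channels
        are read.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError("file too short for an EDF header")
        try:
            n_records = int(_read_field(head, 236, 8))
            record_dur = float(_read_field(head, 244, 8))
            n_sig = int(_read_field(head, 252, 4))
        except ValueError as exc:
            raise FormatError(f"malformed EDF header: {exc}") from exc
        if n_sig <= 0 or n_records < 0 or record_dur <= 0:
            raise FormatError("malformed EDF header: non-positive layout fields")
        sig = fh.read(256 * n_sig)
        if len(sig) < 256 * n_sig:
            raise FormatError("truncated EDF signal header")

        def col(offset: int, width: int) -> list[str]:
            return [_read_field(sig, offset * n_sig + i * width, width) for i in range(n_sig)]

        labels = col(0, 16)
        units = col(16 + 80, 8)
        try:
            pmin = np.array([float(v) for v in col(16 + 80 + 8, 8)])
            pmax = np.array([float(v) for v in col(16 + 80 + 16, 8)])
            dmin = np.array([float(v) for v in col(16 + 80 + 24, 8)])
            dmax = np.array([float(v) for v in col(16 + 80 + 32, 8)])
            spr = np.array([int(v) for v in col(16 + 80 + 40 + 80, 8)])
        except ValueError as exc:
            raise FormatError(f"malformed EDF signal header: {exc}") from exc

        raw = np.frombuffer(fh.read(), dtype="<i2")

    # channel selection (EDF+ annotation channels are never signal data)
    selectable = [i for i, lab in enumerate(labels) if "EDF Annotations" not in lab]
    if channels is None:
        keep = [i for i in selectable if labels[i] in PAPER_CHANNELS]
        if not keep:
            keep = selectable
    else:
        keep = [i for i in selectable if labels[i] in channels]
        if not keep:
            raise FormatError(f"none of the requested channels {channels} present")
    dropped = [labels[i] for i in selectable if i not in keep]
    if dropped:
        logger.info("read_edf: ignoring channels outside whitelist: %s", dropped)

    if len({int(spr[i]) for i in keep}) != 1:
        raise UnsupportedLayoutError(
            "selected channels have mixed sampling rates: "
            + str(sorted({int(spr[i]) for i in keep}))
        )

    total_spr = int(spr.sum())
    if raw.size < n_records * total_spr:
        raise FormatError("EDF data section shorter than the header declares")
    records = raw[: n_records * total_spr].reshape(n_records, total_spr)
    offsets = np.concatenate([[0], np.cumsum(spr)]).astype(int)

    fs = spr[keep[0]] / record_dur
    data = np.empty((len(keep), n_records * int(spr[keep[0]])))
    for row, i in enumerate(keep):
        dig = records[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (dig - dmin[i]) * gain + pmin[i]
        unit = _UNIT_TO_UV.get(units[i].lower())
        if unit is None:
            warnings.warn(
                f"channel {labels[i]!r}: unknown physical dimension {units[i]!r}; "
                "passing values through unconverted"
            )
            unit = 1.0
        data[row] = phys * unit

    return Recording(
        data=data,
        fs=fs,
        channel_labels=[labels[i] for i in keep],
        subject_id=_read_field(head, 8, 80) or "",
    )


# ---------------------------------------------------------------------------
# Tabular artifacts
# ---------------------------------------------------------------------------

def read_events(path, vocabulary: list[str] | None = None) -> EventTable:
    """Read a TSV/CSV event table (columns onset_s, duration_s, label).

    ``vocabulary`` defaults to the seven stimuli plus the two rest states;
    pass ``None``-like empty behaviour by supplying your own list.
    """
    if vocabulary is None:
        vocabulary = DEFAULT_VOCABULARY
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df = df.sort_values("onset_s") if "onset_s" in df.columns else df
    return EventTable(df, vocabulary=vocabulary)


def write_events(path, events: EventTable) -> None:
    events.table.to_csv(path, sep="\t", index=False)


def _check_feature_integrity(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=FEATURE_KEY)
    if dup.any():
        first = df.loc[dup.idxmax(), FEATURE_KEY].tolist()
        raise IntegrityError(
            f"duplicate (subject, condition, channel, feature) key, e.g. {first}"
        )


def write_feature_table(path, rows: pd.DataFrame) -> None:
    """Write long-format feature rows with a stable column order."""
    missing = [c for c in FEATURE_COLUMNS if c not in rows.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    df = rows[FEATURE_COLUMNS].copy()
    _check_feature_integrity(df)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in FEATURE_COLUMNS[:-1]})
    df["value"] = df["value"].astype(float)
    _check_feature_integrity(df)
    return df


def write_ratings_table(path, ratings: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing:
        raise ValidationError(f"ratings table missing columns: {missing}")
    ratings[RATING_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ratings_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in RATING_COLUMNS[:-1]})
    df["value"] = df["value"].astype(float)
    return df
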
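"""EEG preprocessing for resting-state connectivity analysis.

Implements the fixed preprocessing chain used throughout the package:

    channel selection -> alpha-band FIR filtering -> average re-reference
    -> hemisphere flipping -> rectangular windowing

The chain normalises every recording to a 22-channel 10-20 montage with
the *left* hemisphere defined as the lesioned (affected) side: recordings
from subjects with a right-hemisphere lesion have their homologous
left/right channel pairs swapped, so that "ipsilesional" always means
"left" downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "Montage",
    "WindowSet",
    "DEFAULT_MONTAGE",
    "select_channels",
    "bandpass_alpha",
    "rereference_average",
    "flip_hemispheres",
    "segment_windows",
    "preprocess_recording",
    "read_delimited_recording",
    "write_delimited_recording",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGRecording:
    """Labelled multichannel EEG time series.

    data : (n_channels, n_samples) array, microvolts
    labels : channel names, one per row of ``data``
    fs : sampling rate in Hz
    lesion_side : "L" or "R" (side of the stroke lesion), or None if unknown
    group : treatment arm tag (e.g. "BCI-FES", "FES"), free-form
    session : "pre" or "post"
    subject_id : free-form identifier
    """

    data: np.ndarray
    labels: tuple[str, ...]
    fs: float
    lesion_side: str | None = None
    group: str | None = None
    session: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", tuple(self.labels))
        if data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {data.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Montage:
    """A named electrode montage split into left / right / midline sets.

    ``homologous_pairs`` lists (left, right) electrode pairs that are
    mirror images across the sagittal plane; hemisphere flipping swaps
    exactly these pairs.
    """

    labels: tuple[str, ...]
    left: frozenset[str]
    right: frozenset[str]
    midline: frozenset[str]
    homologous_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "left", frozenset(self.left))
        object.__setattr__(self, "right", frozenset(self.right))
        object.__setattr__(self, "midline", frozenset(self.midline))
        object.__setattr__(
            self, "homologous_pairs", tuple(map(tuple, self.homologous_pairs))
        )
        union = self.left | self.right | self.midline
        if union != set(self.labels):
            raise ValueError("left/right/midline must partition the labels")
        if (self.left & self.right) or (self.left & self.midline) or (
            self.right & self.midline
        ):
            raise ValueError("left/right/midline sets must be disjoint")
        for l, r in self.homologous_pairs:
            if l not in self.left or r not in self.right:
                raise ValueError(f"pair ({l},{r}) not a (left,right) pair")

    def hemisphere(self, label: str) -> str:
        """Return 'L', 'R' or 'M' for a montage label."""
        if label in self.left:
            return "L"
        if label in self.right:
            return "R"
        if label in self.midline:
            return "M"
        raise KeyError(f"label {label!r} not in montage")


#: The 22-channel 10-20 montage used for all default analyses.
DEFAULT_MONTAGE = Montage(
    labels=(
        "F3", "F4", "FC3", "FC4", "C3", "C4", "CP3", "CP4", "P3", "P4",
        "FT7", "FT8", "T3", "T4", "TP7", "TP8",
        "Fz", "Oz", "FCz", "Cz", "CPz", "Pz",
    ),
    left=frozenset({"F3", "FC3", "C3", "CP3", "P3", "FT7", "T3", "TP7"}),
    right=frozenset({"F4", "FC4", "C4", "CP4", "P4", "FT8", "T4", "TP8"}),
    midline=frozenset({"Fz", "Oz", "FCz", "Cz", "CPz", "Pz"}),
    homologous_pairs=(
        ("F3", "F4"), ("FC3", "FC4"), ("C3", "C4"), ("CP3", "CP4"),
        ("P3", "P4"), ("FT7", "FT8"), ("T3", "T4"), ("TP7", "TP8"),
    ),
)


@dataclass(frozen=True)
class WindowSet:
    """Rectangular analysis windows cut from one recording.

    segments : list of (n_channels, window_samples) arrays
    window_s, step_s : window length and hop in seconds
    """

    segments: tuple[np.ndarray, ...]
    window_s: float
    step_s: float
    fs: float
    labels: tuple[str, ...]
    parent_id: str | None = None

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_channels(rec: EEGRecording, montage: Montage = DEFAULT_MONTAGE) -> EEGRecording:
    """Keep exactly the montage channels, in montage order.

    Reference electrodes (A1/A2) or any other extra channels are dropped;
    a missing montage channel is a hard error.
    """
    index = {lab: i for i, lab in enumerate(rec.labels)}
    missing = [lab for lab in montage.labels if lab not in index]
    if missing:
        raise ValueError(f"recording is missing montage channels: {missing}")
    rows = [index[lab] for lab in montage.labels]
    return replace(rec, data=rec.data[rows], labels=montage.labels)


def _alpha_fir(fs: float, low: float, high: float, transition: float = 2.0) -> np.ndarray:
    """Linear-phase Hamming-window band-pass FIR for the analysis band.

    Cutoffs are placed half a transition width outside the band so the
    band edges sit in the flat passband; the tap count targets the
    requested transition width (Hamming: ~3.3 / (numtaps * fs)).
    """
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd -> type-I linear phase
    edges = [low - transition / 2, high + transition / 2]
    return signal.firwin(numtaps, edges, pass_zero=False, fs=fs)


def bandpass_alpha(rec: EEGRecording, low: float = 8.0, high: float = 13.0) -> EEGRecording:
    """Zero-phase FIR band-pass to the alpha band (default 8-13 Hz).

    The filter is applied forward-backward (``filtfilt``), so the net
    phase response is zero and the magnitude response is squared.
    """
    if rec.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for band edge {high} Hz"
        )
    taps = _alpha_fir(rec.fs, low, high)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    out = signal.filtfilt(taps, [1.0], rec.data, axis=1, padlen=padlen)
    return replace(rec, data=out)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Common-average reference: subtract the instantaneous channel mean."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=out)


def flip_hemispheres(
    rec: EEGRecording, montage: Montage = DEFAULT_MONTAGE, *, force: bool = False
) -> EEGRecording:
    """Swap homologous left/right channels for right-lesion subjects.

    After this step the left hemisphere is the lesioned side for every
    subject. Left-lesion recordings pass through unchanged. ``force``
    applies the swap regardless of lesion side (useful for testing the
    involution property).
    """
    if not force:
        if rec.lesion_side not in ("L", "R"):
            raise ValueError(f"unknown lesion side {rec.lesion_side!r}")
        if rec.lesion_side == "L":
            return rec
    index = {lab: i for i, lab in enumerate(rec.labels)}
    out = rec.data.copy()
    for l, r in montage.homologous_pairs:
        li, ri = index[l], index[r]
        out[[li, ri]] = rec.data[[ri, li]]
    side = rec.lesion_side
    if side == "R":
        side = "L"
    return replace(rec, data=out, lesion_side=side)


def segment_windows(
    rec: EEGRecording, window_s: float = 20.0, step_s: float = 5.0
) -> WindowSet:
    """Cut maximal fully-contained rectangular windows.

    The number of windows is floor((T - window) / step) + 1; a partial
    trailing window is discarded (no zero padding).
    """
    wlen = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    if rec.n_samples < wlen:
        raise ValueError(
            f"recording of {rec.duration:.1f}s shorter than {window_s}s window"
        )
    n_win = (rec.n_samples - wlen) // step + 1
    segments = tuple(
        rec.data[:, i * step: i * step + wlen].copy() for i in range(n_win)
    )
    return WindowSet(
        segments=segments,
        window_s=window_s,
        step_s=step_s,
        fs=rec.fs,
        labels=rec.labels,
        parent_id=rec.subject_id,
    )


def preprocess_recording(
    rec: EEGRecording,
    montage: Montage = DEFAULT_MONTAGE,
    band: tuple[float, float] = (8.0, 13.0),
    window_s: float = 20.0,
    step_s: float = 5.0,
    max_duration_s: float | None = 300.0,
    artifact_hook: Callable[[EEGRecording], EEGRecording] | None = None,
) -> WindowSet:
    """Run the full fixed-order preprocessing chain on one recording.

    ``max_duration_s`` truncates to the leading resting-state segment
    (default: first 5 minutes). ``artifact_hook`` is an optional callable
    (e.g. an ICA-based ocular-artifact remover) applied after channel
    selection; the default synthetic path generates artifact-free data
    and skips it.
    """
    if max_duration_s is not None:
        n = int(round(max_duration_s * rec.fs))
        if rec.n_samples > n:
            rec = replace(rec, data=rec.data[:, :n])
    rec = select_channels(rec, montage)
    if artifact_hook is not None:
        rec = artifact_hook(rec)
    rec = bandpass_alpha(rec, *band)
    rec = rereference_average(rec)
    rec = flip_hemispheres(rec, montage)
    return segment_windows(rec, window_s, step_s)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def write_delimited_recording(rec: EEGRecording, path: str | Path, sep: str = "\t") -> None:
    """Write a recording as a labelled channels-x-samples matrix.

    The first line is ``# fs=<Hz> lesion_side=<L|R> group=<..> session=<..>
    subject=<..>``; the second line is the tab-separated channel labels;
    each following line is one channel's samples.
    """
    path = Path(path)
    meta = (
        f"# fs={rec.fs} lesion_side={rec.lesion_side} group={rec.group} "
        f"session={rec.session} subject={rec.subject_id}"
    )
    with path.open("w") as fh:
        fh.write(meta + "\n")
        fh.write(sep.join(rec.labels) + "\n")
        np.savetxt(fh, rec.data, delimiter=sep, fmt="%.8g")


def read_delimited_recording(path: str | Path, sep: str = "\t") -> EEGRecording:
    """Read a recording written by :func:`write_delimited_recording`."""
    path = Path(path)
    with path.open() as fh:
        meta_line = fh.readline().strip()
        labels = tuple(fh.readline().strip().split(sep))
        data = np.loadtxt(fh, delimiter=sep, ndmin=2)
    meta: dict[str, str] = {}
    for token in meta_line.lstrip("# ").split():
        key, _, val = token.partition("=")
        meta[key] = val

    def _opt(key: str) -> str | None:
        val = meta.get(key)
        return None if val in (None, "None") else val

    return EEGRecording(
        data=data,
        labels=labels,
        fs=float(meta["fs"]),
        lesion_side=_opt("lesion_side"),
        group=_opt("group"),
        session=_opt("session"),
        subject_id=_opt("subject"),
    )
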
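"""Recording container and on-disk formats.

A :class:`Recording` is one subject's multichannel resting-state EEG:
a channels x time matrix plus sampling rate, channel labels, and a group
label.  Two interchange formats are supported:

* a plain CSV matrix dialect (rows = samples, columns = channels, header =
  channel labels) that needs nothing beyond pandas, and
* EDF, read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The 16 scalp positions of the reduced international 10-20 montage used
#: throughout this package.
CHANNELS_10_20 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "Fz", "Pz", "T5", "T6",
)

GROUP_YOUNGER = "younger"
GROUP_OLDER = "older"


@dataclass
class Recording:
    """One subject's multichannel signal (channels x time, arbitrary units)."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = CHANNELS_10_20
    group: str | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return Recording(
            samples=samples,
            sampling_rate=self.sampling_rate,
            channel_labels=self.channel_labels,
            group=self.group,
            subject_id=self.subject_id,
        )


def write_recording_csv(recording: Recording, path: str | Path) -> Path:
    """Write a recording in the CSV matrix dialect (rows=samples, cols=channels)."""
    path = Path(path)
    frame = pd.DataFrame(recording.samples.T, columns=list(recording.channel_labels))
    frame.to_csv(path, index=False, float_format="%.8g")
    return path


def read_recording_csv(
    path: str | Path,
    sampling_rate: float,
    group: str | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read the CSV matrix dialect written by :func:`write_recording_csv`."""
    path = Path(path)
    frame = pd.read_csv(path)
    return Recording(
        samples=frame.to_numpy().T,
        sampling_rate=sampling_rate,
        channel_labels=tuple(frame.columns),
        group=group,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def read_recording_edf(
    path: str | Path, group: str | None = None, subject_id: str | None = None
) -> Recording:
    """Read an EDF file via :mod:`mne` (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        samples=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        group=group,
        subject_id=subject_id if subject_id is not None else Path(path).stem,
    )


def write_cohort_csv(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write one CSV per subject plus a cohort manifest (subject_id, group)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        write_recording_csv(rec, out_dir / f"{rec.subject_id}.csv")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "sampling_rate": rec.sampling_rate,
                "n_samples": rec.n_samples,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort_csv(cohort_dir: str | Path) -> list[Recording]:
    """Read a cohort written by :func:`write_cohort_csv`."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    recordings = []
    for row in manifest.itertuples():
        recordings.append(
            read_recording_csv(
                cohort_dir / f"{row.subject_id}.csv",
                sampling_rate=float(row.sampling_rate),
                group=row.group,
                subject_id=str(row.subject_id),
            )
        )
    return recordings
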
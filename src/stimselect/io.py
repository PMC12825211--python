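"""Keypoint-series container and file formats.

Two text formats are supported: the DeepLabCut CSV dialect (three header
rows — scorer / bodyparts / coords — with x, y, likelihood triplets per
keypoint) and the timestamped sweep log emitted by the stimulation
multiplexer (one line per configuration change).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "KeypointSeries",
    "DEFAULT_BODYPARTS",
    "DLCFormatError",
    "SweepLogError",
    "read_dlc_csv",
    "write_dlc_csv",
    "read_sweep_log",
    "write_sweep_log",
    "validate_epochs",
]

#: Hindlimb keypoint schema: hip to toes, toe_1 proximal/medial through
#: toe_5 distal/lateral.
DEFAULT_BODYPARTS = (
    "hip",
    "knee",
    "ankle",
    "heel",
    "instep",
    "toe_1",
    "toe_2",
    "toe_3",
    "toe_4",
    "toe_5",
)

EPOCH_COLUMNS = (
    "label",
    "mode",
    "on_start",
    "on_stop",
    "off_start",
    "off_stop",
    "subject_id",
    "channels",
    "timestamp",
)


class DLCFormatError(ValueError):
    """Malformed pose-estimation CSV (wrong header dialect or schema)."""


class SweepLogError(ValueError):
    """Malformed or inconsistent sweep log / epoch table."""


@dataclass
class KeypointSeries:
    """Planar keypoint trajectories with per-cell tracking confidence.

    x, y and likelihood are (T, K) float arrays; masked (filtered) cells are
    NaN in x/y.  Coordinates are pixels unless converted downstream.
    """

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    bodyparts: tuple[str, ...] = DEFAULT_BODYPARTS
    fps: float = 60.0
    scorer: str = "stimselect"
    subject_id: str = "subject01"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (self.x.shape == self.y.shape == self.likelihood.shape):
            raise ValueError("x, y, likelihood must share shape (T, K)")
        if self.x.ndim != 2 or self.x.shape[0] < 1:
            raise ValueError("need a (T, K) array with T >= 1")
        if self.x.shape[1] != len(self.bodyparts):
            raise ValueError("K must match the number of bodyparts")
        finite = self.likelihood[np.isfinite(self.likelihood)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("likelihood must lie in [0, 1]")
        self.bodyparts = tuple(self.bodyparts)

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.x.shape[1]

    def coords(self) -> np.ndarray:
        """(T, K, 2) stacked coordinates."""
        return np.stack([self.x, self.y], axis=-1)

    def copy(self) -> "KeypointSeries":
        return replace(
            self, x=self.x.copy(), y=self.y.copy(), likelihood=self.likelihood.copy()
        )

    def mask(self) -> np.ndarray:
        """(T, K) boolean, True where a cell is masked (NaN coordinates)."""
        return np.isnan(self.x) | np.isnan(self.y)


# ---------------------------------------------------------------------------
# DeepLabCut CSV dialect
# ---------------------------------------------------------------------------

def write_dlc_csv(series: KeypointSeries, path) -> None:
    """Write a series in the three-header-row pose CSV dialect."""
    cols = pd.MultiIndex.from_product(
        [[series.scorer], list(series.bodyparts), ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.empty((series.n_frames, 3 * series.n_keypoints))
    data[:, 0::3] = series.x
    data[:, 1::3] = series.y
    data[:, 2::3] = series.likelihood
    frame = pd.DataFrame(data, columns=cols)
    frame.to_csv(path, index=True, index_label=None, float_format="%.17g")


def read_dlc_csv(path, fps: float = 60.0, subject_id: str = "subject01") -> KeypointSeries:
    """Read a pose CSV, validating the scorer/bodyparts/coords header rows."""
    try:
        frame = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise DLCFormatError(f"cannot parse pose CSV {path}: {exc}") from exc
    if frame.columns.nlevels != 3:
        raise DLCFormatError(
            "expected 3 header rows (scorer / bodyparts / coords), "
            f"got {frame.columns.nlevels}"
        )
    coords_row = [str(c).strip() for c in frame.columns.get_level_values(2)]
    if set(coords_row) != {"x", "y", "likelihood"}:
        raise DLCFormatError(
            "header row 3 (coords) must repeat x, y, likelihood; got "
            f"{sorted(set(coords_row))[:6]}"
        )
    bodyparts = list(dict.fromkeys(frame.columns.get_level_values(1)))
    scorer = str(frame.columns.get_level_values(0)[0])
    K, T = len(bodyparts), len(frame)
    x = np.empty((T, K))
    y = np.empty((T, K))
    lik = np.empty((T, K))
    for k, bp in enumerate(bodyparts):
        for name, out in (("x", x), ("y", y), ("likelihood", lik)):
            col = frame.loc[:, (scorer, bp, name)]
            if isinstance(col, pd.DataFrame):
                col = col.iloc[:, 0]
            out[:, k] = pd.to_numeric(col, errors="raise").to_numpy()
    return KeypointSeries(
        x=x, y=y, likelihood=lik, bodyparts=tuple(bodyparts), fps=fps,
        scorer=scorer, subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Sweep log (.txt)
# ---------------------------------------------------------------------------

def validate_epochs(epochs: pd.DataFrame) -> None:
    """Check epoch ordering and non-overlap; raise SweepLogError otherwise."""
    missing = set(("label", "on_start", "on_stop", "off_start", "off_stop")) - set(
        epochs.columns
    )
    if missing:
        raise SweepLogError(f"epoch table missing columns: {sorted(missing)}")
    prev_stop = -1
    for row in epochs.itertuples(index=False):
        if not (row.on_start < row.on_stop <= row.off_start < row.off_stop):
            raise SweepLogError(
                f"epoch for configuration {row.label} has inconsistent spans"
            )
        if row.on_start < prev_stop:
            raise SweepLogError(
                f"epochs overlap or are out of order at configuration {row.label}"
            )
        prev_stop = row.off_stop


def write_sweep_log(epochs: pd.DataFrame, path) -> None:
    """Write one timestamped line per configuration change."""
    validate_epochs(epochs)
    lines = ["# stimselect sweep log v1"]
    for row in epochs.itertuples(index=False):
        ts = getattr(row, "timestamp", "1970-01-01T00:00:00")
        subject = getattr(row, "subject_id", "subject01")
        channels = getattr(row, "channels", "")
        lines.append(
            f"{ts}\tmode={row.mode}\tlabel={row.label}\tchannels={channels}\t"
            f"on={row.on_start}:{row.on_stop}\toff={row.off_start}:{row.off_stop}\t"
            f"subject={subject}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sweep_log(path) -> pd.DataFrame:
    """Parse a sweep log back into an epoch table."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                ts = parts[0]
                kv = dict(p.split("=", 1) for p in parts[1:])
                on0, on1 = kv["on"].split(":")
                off0, off1 = kv["off"].split(":")
                rows.append(
                    {
                        "label": int(kv["label"]),
                        "mode": kv["mode"],
                        "on_start": int(on0),
                        "on_stop": int(on1),
                        "off_start": int(off0),
                        "off_stop": int(off1),
                        "subject_id": kv.get("subject", "subject01"),
                        "channels": kv.get("channels", ""),
                        "timestamp": ts,
                    }
                )
            except (KeyError, ValueError) as exc:
                raise SweepLogError(f"bad sweep-log line {lineno}: {line!r}") from exc
    epochs = pd.DataFrame(rows, columns=list(EPOCH_COLUMNS))
    validate_epochs(epochs)
    return epochs
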
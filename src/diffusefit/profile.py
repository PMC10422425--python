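"""Reflectance-profile container and delimited-text I/O.

A profile is the signal of one acquisition: detected intensity versus
radial distance from the light entry point, for one colour channel.  The
canonical on-disk form is a long-format delimited table with one row per
detector element::

    distance_mm,intensity,channel,record_id
    0.25,1523.4,R,rec0
    ...

Comma and tab delimiters are auto-detected.  Distances are always
serialized in mm.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = ["ReflectanceProfile", "read_profiles", "write_profiles", "CHANNEL_WAVELENGTHS_NM"]

#: Peak wavelength of each LED channel of the acquisition device, nm.
CHANNEL_WAVELENGTHS_NM = {"R": 630, "G": 525, "B": 472}

_COLUMNS = ["distance_mm", "intensity", "channel", "record_id"]


@dataclass
class ReflectanceProfile:
    """One spatially resolved reflectance record.

    Attributes
    ----------
    distances : ndarray
        Radial source-detector distances, mm, strictly increasing.
    intensities : ndarray
        Detected intensity per detector, arbitrary units, finite.
    channel : str
        Colour-channel label ("R", "G" or "B" for the stock device).
    record_id : str
        Identifier of the acquisition this profile belongs to.
    """

    distances: NDArray[np.float64]
    intensities: NDArray[np.float64]
    channel: str = "R"
    record_id: str = "rec0"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.distances.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("distances and intensities must be 1-D")
        if self.distances.shape != self.intensities.shape:
            raise ValueError(
                f"length mismatch: {self.distances.size} distances vs "
                f"{self.intensities.size} intensities"
            )
        if self.distances.size > 1 and np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        if not np.all(np.isfinite(self.distances)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise ValueError("distances and intensities must be finite")

    def __len__(self) -> int:
        return self.distances.size

    def with_intensities(self, intensities: NDArray[np.float64]) -> "ReflectanceProfile":
        """Copy of this profile with new intensities on the same grid."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    @property
    def wavelength_nm(self) -> int | None:
        return CHANNEL_WAVELENGTHS_NM.get(self.channel)


def _detect_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def read_profiles(path: str | Path, sep: str | None = None) -> list[ReflectanceProfile]:
    """Read profiles from a long-format delimited text file.

    Parameters
    ----------
    path : path
        File with header columns distance_mm, intensity, channel,
        record_id; comma- or tab-delimited (auto-detected when ``sep``
        is None).

    Returns
    -------
    list of ReflectanceProfile
        One profile per (record_id, channel) pair, in file order.

    Raises
    ------
    ValueError
        On missing columns, non-numeric cells or non-monotone distances,
        naming the offending line.
    """
    path = Path(path)
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"channel": str, "record_id": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (line 1)")
    for col in ("distance_mm", "intensity"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = numeric
    if df["distance_mm"].isna().any() or df["intensity"].isna().any():
        line = int(df[["distance_mm", "intensity"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}: missing numeric value at line {line}")

    profiles: list[ReflectanceProfile] = []
    for (rec, chan), grp in df.groupby(["record_id", "channel"], sort=False):
        d = grp["distance_mm"].to_numpy()
        if d.size > 1 and np.any(np.diff(d) <= 0):
            pos = int(np.flatnonzero(np.diff(d) <= 0)[0])
            line = int(grp.index[pos + 1]) + 2
            raise ValueError(
                f"{path}: non-monotone distance for record {rec!r} "
                f"channel {chan!r} at line {line}"
            )
        profiles.append(
            ReflectanceProfile(
                distances=d,
                intensities=grp["intensity"].to_numpy(),
                channel=str(chan),
                record_id=str(rec),
            )
        )
    return profiles


def write_profiles(
    profiles: Iterable[ReflectanceProfile], path: str | Path, sep: str = ","
) -> None:
    """Write profiles as a long-format delimited text file.

    Deterministic column order and 12-significant-digit formatting, so a
    write -> read round trip preserves values to that precision and the
    byte output is stable for a fixed input.
    """
    frames = [
        pd.DataFrame(
            {
                "distance_mm": p.distances,
                "intensity": p.intensities,
                "channel": p.channel,
                "record_id": p.record_id,
            }
        )
        for p in profiles
    ]
    if not frames:
        raise ValueError("no profiles to write")
    df = pd.concat(frames, ignore_index=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep=sep, index=False, float_format="%.12g", lineterminator="\n")
    Path(path).write_text(buf.getvalue())
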
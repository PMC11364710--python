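"""DICOM ingestion of TI scout series.

Vendors expose the scout inversion time under different tags: GE under
``InversionTime`` (0018,0082), Siemens and Philips under ``TriggerTime``
(0018,1060).  Loading normalises photometric interpretation (MONOCHROME1
is inverted so higher stored value always means brighter signal), applies
RescaleSlope/Intercept, sorts frames by ascending TI (InstanceNumber breaks
exact ties, first occurrence kept), and returns a :class:`TIScoutSeries`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom

from .series import TIScoutSeries

__all__ = ["TIScoutSeries", "extract_ti", "load_series", "MissingMetadataError", "AmbiguousInputError"]


class MissingMetadataError(KeyError):
    """Raised when no inversion-time tag can be found for a frame."""


class AmbiguousInputError(ValueError):
    """Raised when a directory mixes multiple DICOM series."""


def extract_ti(frame_metadata, vendor: str = "unknown") -> float:
    """Read the inversion time (ms) from a frame's DICOM metadata.

    ``ge`` reads InversionTime; ``siemens`` and ``philips`` read TriggerTime;
    ``unknown`` tries InversionTime first, then TriggerTime.
    """
    order = {
        "ge": ("InversionTime",),
        "siemens": ("TriggerTime",),
        "philips": ("TriggerTime",),
        "unknown": ("InversionTime", "TriggerTime"),
    }
    try:
        tags = order[vendor]
    except KeyError:
        raise ValueError(f"unknown vendor {vendor!r}") from None
    for tag in tags:
        value = getattr(frame_metadata, tag, None)
        if value is not None:
            return float(value)
    series = getattr(frame_metadata, "SeriesInstanceUID", "<unknown series>")
    frame = getattr(frame_metadata, "InstanceNumber", "<unknown frame>")
    raise MissingMetadataError(
        f"no inversion-time tag ({' or '.join(tags)}) in series {series}, frame {frame}"
    )


def _frame_pixels(ds) -> np.ndarray:
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        pixels = pixels.max() - pixels  # invert so bright = high signal
    return pixels


def _guess_vendor(manufacturer: str) -> str:
    m = manufacturer.lower()
    if "ge" in m.split() or m.startswith("ge"):
        return "ge"
    if "siemens" in m:
        return "siemens"
    if "philips" in m:
        return "philips"
    return "unknown"


def load_series(directory, vendor: str | None = None) -> TIScoutSeries:
    """Load every DICOM file in ``directory`` as one TI scout series.

    Frames are sorted by ascending TI; frames with duplicate TI collapse to
    the one with the lowest InstanceNumber.  A directory holding more than
    one SeriesInstanceUID is rejected as ambiguous.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")

    records = []
    series_uids = set()
    for path in files:
        try:
            ds = pydicom.dcmread(path)
        except Exception as exc:
            raise IOError(f"unreadable DICOM file {path}: {exc}") from exc
        series_uids.add(str(getattr(ds, "SeriesInstanceUID", "")))
        frame_vendor = vendor or _guess_vendor(str(getattr(ds, "Manufacturer", "")))
        ti = extract_ti(ds, frame_vendor)
        instance = int(getattr(ds, "InstanceNumber", 0))
        records.append((ti, instance, _frame_pixels(ds), frame_vendor))
    if len(series_uids) > 1:
        raise AmbiguousInputError(
            f"{directory} contains {len(series_uids)} series: {sorted(series_uids)}"
        )

    records.sort(key=lambda r: (r[0], r[1]))
    deduped = []
    seen_tis: set[float] = set()
    for ti, instance, pixels, frame_vendor in records:
        if ti in seen_tis:
            continue  # exact TI tie: keep first (lowest InstanceNumber)
        seen_tis.add(ti)
        deduped.append((ti, pixels, frame_vendor))

    frames = np.stack([r[1] for r in deduped])
    tis = np.array([r[0] for r in deduped], dtype=float)
    return TIScoutSeries(
        frames=frames,
        ti_values=tis,
        vendor=deduped[0][2],
        series_id=next(iter(series_uids)),
    )
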
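"""Independent beam-timing verification from EPID cine frames.

The electronic portal imaging device (EPID) acquires continuous frames
during gated delivery (cine mode, nominally 25 fps / 0.04 s). For each
frame the mean pixel intensity inside a square region of interest centered
on the beam axis is computed and normalized to the series maximum; frames
strictly above 50% of that maximum are beam-on, contiguous runs become
beam-on segments, and each segment's duration is its frame count times the
frame period. This gives a log-independent estimate of the trigger-on
durations that the log analysis reports.

Input is either DICOM RT IMAGE files (one per frame or multi-frame) or a
raw frame-stack fixture: ``frames.npy`` plus a JSON sidecar carrying
``frame_period_s``, ``pixel_spacing_cm``, ``sid_cm`` and ``sad_cm``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._stats import AggregateStats, aggregate_stats
from .errors import ConfigurationError, EmptyInputError, ParameterError

__all__ = [
    "RoiSpec",
    "FrameStack",
    "EpidFrameSeries",
    "load_cine_frames",
    "write_raw_stack",
    "write_dicom_stack",
    "compute_roi_series",
    "detect_beam_on_frames",
    "epid_beam_durations",
    "compare_epid_vs_log",
]

RT_IMAGE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.1"


@dataclass
class RoiSpec:
    """Square ROI defined at the isocenter plane and projected to the imager.

    ``side_cm_at_iso`` is the side length at isocenter (default 5.0 cm);
    the projected side on the imager is ``side * sid / sad``. ``center``
    is a (row, col) pixel pair, or None for the beam axis (frame center).
    """

    side_cm_at_iso: float = 5.0
    center: tuple[int, int] | None = None
    sad_cm: float = 100.0
    sid_cm: float = 150.0

    def __post_init__(self):
        if self.side_cm_at_iso <= 0:
            raise ParameterError("ROI side must be positive")
        if not self.sid_cm >= self.sad_cm > 0:
            raise ParameterError("require sid_cm >= sad_cm > 0")

    @property
    def projected_side_cm(self) -> float:
        return self.side_cm_at_iso * self.sid_cm / self.sad_cm


@dataclass
class FrameStack:
    """Ordered cine frames with acquisition geometry."""

    frames: np.ndarray  # (n_frames, rows, cols)
    frame_times: np.ndarray  # seconds, uniform within 10%
    pixel_spacing_cm: float
    sid_cm: float
    sad_cm: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (n, rows, cols) array")
        if self.frame_times.size != self.frames.shape[0]:
            raise ParameterError("frame_times length must match frame count")
        dt = np.diff(self.frame_times)
        if dt.size and (np.any(dt <= 0) or
                        np.max(np.abs(dt - np.median(dt))) > 0.1 * np.median(dt)):
            raise ParameterError("frame times must be uniform within 10%")

    @property
    def frame_period(self) -> float:
        if self.frame_times.size < 2:
            raise ParameterError("cannot infer frame period from < 2 frames")
        return float(np.median(np.diff(self.frame_times)))


@dataclass
class EpidFrameSeries:
    """Per-frame ROI mean intensities with timing."""

    frame_times: np.ndarray
    frame_period: float
    roi_mean: np.ndarray
    roi_mean_norm: np.ndarray


def _dicom_time_to_seconds(value: str) -> float:
    """DICOM TM 'HHMMSS.FFFFFF' to seconds since midnight."""
    s = str(value)
    hh = int(s[0:2])
    mm = int(s[2:4])
    ss = float(s[4:]) if len(s) > 4 else 0.0
    return hh * 3600 + mm * 60 + ss


def load_cine_frames(
    path: str | os.PathLike,
    frame_period: float | None = None,
    pixel_spacing_cm: float | None = None,
    sid_cm: float | None = None,
    sad_cm: float | None = None,
) -> FrameStack:
    """Load an EPID cine acquisition from a directory.

    A directory containing ``frames.npy`` + ``sidecar.json`` is read as a
    raw fixture stack; otherwise every ``*.dcm`` file is read as a DICOM
    RT IMAGE (single- or multi-frame). Frames are ordered by acquisition
    time when content/acquisition times are tagged, else by instance
    number. Geometry (pixel spacing, SID, SAD) comes from the metadata
    when present, falling back to the explicit arguments; frames without
    any timing source use a uniform grid at ``frame_period``.
    """
    path = Path(os.fspath(path))
    if (path / "frames.npy").exists():
        return _load_raw_stack(path, frame_period, pixel_spacing_cm, sid_cm, sad_cm)
    dcm_files = sorted(path.glob("*.dcm")) if path.is_dir() else [path]
    if not dcm_files:
        raise ConfigurationError(f"no frames found under {path}")
    return _load_dicom_stack(dcm_files, frame_period, pixel_spacing_cm, sid_cm, sad_cm)


def _load_raw_stack(path, frame_period, pixel_spacing_cm, sid_cm, sad_cm):
    frames = np.load(path / "frames.npy")
    with open(path / "sidecar.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    fp = meta.get("frame_period_s", frame_period)
    if fp is None:
        raise ConfigurationError("raw stack has no frame_period_s and none was given")
    return FrameStack(
        frames=frames,
        frame_times=np.arange(frames.shape[0]) * float(fp),
        pixel_spacing_cm=float(meta.get("pixel_spacing_cm", pixel_spacing_cm or 0.0336)),
        sid_cm=float(meta.get("sid_cm", sid_cm or 150.0)),
        sad_cm=float(meta.get("sad_cm", sad_cm or 100.0)),
    )


def _load_dicom_stack(files, frame_period, pixel_spacing_cm, sid_cm, sad_cm):
    import logging

    import pydicom

    logger = logging.getLogger(__name__)
    entries = []  # (sort_key, time_or_None, frame_array, geometry)
    for f in files:
        ds = pydicom.dcmread(f)
        arr = ds.pixel_array.astype(float)
        spacing = None
        if "ImagePlanePixelSpacing" in ds:
            spacing = float(ds.ImagePlanePixelSpacing[0]) / 10.0  # mm -> cm
        elif "PixelSpacing" in ds:
            spacing = float(ds.PixelSpacing[0]) / 10.0
        sid = float(ds.RTImageSID) / 10.0 if "RTImageSID" in ds else None
        sad = (float(ds.RadiationMachineSAD) / 10.0
               if "RadiationMachineSAD" in ds else None)
        tm = None
        for tag in ("ContentTime", "AcquisitionTime"):
            if tag in ds and str(getattr(ds, tag)).strip():
                tm = _dicom_time_to_seconds(getattr(ds, tag))
                break
        inst = int(getattr(ds, "InstanceNumber", 0) or 0)
        if arr.ndim == 3:  # multi-frame object
            for k in range(arr.shape[0]):
                entries.append(((inst, k), tm, arr[k], (spacing, sid, sad)))
        else:
            entries.append(((inst, 0), tm, arr, (spacing, sid, sad)))
    if all(e[1] is not None for e in entries):
        entries.sort(key=lambda e: (e[1], e[0]))
    else:
        entries.sort(key=lambda e: e[0])
    shapes = {e[2].shape for e in entries}
    geoms = {e[3] for e in entries}
    if len(shapes) > 1 or len(geoms) > 1:
        raise ConfigurationError(
            f"mixed image geometries in cine stack: shapes {shapes}, geometry {geoms}"
        )
    spacing, sid, sad = entries[0][3]
    if spacing is None:
        if pixel_spacing_cm is None:
            raise ConfigurationError("no pixel spacing in metadata or config")
        logger.info("pixel spacing missing from metadata; using config value")
        spacing = pixel_spacing_cm
    if sid is None:
        if sid_cm is None:
            raise ConfigurationError("no SID in metadata or config")
        logger.info("SID missing from metadata; using config value")
        sid = sid_cm
    if sad is None:
        if sad_cm is None:
            raise ConfigurationError("no SAD in metadata or config")
        logger.info("SAD missing from metadata; using config value")
        sad = sad_cm
    times = [e[1] for e in entries]
    if any(tm is None for tm in times) or len(set(times)) < len(times):
        if frame_period is None:
            raise ConfigurationError(
                "frames carry no usable per-frame times and no frame_period was given"
            )
        frame_times = np.arange(len(entries)) * frame_period
    else:
        t0 = times[0]
        frame_times = np.asarray([tm - t0 for tm in times])
    return FrameStack(
        frames=np.stack([e[2] for e in entries]),
        frame_times=frame_times,
        pixel_spacing_cm=spacing,
        sid_cm=sid,
        sad_cm=sad,
    )


def write_raw_stack(stack: FrameStack, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a stack in the raw fixture format (frames.npy + sidecar.json)."""
    out = Path(os.fspath(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "frames.npy", stack.frames)
    sidecar = {
        "frame_period_s": stack.frame_period,
        "pixel_spacing_cm": stack.pixel_spacing_cm,
        "sid_cm": stack.sid_cm,
        "sad_cm": stack.sad_cm,
        "n_frames": int(stack.frames.shape[0]),
    }
    with open(out / "sidecar.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"frames": str(out / "frames.npy"), "sidecar": str(out / "sidecar.json")}


def write_dicom_stack(stack: FrameStack, out_dir: str | os.PathLike) -> list[str]:
    """Write each frame as a minimal DICOM RT IMAGE file (for fixtures)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    out = Path(os.fspath(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    series_uid = generate_uid()
    for i in range(stack.frames.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID(RT_IMAGE_SOP_CLASS)
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "RTIMAGE"
        ds.InstanceNumber = i + 1
        tm = stack.frame_times[i]
        hh, rem = divmod(tm, 3600)
        mm, ss = divmod(rem, 60)
        ds.ContentTime = f"{int(hh):02d}{int(mm):02d}{ss:09.6f}"
        ds.ImagePlanePixelSpacing = [stack.pixel_spacing_cm * 10.0] * 2
        ds.RTImageSID = stack.sid_cm * 10.0
        ds.RadiationMachineSAD = stack.sad_cm * 10.0
        frame = np.clip(stack.frames[i], 0, 65535).astype(np.uint16)
        ds.Rows, ds.Columns = frame.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = frame.tobytes()
        p = out / f"frame_{i:04d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(str(p))
    return paths


def compute_roi_series(
    stack: FrameStack,
    roi: RoiSpec | None = None,
    median_filter: bool = False,
) -> EpidFrameSeries:
    """Per-frame mean intensity over the projected ROI, series-normalized.

    The ROI pixel extent is ``round(projected_side / pixel_spacing)``,
    centered on ``roi.center`` (frame center when None). ``median_filter``
    applies a 3x3 per-frame median filter before averaging (noise
    reduction; off by default so the documented pipeline is the default).
    """
    roi = roi or RoiSpec(sid_cm=stack.sid_cm, sad_cm=stack.sad_cm)
    n, rows, cols = stack.frames.shape
    n_px = max(1, int(round(roi.projected_side_cm / stack.pixel_spacing_cm)))
    cr, cc = roi.center if roi.center is not None else (rows // 2, cols // 2)
    r0 = cr - n_px // 2
    c0 = cc - n_px // 2
    r1, c1 = r0 + n_px, c0 + n_px
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise ParameterError(
            f"ROI ({n_px}x{n_px} px at ({cr},{cc})) exceeds frame ({rows}x{cols})"
        )
    frames = stack.frames
    if median_filter:
        from scipy.ndimage import median_filter as _mf

        frames = np.stack([_mf(f, size=3) for f in frames])
    roi_mean = frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    peak = roi_mean.max()
    if peak <= 0:
        raise ParameterError("ROI series maximum is not positive; cannot normalize")
    return EpidFrameSeries(
        frame_times=stack.frame_times.copy(),
        frame_period=stack.frame_period,
        roi_mean=roi_mean,
        roi_mean_norm=roi_mean / peak,
    )


def detect_beam_on_frames(
    series: EpidFrameSeries, threshold_fraction: float = 0.5
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Threshold the normalized ROI series into beam-on frames and segments.

    A frame is beam-on iff its normalized ROI mean is strictly above
    ``threshold_fraction``; contiguous runs become (start, end) index
    pairs, end inclusive.
    """
    mask = series.roi_mean_norm > threshold_fraction
    segments: list[tuple[int, int]] = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            segments.append((i, j))
            i = j + 1
        else:
            i += 1
    return mask, segments


def epid_beam_durations(
    segments: list[tuple[int, int]],
    frame_period: float,
) -> list[float]:
    """Duration of each beam-on segment: frame count x frame period."""
    if frame_period <= 0:
        raise ParameterError("frame_period must be positive")
    return [(end - start + 1) * frame_period for start, end in segments]


def epid_duration_stats(
    durations: list[float], sd_mode: str = "population"
) -> AggregateStats:
    if not durations:
        raise EmptyInputError("no EPID beam-on segments to aggregate")
    return aggregate_stats(durations, sd_mode=sd_mode)


@dataclass
class EpidLogComparison:
    mode: str  # "paired" or "mean"
    diffs: list[float] | None
    diff_stats: AggregateStats | None
    mean_diff: float


def compare_epid_vs_log(
    epid_durations: list[float],
    log_durations: list[float],
    sd_mode: str = "population",
) -> EpidLogComparison:
    """EPID-derived vs log-derived beam-on durations.

    With matching counts, per-cycle differences (EPID - log, paired by
    order) are aggregated; otherwise the difference of means is reported.
    """
    if not epid_durations and not log_durations:
        raise EmptyInputError("no durations to compare on either side")
    if not epid_durations or not log_durations:
        raise EmptyInputError("need at least one duration on each side")
    if len(epid_durations) == len(log_durations):
        diffs = [e - l for e, l in zip(epid_durations, log_durations)]
        st = aggregate_stats(diffs, sd_mode=sd_mode)
        return EpidLogComparison("paired", diffs, st, st.mean)
    mean_diff = float(np.mean(epid_durations) - np.mean(log_durations))
    return EpidLogComparison("mean", None, None, mean_diff)
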
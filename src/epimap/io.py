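"""Movie container and file I/O for optical-mapping recordings.

Movies are time-ordered frame stacks of fluorescence counts with two pieces of
acquisition metadata that the whole pipeline depends on: the frame rate (Hz)
and the pixel pitch (µm/pixel). On disk a movie is either a multi-frame TIFF
(uint16, metadata in the ImageDescription tag) or an HDF5 file with dataset
``frames`` and attributes ``frame_rate_hz`` / ``pixel_pitch_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

__all__ = ["MovieStack", "read_movie", "write_movie"]


@dataclass
class MovieStack:
    """A fluorescence movie: ``frames`` is a (T, H, W) array of counts."""

    frames: np.ndarray
    frame_rate: float  # Hz
    pixel_pitch: float  # µm per pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T, H, W) with T >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def dt_ms(self) -> float:
        """Frame interval in milliseconds."""
        return 1000.0 / self.frame_rate

    @property
    def times_ms(self) -> np.ndarray:
        """Frame times in ms; the first frame is t = 0."""
        return np.arange(self.n_frames) * self.dt_ms


def write_movie(movie: MovieStack, path: str) -> None:
    """Write a movie as multi-frame TIFF (``.tif``) or HDF5 (``.h5``)."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        data = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max)
        desc = json.dumps(
            {
                "frame_rate_hz": movie.frame_rate,
                "pixel_pitch_um": movie.pixel_pitch,
                **{k: v for k, v in movie.meta.items() if _jsonable(v)},
            }
        )
        tifffile.imwrite(path, data.astype(np.uint16), description=desc)
    elif path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("frames", data=movie.frames.astype(np.float32))
            ds.attrs["frame_rate_hz"] = movie.frame_rate
            ds.attrs["pixel_pitch_um"] = movie.pixel_pitch
            for k, v in movie.meta.items():
                if _jsonable(v):
                    ds.attrs[k] = v
    else:
        raise ValueError(f"unsupported movie format: {path}")


def read_movie(path: str) -> MovieStack:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        fr = float(meta.pop("frame_rate_hz"))
        pitch = float(meta.pop("pixel_pitch_um"))
        return MovieStack(frames.astype(np.float64), fr, pitch, meta)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            ds = f["frames"]
            frames = ds[...].astype(np.float64)
            meta = {k: v for k, v in ds.attrs.items()}
        fr = float(meta.pop("frame_rate_hz"))
        pitch = float(meta.pop("pixel_pitch_um"))
        return MovieStack(frames, fr, pitch, meta)
    raise ValueError(f"unsupported movie format: {path}")


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool))
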
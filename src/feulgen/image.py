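"""Absorbance images and transmittance conversion.

The measurement substrate of scanning microspectrophotometry is a grid of
per-pixel optical densities (absorbances).  Instruments of the scanning-spot
type report absorbance directly; file-based inputs (8-bit transmittance
images) are converted through the Beer-Lambert relation
``OD = log10(I_white / I)`` against a recorded white reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

#: µm per pixel edge of the scanning spot; each pixel covers 0.25 µm².
DEFAULT_PIXEL_PITCH_UM = 0.5

_SOURCES = frozenset({"measured-absorbance", "converted-from-transmittance", "synthetic"})


@dataclass(eq=False)
class AbsorbanceImage:
    """2-D grid of optical densities with a physical pixel pitch.

    Parameters
    ----------
    values
        2-D float array of per-pixel absorbance; finite and >= 0.
    pixel_pitch_um
        Edge length of one pixel in µm (default 0.5, i.e. 0.25 µm² per pixel).
    source
        Provenance tag: ``measured-absorbance``, ``converted-from-transmittance``
        or ``synthetic``.
    saturated
        Optional boolean mask of pixels whose raw intensity hit the
        conversion floor (transmittance inputs only).
    """

    values: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    source: str = "measured-absorbance"
    saturated: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"absorbance image must be 2-D, got {self.values.ndim}-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("absorbance values must be finite")
        if np.any(self.values < 0):
            raise ValueError("absorbance values must be >= 0")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {sorted(_SOURCES)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_pitch_um**2


def absorbance_map(
    raw: np.ndarray,
    white_reference: float,
    *,
    intensity_floor: float = 1.0,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> AbsorbanceImage:
    """Convert a transmittance (intensity) image to optical density.

    ``OD = log10(white_reference / intensity)``.  Intensities at or below
    ``intensity_floor`` (default 1 count) cannot be trusted — the detector is
    effectively saturated in absorbance — so they are clipped to the floor
    before conversion and flagged in the result's ``saturated`` mask.

    Raises
    ------
    ValueError
        If ``white_reference`` is not positive or intensities exceed it.
    """
    if white_reference <= 0:
        raise ValueError("white_reference must be positive")
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0) or np.any(raw > white_reference):
        raise ValueError("raw intensities must lie in [0, white_reference]")
    saturated = raw <= intensity_floor
    clipped = np.maximum(raw, intensity_floor)
    od = np.log10(white_reference / clipped)
    # white pixels give exactly 0; numerical negatives cannot occur since
    # clipped <= white_reference
    return AbsorbanceImage(
        od,
        pixel_pitch_um=pixel_pitch_um,
        source="converted-from-transmittance",
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# file IO


def write_absorbance_tiff(img: AbsorbanceImage, path: str | Path) -> None:
    """Write absorbance as 32-bit float TIFF; pitch stored in the description tag."""
    meta = {"pixel_pitch_um": img.pixel_pitch_um, "source": img.source}
    tifffile.imwrite(Path(path), img.values.astype(np.float32), description=json.dumps(meta))


def read_absorbance_tiff(path: str | Path, pixel_pitch_um: float | None = None) -> AbsorbanceImage:
    """Read a float-absorbance TIFF written by :func:`write_absorbance_tiff`.

    ``pixel_pitch_um`` overrides the value recorded in the file; if neither is
    available the 0.5 µm default applies.
    """
    with tifffile.TiffFile(Path(path)) as tif:
        values = tif.asarray().astype(float)
        desc = tif.pages[0].description
    pitch = pixel_pitch_um
    source = "measured-absorbance"
    if desc:
        try:
            meta = json.loads(desc)
            if pitch is None:
                pitch = float(meta.get("pixel_pitch_um", DEFAULT_PIXEL_PITCH_UM))
            source = meta.get("source", source)
        except (json.JSONDecodeError, TypeError, ValueError):
            pass
    if pitch is None:
        pitch = DEFAULT_PIXEL_PITCH_UM
    return AbsorbanceImage(np.maximum(values, 0.0), pixel_pitch_um=pitch, source=source)


def write_transmittance_png(
    img: AbsorbanceImage, path: str | Path, *, white_reference: float = 255.0
) -> None:
    """Write an 8-bit transmittance PNG plus a JSON sidecar with the white reference."""
    path = Path(path)
    intensity = np.clip(np.round(white_reference * 10.0 ** (-img.values)), 0, 255)
    iio.imwrite(path, intensity.astype(np.uint8))
    sidecar = {"white_reference": white_reference, "pixel_pitch_um": img.pixel_pitch_um}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_transmittance_image(
    path: str | Path,
    white_reference: float | None = None,
    pixel_pitch_um: float | None = None,
) -> AbsorbanceImage:
    """Read an 8-bit transmittance PNG/TIFF and convert to absorbance.

    The white reference and pixel pitch come from a sidecar ``<name>.json``
    unless given explicitly.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if white_reference is None:
            white_reference = float(meta["white_reference"])
        if pixel_pitch_um is None:
            pixel_pitch_um = float(meta.get("pixel_pitch_um", DEFAULT_PIXEL_PITCH_UM))
    if white_reference is None:
        raise ValueError(f"no white reference for {path}: pass one or provide {sidecar.name}")
    raw = np.asarray(iio.imread(path), dtype=float)
    if raw.ndim == 3:  # grayscale stored as RGB
        raw = raw.mean(axis=2)
    return absorbance_map(
        raw, white_reference, pixel_pitch_um=pixel_pitch_um or DEFAULT_PIXEL_PITCH_UM
    )
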
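"""Data model, configuration parsing, dataset discovery, and TIFF + sidecar I/O.

Images are held as 5-D rasters indexed ``[t][c][z][y][x]``; absent axes have
extent 1.  Physical calibration (pixel size, Z step, frame interval, channel
wavelengths, optional wavelength axis and stage positions) lives in a
plain-text sidecar next to each multi-page TIFF, which always takes precedence
over anything embedded in the TIFF itself.

Coordinate convention: 0-based indices; the physical coordinate of pixel *i*
along an axis is ``i * spacing`` (pixel-centre convention).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "SystemConfig",
    "Dataset",
    "ConfigError",
    "DatasetError",
    "SidecarError",
    "parse_config",
    "discover_dataset",
    "read_stack",
    "write_stack",
    "SIDECAR_KEYS",
]


class ConfigError(ValueError):
    """Raised for malformed or incomplete system configuration files."""


class DatasetError(ValueError):
    """Raised for unusable recording directories (spaces, duplicates...)."""


class SidecarError(ValueError):
    """Raised when a TIFF sidecar is missing, malformed or inconsistent."""


#: Calibration keys understood in a ``<stem>.meta.yaml`` / ``.meta.json`` sidecar.
SIDECAR_KEYS = (
    "pixel_size_xy_um",
    "z_step_um",
    "frame_interval_s",
    "channel_wavelengths_nm",
    "wavelength_axis_nm",
    "stage_positions_um",
    "bit_depth",
    "size_t",
    "size_c",
    "size_z",
    "axes_sign",
)


@dataclass
class ImageStack:
    """An N-dimensional intensity raster with physical calibration.

    Parameters
    ----------
    pixels
        Array indexed ``[t, c, z, y, x]``; absent axes have extent 1.
    pixel_size_xy
        Lateral pixel size in µm/pixel.
    z_step
        Axial step in µm (0 if there is no Z axis).
    frame_interval
        Time between frames in seconds (0 if there is no T axis).
    channel_wavelengths
        One excitation/detection wavelength (nm) per channel.
    wavelength_axis
        For lambda scans: detection wavelength (nm) per T index.
    stage_positions
        Commanded stage (x, y) position in µm per T index.
    bit_depth
        Detector bit depth (8/12/16); used for saturation checks.
    axes_sign
        Sign convention mapping commanded stage motion to image motion;
        the default (-1, -1) means the specimen moves opposite to the field.
    """

    pixels: np.ndarray
    pixel_size_xy: float = 1.0
    z_step: float = 0.0
    frame_interval: float = 0.0
    channel_wavelengths: list = field(default_factory=lambda: [0.0])
    wavelength_axis: Optional[list] = None
    stage_positions: Optional[list] = None
    bit_depth: int = 16
    axes_sign: tuple = (-1, -1)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"pixels must be 5-D [t][c][z][y][x], got {self.pixels.ndim}-D"
            )
        if any(e < 1 for e in self.pixels.shape):
            raise ValueError("all axis extents must be >= 1")
        t, c, z, y, x = self.pixels.shape
        if len(self.channel_wavelengths) != c:
            raise ValueError(
                f"channel_wavelengths has {len(self.channel_wavelengths)} entries "
                f"for {c} channels"
            )
        if self.wavelength_axis is not None and len(self.wavelength_axis) != t:
            raise ValueError(
                f"wavelength_axis has {len(self.wavelength_axis)} entries "
                f"for T extent {t}"
            )
        if self.stage_positions is not None and len(self.stage_positions) != t:
            raise ValueError(
                f"stage_positions has {len(self.stage_positions)} entries "
                f"for T extent {t}"
            )

    # -- axis extents ------------------------------------------------------
    @property
    def size_t(self) -> int:
        return self.pixels.shape[0]

    @property
    def size_c(self) -> int:
        return self.pixels.shape[1]

    @property
    def size_z(self) -> int:
        return self.pixels.shape[2]

    @property
    def size_y(self) -> int:
        return self.pixels.shape[3]

    @property
    def size_x(self) -> int:
        return self.pixels.shape[4]

    def frame(self, t: int = 0, c: int = 0, z: int = 0) -> np.ndarray:
        """Return the 2-D (y, x) plane at the given t/c/z indices."""
        return self.pixels[t, c, z]

    def xz_plane(self, t: int = 0, c: int = 0) -> np.ndarray:
        """Return the (z, x) plane at y=0, as produced by an XZ line scan."""
        return self.pixels[t, c, :, 0, :]


@dataclass
class SystemConfig:
    """Installed objectives and the laser lines used per assay."""

    system_name: str
    objectives: list
    lasers_by_assay: dict

    def __post_init__(self):
        if not self.system_name:
            raise ConfigError("system name must be non-empty")
        if not self.objectives:
            raise ConfigError("objective list must be non-empty")
        for assay, lines in self.lasers_by_assay.items():
            for nm in lines:
                if not (350.0 <= nm <= 700.0):
                    raise ConfigError(
                        f"laser line {nm} nm for assay '{assay}' outside 350-700 nm"
                    )


@dataclass
class Dataset:
    """Recordings discovered under one objective's directory, keyed by keyword.

    ``stage`` and ``stageacc`` map to ordered lists of up to 3 paths; every
    other keyword maps to a single-element list.
    """

    root: Path
    objective: str
    recordings: dict
    skipped: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# configuration file
# ---------------------------------------------------------------------------

def parse_config(text: str) -> SystemConfig:
    """Parse the line-oriented system configuration dialect.

    Recognised lines::

        system=NAME
        objectives=10x,20x,63x
        lasers.<assay>=405,488,561,633

    ``#`` starts a comment; blank lines are ignored; unknown keys are ignored
    with a logged warning.

    Raises
    ------
    ConfigError
        On a missing system name, an empty objective list, duplicate
        objective labels, or out-of-range laser lines; the message names the
        offending line.
    """
    system_name = None
    objectives: list = []
    lasers: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            logger.warning("config line %d not key=value, ignored: %r", lineno, raw)
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if key == "system":
            system_name = value
        elif key == "objectives":
            objectives = [o.strip() for o in value.split(",") if o.strip()]
            seen: dict = {}
            for o in objectives:
                seen[o] = seen.get(o, 0) + 1
            dupes = sorted(o for o, n in seen.items() if n > 1)
            if dupes:
                raise ConfigError(
                    f"line {lineno}: duplicate objective label(s): {', '.join(dupes)}"
                )
        elif key.startswith("lasers."):
            assay = key[len("lasers."):]
            try:
                lines = [float(v) for v in value.split(",") if v.strip()]
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: bad laser list {value!r}") from exc
            lasers[assay] = lines
        else:
            logger.warning("config line %d: unknown key %r ignored", lineno, key)
    if not system_name:
        raise ConfigError("configuration defines no 'system=' line")
    if not objectives:
        raise ConfigError("configuration defines no 'objectives=' line")
    return SystemConfig(system_name, objectives, lasers)


# ---------------------------------------------------------------------------
# dataset discovery
# ---------------------------------------------------------------------------

# Most specific first: "stageacc1" must not be claimed by "stage".
_KEYWORD_PATTERNS = (
    ("stageacc", re.compile(r"stageacc([123])")),
    ("stage", re.compile(r"stage([123])")),
    ("scanpmt", re.compile(r"scanpmt(\d+)")),
    ("axial405", re.compile(r"axial405")),
    ("axial488", re.compile(r"axial488")),
    ("field", re.compile(r"field(\d{3})")),
    ("laser", re.compile(r"laser")),
    ("bead", re.compile(r"bead")),
    ("psf", re.compile(r"psf")),
    ("grid", re.compile(r"grid")),
    ("zgalvo", re.compile(r"zgalvo")),
)

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _match_keyword(stem: str):
    """Return (recordings key, order index) for a file stem, or None."""
    s = stem.lower()
    for base, pattern in _KEYWORD_PATTERNS:
        m = pattern.search(s)
        if not m:
            continue
        if base in ("stage", "stageacc"):
            return base, int(m.group(1))
        if base == "scanpmt":
            return f"scanpmt{int(m.group(1))}", 0
        if base == "field":
            return f"field{m.group(1)}", 0
        return base, 0
    return None


def discover_dataset(directory, objective: str) -> Dataset:
    """Scan a directory for keyword-named recordings.

    File stems are matched case-insensitively against the keyword set
    (laser, axial405, axial488, field<nm>, bead, psf, scanpmt<k>, grid,
    stage1-3, stageacc1-3, zgalvo).  Whitespace anywhere in the directory
    or file names is a hard error; unrecognised files are listed in the
    ``skipped`` report.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DatasetError(f"no such dataset directory: {directory}")
    if any(ch.isspace() for ch in directory.name):
        raise DatasetError(
            f"dataset folder name contains whitespace: {directory.name!r}; "
            "file and folder names must not contain any spaces"
        )
    grouped: dict = {}
    skipped: list = []
    for entry in sorted(directory.iterdir()):
        if not entry.is_file() or entry.suffix.lower() not in _TIFF_SUFFIXES:
            continue
        if any(ch.isspace() for ch in entry.name):
            raise DatasetError(
                f"file name contains whitespace: {entry.name!r}; "
                "file and folder names must not contain any spaces"
            )
        matched = _match_keyword(entry.stem)
        if matched is None:
            skipped.append(entry)
            continue
        key, order = matched
        grouped.setdefault(key, []).append((order, entry))
    recordings: dict = {}
    for key, pairs in grouped.items():
        pairs.sort()
        if key in ("stage", "stageacc"):
            orders = [o for o, _ in pairs]
            if len(set(orders)) != len(orders):
                raise DatasetError(f"duplicate {key}<n> recordings in {directory}")
        elif len(pairs) > 1:
            names = ", ".join(p.name for _, p in pairs)
            raise DatasetError(
                f"keyword {key!r} matched by multiple files in {directory}: {names}"
            )
        recordings[key] = [p for _, p in pairs]
    if skipped:
        logger.info(
            "discovery skipped %d unrecognised file(s) in %s: %s",
            len(skipped), directory, ", ".join(p.name for p in skipped),
        )
    return Dataset(root=directory, objective=objective,
                   recordings=recordings, skipped=skipped)


# ---------------------------------------------------------------------------
# TIFF + sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(tiff_path: Path) -> Optional[Path]:
    for suffix in (".meta.yaml", ".meta.yml", ".meta.json"):
        p = tiff_path.with_name(tiff_path.stem + suffix)
        if p.exists():
            return p
    return None


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def read_stack(tiff_path) -> ImageStack:
    """Read a multi-page TIFF and its calibration sidecar into an ImageStack.

    The sidecar (``<stem>.meta.yaml|yml|json``) declares axis extents
    (``size_t``/``size_c``/``size_z``; pages are ordered T-slowest, then C,
    then Z) and all physical calibration.  Sidecar values always win over
    embedded TIFF metadata; a detected disagreement is logged as a warning.
    """
    tiff_path = Path(tiff_path)
    if not tiff_path.exists():
        raise SidecarError(f"no such TIFF: {tiff_path}")
    sidecar = _sidecar_path(tiff_path)
    if sidecar is None:
        raise SidecarError(
            f"missing sidecar for {tiff_path.name}: expected "
            f"{tiff_path.stem}.meta.yaml (or .json) with keys "
            f"{', '.join(SIDECAR_KEYS[:7])}"
        )
    meta = _load_sidecar(sidecar)
    unknown = set(meta) - set(SIDECAR_KEYS)
    if unknown:
        logger.warning("sidecar %s: ignoring unknown keys %s",
                       sidecar.name, sorted(unknown))

    data = tifffile.imread(tiff_path)
    if data.ndim == 2:
        data = data[None]
    elif data.ndim != 3:
        raise SidecarError(
            f"{tiff_path.name}: expected grayscale pages, got shape {data.shape}"
        )
    n_pages, ny, nx = data.shape
    size_t = int(meta.get("size_t", 1))
    size_c = int(meta.get("size_c", 1))
    size_z = int(meta.get("size_z", 1))
    if size_t * size_c * size_z != n_pages:
        raise SidecarError(
            f"{tiff_path.name}: sidecar declares T={size_t} C={size_c} "
            f"Z={size_z} = {size_t * size_c * size_z} pages but file has {n_pages}"
        )
    pixels = data.reshape(size_t, size_c, size_z, ny, nx)

    wavelengths = meta.get("channel_wavelengths_nm")
    if wavelengths is None:
        wavelengths = [0.0] * size_c
    if len(wavelengths) != size_c:
        raise SidecarError(
            f"{tiff_path.name}: sidecar declares {len(wavelengths)} channel "
            f"wavelengths for {size_c} channel(s)"
        )
    pixel_size = float(meta.get("pixel_size_xy_um", 1.0))
    _check_embedded_resolution(tiff_path, pixel_size)

    stage = meta.get("stage_positions_um")
    if stage is not None:
        stage = [tuple(float(v) for v in pos) for pos in stage]
    axes_sign = tuple(meta.get("axes_sign", (-1, -1)))
    try:
        return ImageStack(
            pixels=pixels,
            pixel_size_xy=pixel_size,
            z_step=float(meta.get("z_step_um", 0.0)),
            frame_interval=float(meta.get("frame_interval_s", 0.0)),
            channel_wavelengths=list(wavelengths),
            wavelength_axis=meta.get("wavelength_axis_nm"),
            stage_positions=stage,
            bit_depth=int(meta.get("bit_depth", 16)),
            axes_sign=axes_sign,
        )
    except ValueError as exc:
        raise SidecarError(f"{tiff_path.name}: {exc}") from exc


def _check_embedded_resolution(tiff_path: Path, sidecar_um: float) -> None:
    """Warn when the TIFF's own resolution tag disagrees with the sidecar."""
    try:
        with tifffile.TiffFile(tiff_path) as tif:
            page = tif.pages[0]
            tag = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if tag is None:
                return
            num, den = tag.value
            if num == 0 or den == 0 or (num == 1 and den == 1):
                return  # absent or writer-default tag carries no information
            # pixels per cm -> µm per pixel
            if unit is not None and getattr(unit.value, "value", unit.value) == 3:
                embedded_um = den / num * 1e4
            else:  # pixels per inch
                embedded_um = den / num * 25400.0
    except Exception:  # pragma: no cover - defensive against exotic TIFFs
        return
    # rational-tag encoding limits precision; only flag real disagreement
    if abs(embedded_um - sidecar_um) > 1e-4 * max(abs(sidecar_um), 1e-12):
        logger.warning(
            "%s: embedded pixel size %.6g µm disagrees with sidecar %.6g µm; "
            "sidecar wins", tiff_path.name, embedded_um, sidecar_um,
        )


def write_stack(stack: ImageStack, tiff_path, sidecar_format: str = "yaml") -> Path:
    """Write an ImageStack as a multi-page TIFF plus calibration sidecar.

    Pages are emitted T-slowest, then C, then Z, matching :func:`read_stack`,
    so the round trip preserves pixel values bit-exactly.
    Returns the sidecar path.
    """
    tiff_path = Path(tiff_path)
    t, c, z, ny, nx = stack.pixels.shape
    px_per_cm = 1e4 / stack.pixel_size_xy if stack.pixel_size_xy > 0 else 1.0
    tifffile.imwrite(tiff_path, stack.pixels.reshape(t * c * z, ny, nx),
                     resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")
    meta = {
        "pixel_size_xy_um": float(stack.pixel_size_xy),
        "z_step_um": float(stack.z_step),
        "frame_interval_s": float(stack.frame_interval),
        "channel_wavelengths_nm": [float(v) for v in stack.channel_wavelengths],
        "bit_depth": int(stack.bit_depth),
        "size_t": int(t),
        "size_c": int(c),
        "size_z": int(z),
        "axes_sign": [int(v) for v in stack.axes_sign],
    }
    if stack.wavelength_axis is not None:
        meta["wavelength_axis_nm"] = [float(v) for v in stack.wavelength_axis]
    if stack.stage_positions is not None:
        meta["stage_positions_um"] = [[float(a), float(b)]
                                      for a, b in stack.stage_positions]
    if sidecar_format == "json":
        sidecar = tiff_path.with_name(tiff_path.stem + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1))
    else:
        sidecar = tiff_path.with_name(tiff_path.stem + ".meta.yaml")
        sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return sidecar
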
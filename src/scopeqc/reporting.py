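"""Measurement persistence (tab-delimited), the amendable per-system
per-objective HTML record, and batch orchestration of all assays.

The TSV file is the source of truth: HTML tables can always be regenerated
from it.  HTML reports are static pages with a generated navigation sidebar;
when a new analysis is added, all earlier entry sections are preserved
byte-for-byte.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import logging
import math
import re
import shutil
from dataclasses import dataclass, field
from html import escape
from pathlib import Path
from typing import List, Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import axial as _axial
from . import beads as _beads
from . import field as _field
from . import laser as _laser
from . import spectral as _spectral
from . import stage as _stage
from .core import Dataset, DatasetError, ImageStack, SystemConfig, \
    discover_dataset, read_stack

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementRow",
    "ReportEntry",
    "RunSummary",
    "write_measurements",
    "read_measurements",
    "update_html_report",
    "rebuild_reports",
    "run_suite",
]

TSV_COLUMNS = ("timestamp", "system", "objective", "assay", "parameter",
               "value", "units")


@dataclass
class MeasurementRow:
    """One named scalar result destined for TSV/HTML."""

    timestamp: str
    system: str
    objective: str
    assay: str
    parameter: str
    value: float
    units: str

    def __post_init__(self):
        for name in ("timestamp", "system", "objective", "assay",
                     "parameter", "units"):
            if not getattr(self, name):
                raise ValueError(f"MeasurementRow field {name!r} must be non-empty")
        self.value = float(self.value)
        if not math.isfinite(self.value):
            raise ValueError(f"value for {self.parameter!r} must be finite")


@dataclass
class ReportEntry:
    timestamp: str
    rows: List[MeasurementRow] = field(default_factory=list)
    images: List[Path] = field(default_factory=list)


@dataclass
class RunSummary:
    rows: List[MeasurementRow]
    failures: dict             # keyword -> error message
    ran: list                  # keywords analysed
    tsv_path: Optional[Path]
    html_page: Optional[Path]
    exit_status: int = 0


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def _format_value(value: float) -> str:
    return format(value, ".6g")


def write_measurements(rows: List[MeasurementRow], path) -> None:
    """Append rows to a tab-delimited file (header written once)."""
    if not rows:
        raise ValueError("rows must be non-empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    new_file = not path.exists() or path.stat().st_size == 0
    with open(path, "a", encoding="utf-8") as handle:
        if new_file:
            handle.write("\t".join(TSV_COLUMNS) + "\n")
        for row in rows:
            handle.write("\t".join((
                row.timestamp, row.system, row.objective, row.assay,
                row.parameter, _format_value(row.value), row.units,
            )) + "\n")


def read_measurements(path) -> List[MeasurementRow]:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    header = tuple(lines[0].split("\t"))
    if header != TSV_COLUMNS:
        raise ValueError(f"unexpected TSV header in {path}: {header}")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(TSV_COLUMNS):
            raise ValueError(f"malformed TSV line in {path}: {line!r}")
        rows.append(MeasurementRow(parts[0], parts[1], parts[2], parts[3],
                                   parts[4], float(parts[5]), parts[6]))
    return rows


# ---------------------------------------------------------------------------
# HTML
# ---------------------------------------------------------------------------

_ENTRY_BEGIN = "<!-- scopeqc:entry:begin {ts} -->"
_ENTRY_END = "<!-- scopeqc:entry:end -->"
_ENTRY_RE = re.compile(
    r"<!-- scopeqc:entry:begin (?P<ts>[^ ]+) -->.*?<!-- scopeqc:entry:end -->",
    re.DOTALL,
)

_PAGE_STYLE = """
body { font-family: sans-serif; margin: 0; }
.nav { float: left; width: 12em; padding: 1em; background: #eee;
       min-height: 100vh; }
.main { margin-left: 14em; padding: 1em; }
table { border-collapse: collapse; margin: 0.5em 0; }
td, th { border: 1px solid #999; padding: 2px 8px; text-align: left; }
img { max-width: 480px; margin: 4px; border: 1px solid #ccc; }
section.entry { border-top: 2px solid #444; margin-top: 1.5em; }
"""


def _render_entry_block(entry: ReportEntry, page_dir: Path) -> str:
    parts = [_ENTRY_BEGIN.format(ts=entry.timestamp),
             '<section class="entry">',
             f"<h2>Analysis of {escape(entry.timestamp)}</h2>"]
    if entry.rows:
        parts.append("<table><tr><th>assay</th><th>parameter</th>"
                     "<th>value</th><th>units</th></tr>")
        for row in entry.rows:
            parts.append(
                f"<tr><td>{escape(row.assay)}</td>"
                f"<td>{escape(row.parameter)}</td>"
                f"<td>{_format_value(row.value)}</td>"
                f"<td>{escape(row.units)}</td></tr>")
        parts.append("</table>")
    for image in entry.images:
        image = Path(image)
        try:
            rel = image.resolve().relative_to(page_dir.resolve())
            src = str(rel)
        except ValueError:
            import os
            src = os.path.relpath(image.resolve(), page_dir.resolve())
        parts.append(f'<img src="{escape(src)}" alt="{escape(image.stem)}">')
    parts.append("</section>")
    parts.append(_ENTRY_END)
    return "\n".join(parts)


def _render_page(system: str, objective: str, nav_links: List[str],
                 entry_blocks: List[str]) -> str:
    nav = "\n".join(
        f'<a href="{escape(name)}.html">{escape(name)}</a><br>'
        for name in nav_links)
    body = "\n".join(entry_blocks)
    return (
        "<!DOCTYPE html>\n<html>\n<head>\n"
        f"<meta charset='utf-8'>\n<title>{escape(system)} - "
        f"{escape(objective)}</title>\n"
        f"<style>{_PAGE_STYLE}</style>\n</head>\n<body>\n"
        f'<div class="nav"><h3>{escape(system)}</h3>\n'
        f'<a href="index.html">index</a><br>\n{nav}</div>\n'
        f'<div class="main">\n<h1>{escape(system)} &mdash; '
        f"{escape(objective)}</h1>\n"
        f"{body}\n</div>\n</body>\n</html>\n"
    )


def _objective_pages(system_dir: Path) -> List[str]:
    return sorted(p.stem for p in system_dir.glob("*.html")
                  if p.name != "index.html")


def _render_index(system: str, objectives: List[str]) -> str:
    links = "\n".join(
        f'<li><a href="{escape(o)}.html">{escape(o)}</a></li>'
        for o in objectives)
    return (
        "<!DOCTYPE html>\n<html>\n<head>\n<meta charset='utf-8'>\n"
        f"<title>{escape(system)}</title>\n<style>{_PAGE_STYLE}</style>\n"
        f"</head>\n<body>\n<div class='main' style='margin-left:1em'>"
        f"<h1>{escape(system)}</h1>\n<ul>\n{links}\n</ul>\n</div>\n"
        "</body>\n</html>\n"
    )


def _extract_entries(text: str) -> List[str]:
    """Return the verbatim entry blocks of an existing page.

    Raises ValueError when the file does not look like one of ours
    (mismatched markers), which triggers the backup-and-rebuild path.
    """
    n_begin = text.count("<!-- scopeqc:entry:begin ")
    n_end = text.count(_ENTRY_END)
    blocks = [m.group(0) for m in _ENTRY_RE.finditer(text)]
    if n_begin == 0 or n_begin != n_end or len(blocks) != n_begin:
        raise ValueError("missing or unbalanced entry markers")
    return blocks


def update_html_report(report_dir, system: str, objective: str,
                       entry: ReportEntry,
                       tsv_path: Optional[Path] = None) -> Path:
    """Add a dated section to the objective's page, amending in place.

    Earlier sections are preserved byte-for-byte; only the navigation block
    and the appended section change.  A corrupt existing page is backed up
    with a suffix and rebuilt from the measurements TSV (when available).
    """
    report_dir = Path(report_dir)
    system_dir = report_dir / system
    system_dir.mkdir(parents=True, exist_ok=True)
    page = system_dir / f"{objective}.html"

    blocks: List[str] = []
    if page.exists():
        try:
            blocks = _extract_entries(page.read_text(encoding="utf-8"))
        except ValueError:
            backup = page.with_suffix(
                ".html.corrupt-" + _dt.datetime.now().strftime("%Y%m%d%H%M%S"))
            shutil.copy2(page, backup)
            logger.warning("corrupt report %s backed up to %s and rebuilt "
                           "from TSV", page, backup.name)
            blocks = _rebuild_blocks_from_tsv(tsv_path, system, objective,
                                              system_dir)
    if blocks:
        last_ts = _ENTRY_RE.match(blocks[-1]) or _ENTRY_RE.search(blocks[-1])
        if last_ts and entry.timestamp <= last_ts.group("ts"):
            raise ValueError(
                f"entry timestamp {entry.timestamp} not later than the last "
                f"recorded entry {last_ts.group('ts')}"
            )
    blocks.append(_render_entry_block(entry, system_dir))

    # write the page first so the navigation listing includes it
    page.write_text(_render_page(system, objective, [objective], blocks),
                    encoding="utf-8")
    nav = _objective_pages(system_dir)
    page.write_text(_render_page(system, objective, nav, blocks),
                    encoding="utf-8")
    # refresh the navigation block of sibling pages (entries untouched)
    for sibling in nav:
        if sibling == objective:
            continue
        sibling_page = system_dir / f"{sibling}.html"
        try:
            sibling_blocks = _extract_entries(
                sibling_page.read_text(encoding="utf-8"))
        except (OSError, ValueError):
            continue
        sibling_page.write_text(
            _render_page(system, sibling, nav, sibling_blocks),
            encoding="utf-8")
    (system_dir / "index.html").write_text(_render_index(system, nav),
                                           encoding="utf-8")
    return page


def _rebuild_blocks_from_tsv(tsv_path, system: str, objective: str,
                             page_dir: Path) -> List[str]:
    if tsv_path is None or not Path(tsv_path).exists():
        return []
    rows = [r for r in read_measurements(tsv_path)
            if r.system == system and r.objective == objective]
    by_ts: dict = {}
    for row in rows:
        by_ts.setdefault(row.timestamp, []).append(row)
    return [_render_entry_block(ReportEntry(ts, by_ts[ts]), page_dir)
            for ts in sorted(by_ts)]


def rebuild_reports(report_dir, tsv_path) -> List[Path]:
    """Regenerate all HTML pages from the measurements TSV alone."""
    report_dir = Path(report_dir)
    rows = read_measurements(tsv_path)
    pages = []
    pairs = sorted({(r.system, r.objective) for r in rows})
    for system, objective in pairs:
        system_dir = report_dir / system
        system_dir.mkdir(parents=True, exist_ok=True)
        blocks = _rebuild_blocks_from_tsv(tsv_path, system, objective,
                                          system_dir)
        page = system_dir / f"{objective}.html"
        page.write_text(
            _render_page(system, objective, _objective_pages(system_dir)
                         or [objective], blocks), encoding="utf-8")
        nav = _objective_pages(system_dir)
        page.write_text(_render_page(system, objective, nav, blocks),
                        encoding="utf-8")
        (system_dir / "index.html").write_text(_render_index(system, nav),
                                               encoding="utf-8")
        pages.append(page)
    return pages


# ---------------------------------------------------------------------------
# assay runners: stack(s) -> measurement rows + figures
# ---------------------------------------------------------------------------

def _save(fig, art_dir: Path, name: str, images: list) -> None:
    path = art_dir / f"{name}.png"
    fig.savefig(path, dpi=80)
    plt.close(fig)
    images.append(path)


def _run_laser(stack: ImageStack, make_row, art_dir, images):
    trace = _laser.frame_statistics(stack)
    rows = [
        make_row("laser", "mean_min", trace.min_mean, "counts"),
        make_row("laser", "mean_max", trace.max_mean, "counts"),
        make_row("laser", "max_percent_change", trace.max_percent_change, "%"),
    ]
    first = stack.frame(0, 0, 0)
    noise = _laser.linescan_noise(first, first.shape[0] // 2)
    rows += [
        make_row("laser", "line_mean", noise.mean, "counts"),
        make_row("laser", "line_sd", noise.sd, "counts"),
    ]
    if noise.cv_defined:
        rows.append(make_row("laser", "line_cv", noise.cv, "ratio"))
    hists = _laser.multiscale_histograms(stack)

    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    axes[0, 0].plot(trace.times, trace.mean_intensity)
    axes[0, 0].set(title="mean intensity", xlabel="s", ylabel="counts")
    axes[0, 1].plot(trace.times, trace.mean_intensity)
    pad = max(trace.mean_intensity.std() * 3, 1e-9)
    centre = trace.mean_intensity.mean()
    axes[0, 1].set_ylim(centre - pad, centre + pad)
    axes[0, 1].set(title="mean (rescaled)", xlabel="s")
    axes[1, 0].plot(trace.times, trace.sd_intensity)
    axes[1, 0].set(title="per-frame SD", xlabel="s", ylabel="counts")
    axes[1, 1].plot(noise.profile.positions, noise.profile.intensities)
    axes[1, 1].set(title="first-frame line scan", xlabel="px")
    fig.tight_layout()
    _save(fig, art_dir, "laser_traces", images)

    if hists.histograms:
        fig, axes = plt.subplots(1, len(hists.histograms),
                                 figsize=(3 * len(hists.histograms), 2.6),
                                 squeeze=False)
        for ax, (label, (edges, freqs)) in zip(axes[0],
                                               hists.histograms.items()):
            centres = 0.5 * (edges[1:-2] + edges[2:-1])
            ax.bar(centres, freqs[1:-1], width=0.5)
            ax.set(title=label, xlabel="% change")
        fig.tight_layout()
        _save(fig, art_dir, "laser_histograms", images)
    return rows


def _run_axial(stack: ImageStack, make_row, art_dir, images, assay: str):
    analysis = _axial.axial_channels_analysis(stack)
    rows = []
    ref = analysis.channels[analysis.reference_index].wavelength
    for i, ch in enumerate(analysis.channels):
        tag = f"{ch.wavelength:.0f}nm"
        if not ch.has_peak:
            continue
        rows += [
            make_row(assay, f"peak_z_{tag}", ch.peak_z, "um"),
            make_row(assay, f"fwhm_{tag}", ch.fwhm, "um"),
            make_row(assay, f"dz_vs_{ref:.0f}nm_{tag}",
                     analysis.delta_vs_reference[i], "um"),
        ]

    n = len(analysis.channels)
    fig, axes = plt.subplots(1, n + 1, figsize=(3 * (n + 1), 3),
                             squeeze=False)
    rgb = np.zeros(stack.xz_plane(0, 0).shape + (3,))
    for c in range(min(3, n)):
        plane = stack.xz_plane(0, c).astype(float)
        if plane.max() > 0:
            rgb[..., c] = plane / plane.max()
    axes[0, 0].imshow(rgb, aspect="auto", origin="upper")
    axes[0, 0].axvline(analysis.line_x, color="w", lw=0.8)
    axes[0, 0].set(title="overlay (line marked)")
    for c, ch in enumerate(analysis.channels):
        ax = axes[0, c + 1]
        ax.plot(ch.profile.positions, ch.profile.intensities)
        if ch.has_peak:
            ax.plot([ch.peak_z], [ch.stats.peak_intensity], "ro", ms=4)
            lo, hi = ch.stats.half_max_crossings
            ax.plot([lo, hi], [ch.stats.half_level] * 2, "g.-", ms=4)
        ax.set(title=f"{ch.wavelength:.0f} nm", xlabel="z (um)")
    fig.tight_layout()
    _save(fig, art_dir, f"{assay}_profiles", images)
    return rows


def _run_field(stack: ImageStack, make_row, art_dir, images, assay: str):
    wavelength = float(assay.replace("field", "") or 0)
    result = _field.field_uniformity(stack, wavelength)
    rows = [
        make_row(assay, "min_intensity", result.min_intensity, "counts"),
        make_row(assay, "max_intensity", result.max_intensity, "counts"),
        make_row(assay, "percent_difference", result.percent_difference, "%"),
        make_row(assay, "percent_difference_of_mean",
                 result.percent_difference_of_mean, "%"),
        make_row(assay, "saturated", float(result.saturated), "flag"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    shown = result.smoothed
    axes[0].imshow(shown, cmap="gray",
                   vmin=np.percentile(shown, 0.5),
                   vmax=np.percentile(shown, 99.5))
    axes[0].axhline(shown.shape[0] // 2, color="k", lw=0.8)
    axes[0].axvline(shown.shape[1] // 2, color="k", lw=0.8)
    axes[0].set(title="field (contrast enhanced)")
    # same data on two intensity scales: full range and rescaled
    for profile, label in ((result.h_profile, "horizontal"),
                           (result.v_profile, "vertical")):
        axes[1].plot(profile.positions, profile.intensities, label=label)
        axes[2].plot(profile.positions, profile.intensities, label=label)
    axes[1].set_ylim(0, max(result.max_intensity * 1.05, 1))
    axes[1].set(title="profiles (full scale)", xlabel=result.h_profile.unit)
    axes[2].set(title="profiles (rescaled)", xlabel=result.h_profile.unit)
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    _save(fig, art_dir, f"{assay}_profiles", images)
    return rows


def _z_extended(plane: np.ndarray, stack: ImageStack, z_axis: int = 0):
    """Stretch the Z axis by z_step / pixel_size for display."""
    factor = max(1, int(round(stack.z_step / stack.pixel_size_xy)))
    return np.repeat(plane, factor, axis=z_axis)


def _run_bead(stack: ImageStack, make_row, art_dir, images):
    result = _beads.bead_centroids(stack)
    rows = []
    tags = [f"{w:.0f}nm" for w in stack.channel_wavelengths]
    for i, record in enumerate(result.records):
        if record is None:
            continue
        x, y, z = record.centroid
        rows += [
            make_row("bead", f"centroid_x_{tags[i]}", x, "um"),
            make_row("bead", f"centroid_y_{tags[i]}", y, "um"),
            make_row("bead", f"centroid_z_{tags[i]}", z, "um"),
        ]
        wx, wy, wz = record.centroid_weighted
        rows.append(make_row("bead", f"centroid_z_weighted_{tags[i]}", wz, "um"))
    for i in range(stack.size_c):
        for j in range(i + 1, stack.size_c):
            if math.isfinite(result.xy_distance[i, j]):
                rows += [
                    make_row("bead", f"xy_distance_{tags[i]}_{tags[j]}",
                             result.xy_distance[i, j], "um"),
                    make_row("bead", f"z_distance_{tags[i]}_{tags[j]}",
                             result.z_distance[i, j], "um"),
                ]

    first = next(r for r in result.records if r is not None)
    cx, cy, cz = first.centroid
    iz = int(round(cz / stack.z_step))
    iy = int(round(cy / stack.pixel_size_xy))
    ix = int(round(cx / stack.pixel_size_xy))
    volume = stack.pixels[0].astype(float)  # (c, z, y, x)
    views = {
        "XY": volume[:, iz, :, :],
        "XZ": _z_extended(volume[:, :, iy, :], stack, z_axis=1),
        "YZ": _z_extended(volume[:, :, :, ix], stack, z_axis=1),
    }
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, (name, view) in zip(axes, views.items()):
        rgb = np.zeros(view.shape[1:] + (3,))
        for c in range(min(3, view.shape[0])):
            channel = view[c]
            if channel.max() > 0:
                rgb[..., c] = channel / channel.max()
        ax.imshow(rgb, aspect="equal" if name == "XY" else "auto")
        ax.set(title=f"bead {name}")
    fig.tight_layout()
    _save(fig, art_dir, "bead_overlays", images)
    return rows


def _run_psf(stack: ImageStack, make_row, art_dir, images):
    result = _beads.psf_metrics(stack)
    rows = [
        make_row("psf", "lateral_fwhm_x", result.lateral_fwhm_x, "um"),
        make_row("psf", "lateral_fwhm_y", result.lateral_fwhm_y, "um"),
        make_row("psf", "lateral_fwhm_mean", result.lateral_fwhm_mean, "um"),
        make_row("psf", "axial_fwhm", result.axial_fwhm, "um"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, axis in zip(axes, ("x", "y", "z")):
        profile = result.profiles[axis]
        fit = result.fits[axis]
        ax.plot(profile.positions, profile.intensities, ".", ms=3)
        xs = np.linspace(profile.positions[0], profile.positions[-1], 300)
        ax.plot(xs, fit.amplitude * np.exp(-((xs - fit.mean) ** 2)
                                           / (2 * fit.sigma ** 2))
                + fit.baseline, "r-", lw=1)
        ax.set(title=f"{axis.upper()} fit", xlabel="um")
    fig.tight_layout()
    _save(fig, art_dir, "psf_fits", images)

    volume = stack.pixels[0, 0].astype(float)
    gamma = np.power(volume / max(volume.max(), 1e-12), 0.1)
    nz = volume.shape[0]
    cols = int(math.ceil(math.sqrt(nz)))
    rows_n = int(math.ceil(nz / cols))
    fig, axes = plt.subplots(rows_n, cols, figsize=(1.4 * cols, 1.4 * rows_n),
                             squeeze=False)
    for k in range(rows_n * cols):
        ax = axes[k // cols][k % cols]
        ax.axis("off")
        if k < nz:
            ax.imshow(gamma[k], cmap="turbo")  # pseudo-colour LUT
    fig.tight_layout()
    _save(fig, art_dir, "psf_montage", images)
    return rows


def _run_scanpmt(stack: ImageStack, make_row, art_dir, images, assay: str,
                 reference_lines):
    response = _spectral.lambda_response(stack, assay, reference_lines)
    rows = [make_row(assay, "n_peaks", float(len(response.peaks)), "count")]
    for match in response.matches:
        tag = f"{match.line_nm:.0f}nm"
        if match.absent:
            rows.append(make_row(assay, f"line_absent_{tag}", 1.0, "flag"))
            continue
        peak = response.peaks[match.peak_index]
        rows += [
            make_row(assay, f"peak_wavelength_{tag}", peak.wavelength, "nm"),
            make_row(assay, f"offset_{tag}", match.offset_nm, "nm"),
            make_row(assay, f"peak_intensity_{tag}", peak.intensity, "counts"),
        ]
        if math.isfinite(peak.fwhm):
            rows.append(make_row(assay, f"peak_fwhm_{tag}", peak.fwhm, "nm"))
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(response.wavelengths, response.mean_intensities)
    for line in response.reference_lines:
        ax.axvline(line, color="r", ls="--", lw=0.8)
    ax.set(title=assay, xlabel="wavelength (nm)", ylabel="mean counts")
    fig.tight_layout()
    _save(fig, art_dir, f"{assay}_spectrum", images)
    return rows


def _run_stage_repeat(paths, make_row, art_dir, images):
    rows = []
    fig, ax = plt.subplots(figsize=(4, 4))
    for k, path in enumerate(paths, start=1):
        label = f"stage{k}"
        series = read_stack(path)
        trace = _stage.track_bead(series, position_label=label)
        stats = _stage.repeatability_stats(trace)
        rows += [
            make_row("stage", f"{label}_mean_x", stats.mean_position[0], "um"),
            make_row("stage", f"{label}_mean_y", stats.mean_position[1], "um"),
            make_row("stage", f"{label}_sd_x", stats.sd[0], "um"),
            make_row("stage", f"{label}_sd_y", stats.sd[1], "um"),
            make_row("stage", f"{label}_max_excursion",
                     stats.max_excursion, "um"),
        ]
        valid = np.isfinite(trace.centroids).all(axis=1)
        pts = trace.centroids[valid] - np.asarray(stats.mean_position)
        ax.plot(pts[:, 0], pts[:, 1], ".", color="grey", ms=3)
        ax.errorbar([0], [0], xerr=[stats.sd[0]], yerr=[stats.sd[1]],
                    fmt="o", color="red", ms=4, capsize=3)
    ax.set(title="centroid scatter about mean", xlabel="um", ylabel="um")
    ax.set_aspect("equal")
    fig.tight_layout()
    _save(fig, art_dir, "stage_scatter", images)
    return rows


def _run_stage_accuracy(paths, make_row, art_dir, images):
    rows = []
    residuals = []
    for k, path in enumerate(paths, start=1):
        label = f"stageacc{k}"
        series = read_stack(path)
        trace = _stage.track_bead(series, position_label=label)
        stats = _stage.accuracy_stats(trace, series)
        residuals.append(stats.residuals)
        rows += [
            make_row("stageacc", f"{label}_mean_residual_x",
                     float(stats.residuals[:, 0].mean()), "um"),
            make_row("stageacc", f"{label}_mean_residual_y",
                     float(stats.residuals[:, 1].mean()), "um"),
            make_row("stageacc", f"{label}_mean_scalar_residual",
                     float(stats.scalar_residuals.mean()), "um"),
        ]
    pooled = np.concatenate(residuals, axis=0)
    rows += [
        make_row("stageacc", "pooled_mean_residual_x",
                 float(pooled[:, 0].mean()), "um"),
        make_row("stageacc", "pooled_mean_residual_y",
                 float(pooled[:, 1].mean()), "um"),
    ]
    return rows


def _run_grid(stack: ImageStack, make_row, art_dir, images):
    rendered = _stage.grid_passthrough(stack)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rendered, cmap="gray")
    ax.set(title="grid (contrast enhanced)")
    fig.tight_layout()
    _save(fig, art_dir, "grid", images)
    return [
        make_row("grid", "width_px", float(rendered.shape[1]), "px"),
        make_row("grid", "height_px", float(rendered.shape[0]), "px"),
    ]


def _run_zgalvo(stack: ImageStack, make_row, art_dir, images):
    trace = _axial.zgalvo_drift(stack)
    rows = [
        make_row("zgalvo", "total_drift", trace.total_drift, "um"),
        make_row("zgalvo", "drift_rate", trace.drift_rate, "um/min"),
        make_row("zgalvo", "fwhm_mean", float(np.nanmean(trace.fwhm)), "um"),
        make_row("zgalvo", "fwhm_sd", float(np.nanstd(trace.fwhm)), "um"),
    ]
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].plot(trace.times, trace.peak_z, ".-")
    axes[0].set(title="reflection peak Z", xlabel="s", ylabel="um")
    axes[1].plot(trace.times, trace.fwhm, ".-")
    axes[1].set(title="reflection FWHM (vibration)", xlabel="s", ylabel="um")
    fig.tight_layout()
    _save(fig, art_dir, "zgalvo_drift", images)
    return rows


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_suite(config: SystemConfig, dataset_dir, output_dir,
              objective: str, system: Optional[str] = None,
              html_dir=None, timestamp: Optional[str] = None) -> RunSummary:
    """Discover a dataset and dispatch every recognised keyword to its assay.

    Per-assay failures are logged and recorded but do not abort the run;
    the exit status is nonzero only for hard errors (no recognised
    recordings at all).
    """
    system = system or config.system_name
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if timestamp is None:
        timestamp = _dt.datetime.now().isoformat(timespec="microseconds")
    dataset = discover_dataset(dataset_dir, objective)
    if not dataset.recordings:
        raise DatasetError(f"no recognised recordings in {dataset_dir}")

    art_dir = output_dir / "images" / objective / timestamp.replace(":", "-")
    art_dir.mkdir(parents=True, exist_ok=True)

    def make_row(assay, parameter, value, units):
        return MeasurementRow(timestamp, system, objective, assay,
                              parameter, value, units)

    rows: List[MeasurementRow] = []
    images: List[Path] = []
    failures: dict = {}
    ran: list = []
    scan_lines = config.lasers_by_assay.get("scan", [488.0, 561.0, 633.0])

    for keyword in sorted(dataset.recordings):
        paths = dataset.recordings[keyword]
        try:
            if keyword == "laser":
                new_rows = _run_laser(read_stack(paths[0]), make_row,
                                      art_dir, images)
            elif keyword.startswith("axial"):
                new_rows = _run_axial(read_stack(paths[0]), make_row,
                                      art_dir, images, keyword)
            elif keyword.startswith("field"):
                new_rows = _run_field(read_stack(paths[0]), make_row,
                                      art_dir, images, keyword)
            elif keyword == "bead":
                new_rows = _run_bead(read_stack(paths[0]), make_row,
                                     art_dir, images)
            elif keyword == "psf":
                new_rows = _run_psf(read_stack(paths[0]), make_row,
                                    art_dir, images)
            elif keyword.startswith("scanpmt"):
                new_rows = _run_scanpmt(read_stack(paths[0]), make_row,
                                        art_dir, images, keyword, scan_lines)
            elif keyword == "stage":
                new_rows = _run_stage_repeat(paths, make_row, art_dir, images)
            elif keyword == "stageacc":
                new_rows = _run_stage_accuracy(paths, make_row, art_dir,
                                               images)
            elif keyword == "grid":
                new_rows = _run_grid(read_stack(paths[0]), make_row,
                                     art_dir, images)
            elif keyword == "zgalvo":
                new_rows = _run_zgalvo(read_stack(paths[0]), make_row,
                                       art_dir, images)
            else:  # pragma: no cover - discovery only emits known keywords
                logger.info("no assay for keyword %r, skipped", keyword)
                continue
        except Exception as exc:
            logger.error("assay %r failed: %s", keyword, exc)
            failures[keyword] = str(exc)
            continue
        rows.extend(new_rows)
        ran.append(keyword)

    tsv_path = output_dir / "measurements.tsv"
    if rows:
        write_measurements(rows, tsv_path)

    html_page = None
    if html_dir is not None:
        entry = ReportEntry(timestamp=timestamp, rows=rows, images=images)
        html_page = update_html_report(html_dir, system, objective, entry,
                                       tsv_path=tsv_path)
    return RunSummary(rows=rows, failures=failures, ran=ran,
                      tsv_path=tsv_path if rows else None,
                      html_page=html_page, exit_status=0)
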
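"""Configuration, experiment stores, summary files and plate visualizations.

An experiment is persisted as a directory holding a JSON manifest plus plain
TSV/CSV files (combined raw series, per-well agar reference, layout), so any
run can be reloaded, re-analysed and compared without re-reading the original
reader exports.  `config.txt` is an INI file with one section per treatment
naming the calculators and their windows.

All heatmaps share one absolute colour scale over absorbance [0, 3.5] so
plates and timepoints are directly comparable; square/spot sizes are scaled
between that plate's own minimum and maximum.
"""

from __future__ import annotations

import configparser
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .plate_core import (ArrayLayout, ExperimentSeries, PlateGeometry,
                         PlatePhenError, SATURATION_CEILING, load_layout,
                         write_layout)
from .phenotype_calculators import (CalculatorSpec, ConfigError,
                                    DEFAULT_EPSILON, DEFAULT_LAG_FRACTION,
                                    DEFAULT_SMOOTH_WINDOW, DEFAULT_SPECS,
                                    PhenotypeResult, registered_calculators)
from .preprocess import ProcessedSeries
from .qtl_mapping import GeneticMap, GenotypeMatrix, export_rqtl_csv

log = logging.getLogger("platephen")


# ---------------------------------------------------------------------------
# config.txt
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parsed ``config.txt``: calculator specs per treatment plus run options."""

    specs_by_treatment: dict[str, list[CalculatorSpec]]
    output_dir: str = "."
    seed: int = 0

    def specs_for(self, treatment: str) -> list[CalculatorSpec]:
        if treatment in self.specs_by_treatment:
            return self.specs_by_treatment[treatment]
        return list(DEFAULT_SPECS)


def _parse_window(value: str) -> tuple[float, float]:
    sep = ":" if ":" in value else ","
    lo, hi = (float(v) for v in value.split(sep))
    return lo, hi


def load_config(stream) -> RunConfig:
    """Parse an INI-style config: sections per treatment, keys ``calculators``,
    ``window_h``, ``smooth_window``, ``lag_fraction``, ``epsilon``."""
    text = stream.read() if hasattr(stream, "read") else stream
    parser = configparser.ConfigParser()
    parser.read_string(text)
    known = set(registered_calculators())
    specs_by_treatment: dict[str, list[CalculatorSpec]] = {}
    output_dir = parser.get("DEFAULT", "output_dir", fallback=".")
    seed = parser.getint("DEFAULT", "seed", fallback=0)
    for section in parser.sections():
        sec = parser[section]
        names = [n.strip() for n in sec.get("calculators", "").split(",")
                 if n.strip()]
        unknown = set(names) - known
        if unknown:
            raise ConfigError(f"[{section}] unknown calculators {sorted(unknown)}; "
                              f"registered: {sorted(known)}")
        window = _parse_window(sec["window_h"]) if "window_h" in sec else None
        smooth = sec.getint("smooth_window", DEFAULT_SMOOTH_WINDOW)
        lag_f = sec.getfloat("lag_fraction", DEFAULT_LAG_FRACTION)
        eps = sec.getfloat("epsilon", DEFAULT_EPSILON)
        specs = [CalculatorSpec(n, window_h=window, smooth_window=smooth,
                                lag_fraction=lag_f, epsilon=eps) for n in names]
        specs_by_treatment[section] = specs
    return RunConfig(specs_by_treatment, output_dir, seed)


# ---------------------------------------------------------------------------
# Experiment store (directory + manifest)
# ---------------------------------------------------------------------------

def save_experiment(series: ExperimentSeries, directory) -> Path:
    """Persist an experiment series to a directory store (TSV + JSON manifest)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    labels = series.geometry.labels()
    combined = pd.DataFrame(series.series, columns=labels)
    combined.insert(0, "time_s", series.times_s)
    combined.to_csv(d / "combined.tsv", sep="\t", index=False)
    pd.DataFrame({"position": labels, "agar": series.agar}).to_csv(
        d / "agar.tsv", sep="\t", index=False)
    if series.layout is not None:
        (d / "layout.csv").write_text(write_layout(series.layout))
    manifest = {"plate_id": series.plate_id,
                "geometry": series.geometry.density,
                "treatment": series.treatment,
                "provenance": series.provenance,
                "files": ["combined.tsv", "agar.tsv"] +
                         (["layout.csv"] if series.layout is not None else [])}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("saved experiment plate_id=%s treatment=%s dir=%s",
             series.plate_id, series.treatment, d)
    return d


def load_experiment(directory) -> ExperimentSeries:
    """Reload an experiment series from its directory store."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    geometry = PlateGeometry(int(manifest["geometry"]))
    combined = pd.read_csv(d / "combined.tsv", sep="\t")
    agar = pd.read_csv(d / "agar.tsv", sep="\t")["agar"].to_numpy()
    layout = None
    if (d / "layout.csv").exists():
        layout = load_layout((d / "layout.csv").read_text(), geometry)
    labels = geometry.labels()
    return ExperimentSeries(manifest["plate_id"], geometry, agar,
                            combined["time_s"].to_numpy(),
                            combined[labels].to_numpy(),
                            list(manifest["provenance"]),
                            manifest.get("treatment", ""), layout)


# ---------------------------------------------------------------------------
# Summary files
# ---------------------------------------------------------------------------

def write_summary_files(proc: ProcessedSeries, result: PhenotypeResult,
                        out_dir, phenotypes: pd.DataFrame | None = None,
                        genotypes: GenotypeMatrix | None = None,
                        gmap: GeneticMap | None = None) -> list[Path]:
    """Write the combined-data TSV, the per-colony summary TSV and, when
    genotypes are supplied, an R/qtl-ready csv."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    labels = proc.labels
    combined = pd.DataFrame(proc.corrected, columns=labels)
    combined.insert(0, "time_s", proc.times_s)
    path = d / "combined_corrected.tsv"
    combined.to_csv(path, sep="\t", index=False)
    written.append(path)

    summary = result.table.copy()
    layout = proc.base.layout
    if layout is not None:
        summary.insert(0, "strain",
                       [layout.strain_at(lab) for lab in summary.index])
    flags = proc.flags.loc[summary.index]
    for col in flags.columns:
        summary[f"flag_{col}"] = flags[col].to_numpy()
    path = d / "colony_summary.tsv"
    summary.to_csv(path, sep="\t")
    written.append(path)

    if result.scatter is not None:
        path = d / "printedmass_vs_lag.tsv"
        result.scatter.to_csv(path, sep="\t")
        written.append(path)

    if genotypes is not None and gmap is not None and phenotypes is not None:
        path = d / "rqtl_cross.csv"
        with open(path, "w") as fh:
            export_rqtl_csv(phenotypes, genotypes, gmap, fh)
        written.append(path)
    log.info("wrote %d summary files to %s", len(written), d)
    return written


# ---------------------------------------------------------------------------
# Plate visualizations
# ---------------------------------------------------------------------------

_ABS_NORM = matplotlib.colors.Normalize(vmin=0.0, vmax=SATURATION_CEILING)
_CMAP = matplotlib.colormaps["viridis"]


def _plate_scatter(ax, geometry: PlateGeometry, values: np.ndarray,
                   title: str, marker: str = "s") -> None:
    """Grid of squares/spots: colour absolute over [0, 3.5], size spanning
    this plate's own min..max."""
    rows, cols = np.divmod(np.arange(geometry.n_wells), geometry.n_cols)
    finite = np.isfinite(values)
    vmin = np.nanmin(values) if finite.any() else 0.0
    vmax = np.nanmax(values) if finite.any() else 1.0
    span = vmax - vmin
    size = 40.0 + 160.0 * ((values - vmin) / span if span > 0
                           else np.full_like(values, 0.5))
    ax.scatter(cols, rows, c=values, s=size, marker=marker,
               cmap=_CMAP, norm=_ABS_NORM)
    ax.set_xlim(-1, geometry.n_cols)
    ax.set_ylim(geometry.n_rows, -1)
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.set_xticks([]); ax.set_yticks([])


def render_plate_views(proc: ProcessedSeries, result: PhenotypeResult | None,
                       out_dir, frame_stride: int = 1,
                       max_replicate_plots: int = 12) -> list[Path]:
    """Render the standard plate QC views as PNG files.

    Emits: agar heatmap; printed-mass spot map; all-curves grid coloured by
    printed mass; per-strain replicate plots with inflection dots (when a
    MaxSlopeCalc result is available); and one heatmap frame per timepoint
    (the time-lapse surface; encode externally if a movie is wanted).
    """
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    geometry = proc.base.geometry
    written: list[Path] = []

    fig, ax = plt.subplots(figsize=(8, 5.5))
    _plate_scatter(ax, geometry, proc.base.agar, "Agar absorbance (pre-print)")
    fig.colorbar(plt.cm.ScalarMappable(norm=_ABS_NORM, cmap=_CMAP), ax=ax)
    path = d / "agar_heatmap.png"
    fig.savefig(path, dpi=80); plt.close(fig); written.append(path)

    fig, ax = plt.subplots(figsize=(8, 5.5))
    _plate_scatter(ax, geometry, proc.printed_mass,
                   "Printed mass (initial corrected absorbance)", marker="o")
    fig.colorbar(plt.cm.ScalarMappable(norm=_ABS_NORM, cmap=_CMAP), ax=ax)
    path = d / "printed_mass.png"
    fig.savefig(path, dpi=80); plt.close(fig); written.append(path)

    # all curves, coloured by printed mass scaled to this plate's range
    fig, ax = plt.subplots(figsize=(8, 5))
    pm = proc.printed_mass
    pm_norm = matplotlib.colors.Normalize(vmin=np.nanmin(pm), vmax=np.nanmax(pm))
    occupied = ~proc.flags["empty"].to_numpy() if proc.base.layout is not None \
        else np.ones(geometry.n_wells, bool)
    t_h = proc.times_s / 3600.0
    for w in np.flatnonzero(occupied):
        ax.plot(t_h, proc.corrected[:, w], lw=0.5,
                color=_CMAP(pm_norm(pm[w])))
    ax.set_xlabel("time (h)"); ax.set_ylabel("corrected absorbance")
    ax.set_title("All growth curves (colour: printed mass)")
    path = d / "curves_all.png"
    fig.savefig(path, dpi=80); plt.close(fig); written.append(path)

    if proc.base.layout is not None and result is not None and \
            "inflection_time_s" in result.table.columns:
        groups = proc.base.layout.replicate_groups()
        multi = {s: labs for s, labs in groups.items() if len(labs) >= 2}
        for strain in sorted(multi)[:max_replicate_plots]:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for lab in multi[strain]:
                curve = proc.curve(lab)
                ax.plot(t_h, curve, lw=1.0, label=lab)
                if lab in result.table.index:
                    ti = result.table.at[lab, "inflection_time_s"]
                    if np.isfinite(ti):
                        j = int(np.argmin(np.abs(proc.times_s - ti)))
                        ax.plot(t_h[j], curve[j], "ko", ms=4)
            ax.set_title(f"Replicates of {strain}")
            ax.set_xlabel("time (h)"); ax.set_ylabel("corrected absorbance")
            ax.legend(fontsize=6)
            path = d / f"replicates_{strain}.png"
            fig.savefig(path, dpi=80); plt.close(fig); written.append(path)

    frames_dir = d / "frames"
    frames_dir.mkdir(exist_ok=True)
    for k, t_idx in enumerate(range(0, len(proc.times_s), frame_stride)):
        fig, ax = plt.subplots(figsize=(6, 4))
        _plate_scatter(ax, geometry, proc.corrected[t_idx, :],
                       f"t = {proc.times_s[t_idx] / 3600.0:.2f} h")
        path = frames_dir / f"frame_{k:04d}.png"
        fig.savefig(path, dpi=60); plt.close(fig); written.append(path)
    log.info("rendered %d images to %s", len(written), d)
    return written
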
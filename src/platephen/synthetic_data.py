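"""Seeded generators for plate-reader runs and haploid-cross datasets.

The curve generator reproduces the phenomena characteristic of absorbance
read vertically through colonies on agar: a logistic colony signal on top of
a per-well agar baseline, a transient first-hour dip (evaporating micro-
bubbles in the freshly printed spot act as lenses), measurement noise whose
standard deviation grows with the absorbance itself (optionally with a
plate-synchronised component), perimeter colonies that keep growing after
nutrient exhaustion in the interior (~40 h), and the hard 3.5 reader ceiling.

The cross generator emits tetrad-structured biallelic genotypes: each yeast
tetrad holds the four spores of one meiosis, so alleles segregate exactly
2:2 at every marker.  Recombination between adjacent markers follows the
Haldane model (no interference).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .plate_core import (ArrayLayout, PlateGeometry, ReadingRun,
                         SATURATION_CEILING, position_label)
from .qtl_mapping import GeneticMap, GenotypeMatrix, haldane_recombination

_EPOCH = datetime(2024, 1, 1, 9, 0, 0)


# ---------------------------------------------------------------------------
# Growth curves and plates
# ---------------------------------------------------------------------------

@dataclass
class GrowthParams:
    """Parameters of one simulated colony's raw absorbance trace.

    K is the plateau of the agar-subtracted colony signal (a colony at
    maximum size in a 384 array reads up to ~2.5 without agar); r is the
    logistic rate per hour and tm the inflection time in hours, so the true
    maximum slope is r*K/4 at tm.  A0 is the printed-mass offset right after
    printing.  Measurement noise has SD sigma0 + sigma1*signal.
    """

    K: float = 2.0
    r: float = 0.4              # per hour
    tm: float = 12.0            # hours
    A0: float = 0.1
    dip_depth: float = 0.05
    dip_tau_h: float = 0.3
    sigma0: float = 0.01
    sigma1: float = 0.02
    agar_base: float = 0.5
    agar_gradient: float = 0.0  # absorbance span across the plate diagonal
    edge_onset_h: float = 40.0
    clamp: float = SATURATION_CEILING

    def __post_init__(self) -> None:
        for name in ("K", "r", "dip_depth", "dip_tau_h", "sigma0", "sigma1",
                     "agar_base", "edge_onset_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.clamp != SATURATION_CEILING:
            raise ValueError(f"clamp is fixed at the reader ceiling {SATURATION_CEILING}")


def default_times_s(hours: float = 65.0, interval_min: float = 20.0) -> np.ndarray:
    """The reader's standard schedule: one pass every 20 min, ~65 h total."""
    step = interval_min * 60.0
    return np.arange(0.0, hours * 3600.0 + step / 2, step)


def logistic_signal(params: GrowthParams, times_s: np.ndarray) -> np.ndarray:
    """Noiseless agar-subtracted colony signal (logistic plus printed mass, minus dip)."""
    t_h = np.asarray(times_s, dtype=float) / 3600.0
    sig = params.A0 + params.K / (1.0 + np.exp(-params.r * (t_h - params.tm)))
    if params.dip_depth > 0:
        sig = sig - params.dip_depth * np.exp(-t_h / params.dip_tau_h)
    return sig


def simulate_curve(params: GrowthParams, times_s: np.ndarray,
                   rng: np.random.Generator, agar: float | None = None,
                   shared_noise: np.ndarray | None = None
                   ) -> tuple[np.ndarray, dict]:
    """Simulate one raw absorbance trace plus its ground-truth record.

    raw(t) = min(agar + signal(t) + noise, 3.5) with noise ~ N(0, sigma0 +
    sigma1*signal).  ``shared_noise`` adds a per-timepoint offset common to
    the whole plate (the synchronised variance component).  The truth record
    carries the parameters and the derived max slope r*K/4.
    """
    agar_val = params.agar_base if agar is None else agar
    signal = logistic_signal(params, times_s)
    sd = params.sigma0 + params.sigma1 * np.clip(signal, 0.0, None)
    noise = rng.normal(0.0, 1.0, size=signal.shape) * sd
    raw = agar_val + signal + noise
    if shared_noise is not None:
        raw = raw + shared_noise
    raw = np.minimum(raw, params.clamp)
    truth = {"K": params.K, "r": params.r, "tm_h": params.tm, "A0": params.A0,
             "agar": agar_val, "max_slope_per_h": params.r * params.K / 4.0,
             "signal": signal}
    return raw, truth


def _agar_field(params: GrowthParams, geometry: PlateGeometry,
                rng: np.random.Generator) -> np.ndarray:
    """Per-well agar absorbance, optionally with a diagonal thickness gradient."""
    rows, cols = np.divmod(np.arange(geometry.n_wells), geometry.n_cols)
    frac = (rows / max(geometry.n_rows - 1, 1) +
            cols / max(geometry.n_cols - 1, 1)) / 2.0
    agar = params.agar_base + params.agar_gradient * frac
    agar = agar + rng.normal(0.0, 0.005, size=geometry.n_wells)
    return np.clip(agar, 0.0, None)


def _perimeter_mask(geometry: PlateGeometry) -> np.ndarray:
    rows, cols = np.divmod(np.arange(geometry.n_wells), geometry.n_cols)
    return ((rows == 0) | (rows == geometry.n_rows - 1) |
            (cols == 0) | (cols == geometry.n_cols - 1))


def simulate_plate(layout: ArrayLayout,
                   params_by_strain: dict[str, GrowthParams],
                   rng: np.random.Generator,
                   times_s: np.ndarray | None = None,
                   plate_id: str = "SIMPLATE",
                   program: str = "growth",
                   agar_passes: int = 1,
                   shared_sigma: float = 0.0,
                   edge_boost_per_h: float = 0.0,
                   default_params: GrowthParams | None = None
                   ) -> tuple[ReadingRun, ReadingRun, dict]:
    """Simulate one plate: a pre-print agar blank run plus one growth run.

    Every non-empty well grows with its strain's parameters; empty wells read
    agar plus noise.  ``edge_boost_per_h`` adds linear growth to perimeter
    colonies after ``edge_onset_h`` (the late nutrient edge effect).  Returns
    (agar_run, growth_run, truth) where truth maps well label to that well's
    curve record, plus the agar field under key ``"__agar__"``.
    """
    geometry = layout.geometry
    times = default_times_s() if times_s is None else np.asarray(times_s, float)
    base = default_params or GrowthParams()
    agar = _agar_field(base, geometry, rng)

    agar_times = np.arange(agar_passes) * 240.0  # 4-min passes for a snapshot blank
    agar_readings = agar[None, :] + rng.normal(
        0.0, base.sigma0, size=(agar_passes, geometry.n_wells))
    agar_run = ReadingRun(plate_id, geometry, "agar-blank",
                          _EPOCH, agar_times, np.minimum(agar_readings, SATURATION_CEILING))

    shared = (rng.normal(0.0, shared_sigma, size=len(times))
              if shared_sigma > 0 else None)
    perimeter = _perimeter_mask(geometry)
    readings = np.empty((len(times), geometry.n_wells))
    truth: dict[str, dict] = {"__agar__": {"field": agar}}
    t_h = times / 3600.0
    labels = geometry.labels()
    for w, lab in enumerate(labels):
        strain = layout.strain_at(lab)
        if strain == "":
            noise = rng.normal(0.0, base.sigma0, size=len(times))
            readings[:, w] = np.minimum(agar[w] + noise, SATURATION_CEILING)
            continue
        params = params_by_strain.get(strain, base)
        raw, rec = simulate_curve(params, times, rng, agar=agar[w],
                                  shared_noise=shared)
        if edge_boost_per_h > 0 and perimeter[w]:
            extra = edge_boost_per_h * np.clip(t_h - params.edge_onset_h, 0.0, None)
            raw = np.minimum(raw + extra, SATURATION_CEILING)
            rec = dict(rec, edge_boost_per_h=edge_boost_per_h)
        readings[:, w] = raw
        truth[lab] = rec
    growth_start = _EPOCH.replace(hour=10)  # blank measured an hour before printing
    growth_run = ReadingRun(plate_id, geometry, program, growth_start, times, readings)
    return agar_run, growth_run, truth


def random_layout(geometry: PlateGeometry, n_strains: int, replicates: int,
                  rng: np.random.Generator, prefix: str = "S") -> ArrayLayout:
    """Layout with ``n_strains`` strains × ``replicates`` copies at random positions."""
    n = n_strains * replicates
    if n > geometry.n_wells:
        raise ValueError("more colonies than wells")
    labels = geometry.labels()
    chosen = rng.choice(geometry.n_wells, size=n, replace=False)
    layout = ArrayLayout.empty(geometry)
    for k, w in enumerate(chosen):
        strain = f"{prefix}{k // replicates + 1:03d}"
        layout.table.at[labels[w], "strain"] = strain
        layout.table.at[labels[w], "replicate"] = str(k % replicates + 1)
    return layout


# ---------------------------------------------------------------------------
# Haploid crosses with tetrad structure
# ---------------------------------------------------------------------------

@dataclass
class PlantedQTL:
    chrom: str
    pos_cM: float
    effect_sd: float  # additive effect in units of the phenotype noise SD


@dataclass
class CrossSimParams:
    """Simulated cross design: tetrads of 4 spores, genotyped on a marker grid.

    Defaults follow a 24-tetrad dissection (96 haploid F1 segregants) with two
    biological replicates per segregant, markers every 20 cM on a handful of
    chromosomes, and unit phenotype noise.
    """

    n_tetrads: int = 24
    chrom_lengths_cM: Sequence[float] = (240.0, 240.0, 240.0, 240.0)
    marker_spacing_cM: float = 20.0
    qtls: Sequence[PlantedQTL] = ()
    replicate_count: int = 2
    noise_sd: float = 1.0
    baseline: float = 1.0
    cross_id: str = "XY"


def _build_map(params: CrossSimParams) -> GeneticMap:
    rows = []
    for c, length in enumerate(params.chrom_lengths_cM, start=1):
        chrom = f"chr{c:02d}"
        positions = np.arange(0.0, length + 1e-9, params.marker_spacing_cM)
        for i, pos in enumerate(positions, start=1):
            rows.append({"marker": f"{chrom}_m{i:02d}", "chrom": chrom,
                         "pos_cM": float(pos)})
    return GeneticMap(pd.DataFrame(rows))


def _simulate_spore(gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One meiotic product: Markov chain along each chromosome (Haldane model)."""
    geno = np.empty(gmap.n_markers, dtype=float)
    for chrom, idx in gmap.chrom_indices().items():
        positions = gmap.table["pos_cM"].to_numpy()[idx]
        g = int(rng.integers(0, 2))
        geno[idx[0]] = g
        for j in range(1, len(idx)):
            r = haldane_recombination(positions[j] - positions[j - 1])
            if rng.random() < r:
                g = 1 - g
            geno[idx[j]] = g
    return geno


def simulate_cross(params: CrossSimParams, rng: np.random.Generator
                   ) -> tuple[GenotypeMatrix, GeneticMap, pd.DataFrame, dict]:
    """Simulate genotypes and phenotypes for one cross.

    Tetrads are built as two complementary spore pairs: spores 1 and 2 are
    independent meiotic products and spores 3 and 4 their allele-flipped
    complements, so every marker segregates exactly 2:2 within each tetrad.
    Phenotype per replicate = baseline + sum(effect * genotype at the marker
    nearest each planted QTL) + N(0, noise_sd); replicates share the strain
    genotype and differ only in noise.

    Returns (genotypes, map, phenotypes, truth); phenotypes has one row per
    strain × replicate with columns strain, tetrad, replicate, value.
    """
    gmap = _build_map(params)
    rows, meta = [], []
    for t in range(1, params.n_tetrads + 1):
        s1 = _simulate_spore(gmap, rng)
        s2 = _simulate_spore(gmap, rng)
        for k, g in enumerate((s1, s2, 1.0 - s1, 1.0 - s2), start=1):
            strain = f"{params.cross_id}T{t:02d}{string.ascii_lowercase[k - 1]}"
            rows.append(g)
            meta.append({"strain": strain, "cross": params.cross_id,
                         "tetrad": f"T{t:02d}", "replicate": ""})
    geno = GenotypeMatrix(
        pd.DataFrame(np.array(rows), index=[m["strain"] for m in meta],
                     columns=gmap.table["marker"].tolist()),
        pd.DataFrame(meta).set_index("strain"))

    qtl_markers = []
    for q in params.qtls:
        marker = gmap.nearest_marker(q.chrom, q.pos_cM)
        qtl_markers.append((marker, q.effect_sd))
    pheno_rows = []
    for strain in geno.individuals:
        genetic = params.baseline
        for marker, effect in qtl_markers:
            genetic += effect * params.noise_sd * geno.table.at[strain, marker]
        for rep in range(1, params.replicate_count + 1):
            value = genetic + rng.normal(0.0, params.noise_sd)
            pheno_rows.append({"strain": strain, "cross": params.cross_id,
                               "tetrad": geno.meta.at[strain, "tetrad"],
                               "replicate": str(rep), "value": value})
    phen_table = pd.DataFrame(pheno_rows)
    truth = {"qtl_markers": [{"marker": m, "effect_sd": e,
                              "chrom": gmap.marker_chrom(m),
                              "pos_cM": gmap.marker_pos(m)}
                             for m, e in qtl_markers],
             "noise_sd": params.noise_sd}
    return geno, gmap, phen_table, truth
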
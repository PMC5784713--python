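"""Single-QTL genome scan for haploid biallelic crosses.

The scan regresses the phenotype on the probability of carrying one parental
allele at each position of a 1-cM pseudomarker grid (Haley–Knott-style
regression).  Genotype probabilities come from a two-state Markov chain along
each chromosome with Haldane recombination fractions, conditioning on the
nearest informative flanking markers.  Genome-wide significance is assessed
by permuting phenotypes within strata (tetrad × replicate group, so a sample
never exchanges values with its own biological replicate), taking the 5%
upper quantile of the permutation distribution of the maximum LOD.  Peaks
above the threshold are reported with 1.5-LOD support intervals, and
intervals from multiple crosses are merged into distinct regions.

LOD at a position is (n/2)·log10(RSS0/RSS1): the residual sum of squares
about the phenotype mean versus that of the one-predictor regression.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .plate_core import PlatePhenError


class ScanError(PlatePhenError):
    """Genome scan cannot be run on the given inputs."""


class ExportError(PlatePhenError):
    """Cross data cannot be exported in the requested layout."""


# ---------------------------------------------------------------------------
# Map, genotypes
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Ordered markers (name, chromosome, position in cM)."""

    table: pd.DataFrame  # columns: marker, chrom, pos_cM

    def __post_init__(self) -> None:
        req = {"marker", "chrom", "pos_cM"}
        if not req <= set(self.table.columns):
            raise ScanError(f"genetic map needs columns {sorted(req)}")
        self.table = self.table.reset_index(drop=True)
        for chrom, sub in self.table.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos_cM"].to_numpy()) < 0):
                raise ScanError(f"marker positions decrease on {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Chromosome -> integer marker indices, in map order."""
        return {str(chrom): sub.index.to_numpy()
                for chrom, sub in self.table.groupby("chrom", sort=False)}

    def marker_chrom(self, marker: str) -> str:
        return str(self.table.set_index("marker").at[marker, "chrom"])

    def marker_pos(self, marker: str) -> float:
        return float(self.table.set_index("marker").at[marker, "pos_cM"])

    def nearest_marker(self, chrom: str, pos_cM: float) -> str:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise ScanError(f"no markers on chromosome {chrom!r}")
        i = (sub["pos_cM"] - pos_cM).abs().idxmin()
        return str(self.table.at[i, "marker"])

    def pseudomarker_grid(self, step: float = 1.0) -> pd.DataFrame:
        """Marker positions plus a regular grid every ``step`` cM per chromosome."""
        if step <= 0:
            raise ScanError("grid step must be positive")
        rows = []
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos_cM"].to_numpy()
            grid = np.union1d(pos, np.arange(pos.min(), pos.max() + 1e-9, step))
            rows.append(pd.DataFrame({"chrom": str(chrom), "pos_cM": grid}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class GenotypeMatrix:
    """Individuals × markers, codes in {0, 1, NaN} for one cross's parental alleles.

    ``meta`` is indexed by strain with columns cross, tetrad, replicate.
    """

    table: pd.DataFrame
    meta: pd.DataFrame

    @property
    def individuals(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# Recombination and genotype probabilities
# ---------------------------------------------------------------------------

def haldane_recombination(d_cM):
    """Haldane map function r = (1 - exp(-2d/100)) / 2, no interference."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ScanError("genetic distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


def _trans(g, r):
    """P(state g -> state 1) across recombination fraction r (elementwise)."""
    return np.where(g == 1, 1.0 - r, r)


def genotype_probability(gL, gR, dL, dR) -> float:
    """P(allele code 1) at a query position given flanking observed codes.

    Either flank may be None (unobserved); with no information the haploid
    two-state chain gives 0.5.  With both flanks, the probability is the
    relative weight of the path passing through state 1.
    """
    if gL is None and gR is None:
        return 0.5
    if gR is None:
        return float(_trans(gL, haldane_recombination(dL)))
    if gL is None:
        # chain is reversible with uniform stationary distribution
        return float(_trans(gR, haldane_recombination(dR)))
    rL, rR = haldane_recombination(dL), haldane_recombination(dR)
    p1 = _trans(gL, rL) * np.where(gR == 1, 1.0 - rR, rR)
    p0 = (1.0 - _trans(gL, rL)) * np.where(gR == 1, rR, 1.0 - rR)
    return float(p1 / (p0 + p1))


def compute_genotype_probs(genotypes: GenotypeMatrix, gmap: GeneticMap,
                           step: float = 1.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Allele-1 probabilities for every individual at every grid position.

    Returns (grid, P) where grid has columns chrom/pos_cM and P is an
    (individuals × positions) matrix.  Individuals with a missing call at a
    marker are conditioned on their nearest observed markers instead.
    """
    grid = gmap.pseudomarker_grid(step)
    n_ind = len(genotypes.individuals)
    P = np.full((n_ind, len(grid)), 0.5)
    G = genotypes.table.to_numpy(dtype=float)
    marker_order = list(genotypes.table.columns)
    map_markers = gmap.table["marker"].tolist()
    if marker_order != map_markers:
        try:
            G = genotypes.table[map_markers].to_numpy(dtype=float)
        except KeyError as exc:
            raise ScanError("genotype matrix markers do not match the map") from exc

    col = 0
    for chrom, idx in gmap.chrom_indices().items():
        mpos = gmap.table["pos_cM"].to_numpy()[idx]
        sub = G[:, idx]                      # (n_ind, n_markers_on_chrom)
        qpos = grid.loc[grid["chrom"] == chrom, "pos_cM"].to_numpy()
        block = np.empty((n_ind, len(qpos)))
        complete = not np.isnan(sub).any()
        if complete:
            li = np.searchsorted(mpos, qpos, side="right") - 1
            ri = np.searchsorted(mpos, qpos, side="left")
            li = np.clip(li, 0, len(mpos) - 1)
            ri = np.clip(ri, 0, len(mpos) - 1)
            for j, q in enumerate(qpos):
                gL, gR = sub[:, li[j]], sub[:, ri[j]]
                dL, dR = q - mpos[li[j]], mpos[ri[j]] - q
                if dL <= 0 and mpos[li[j]] == q:
                    block[:, j] = gL
                    continue
                rL, rR = haldane_recombination(dL), haldane_recombination(dR)
                p1 = _trans(gL, rL) * np.where(gR == 1, 1.0 - rR, rR)
                p0 = (1.0 - _trans(gL, rL)) * np.where(gR == 1, rR, 1.0 - rR)
                block[:, j] = p1 / (p0 + p1)
        else:
            for i in range(n_ind):
                obs = np.flatnonzero(~np.isnan(sub[i]))
                if obs.size == 0:
                    block[i, :] = 0.5
                    continue
                opos, og = mpos[obs], sub[i, obs]
                for j, q in enumerate(qpos):
                    lj = np.searchsorted(opos, q, side="right") - 1
                    rj = np.searchsorted(opos, q, side="left")
                    gL = int(og[lj]) if lj >= 0 else None
                    gR = int(og[rj]) if rj < len(opos) else None
                    dL = q - opos[lj] if lj >= 0 else 0.0
                    dR = opos[rj] - q if rj < len(opos) else 0.0
                    block[i, j] = genotype_probability(gL, gR, dL, dR)
        P[:, col:col + len(qpos)] = block
        col += len(qpos)
    return grid, P


# ---------------------------------------------------------------------------
# LOD regression and the genome scan
# ---------------------------------------------------------------------------

def regression_lod(y, p) -> float:
    """LOD of the single-predictor regression of phenotype y on probability p.

    LOD = (n/2)·log10(RSS0/RSS1); incomplete (NaN) cases are dropped
    pairwise.  A constant predictor carries no information (LOD 0); a
    zero-variance phenotype leaves the LOD undefined.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(y) & np.isfinite(p)
    y, p = y[ok], p[ok]
    n = len(y)
    if n < 3:
        raise ScanError(f"need >= 3 complete cases, got {n}")
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0.0:
        raise ScanError("phenotype has zero variance; LOD undefined")
    pc = p - p.mean()
    spp = float(pc @ pc)
    if spp == 0.0:
        return 0.0
    r2 = float(yc @ pc) ** 2 / (spp * rss0)
    r2 = min(r2, 1.0 - 1e-15)
    return (n / 2.0) * math.log10(1.0 / (1.0 - r2))


class GenomeScanner:
    """Precomputes genotype probabilities once, then scans any phenotype fast.

    ``scan(y)`` returns the LOD profile over the pseudomarker grid;
    ``max_lod_many(Y)`` returns genome-wide maxima for many phenotype columns
    at once (used for permutations).
    """

    def __init__(self, genotypes: GenotypeMatrix, gmap: GeneticMap,
                 step: float = 1.0):
        self.genotypes = genotypes
        self.gmap = gmap
        self.grid, self.P = compute_genotype_probs(genotypes, gmap, step)
        self._Pc = self.P - self.P.mean(axis=0, keepdims=True)
        self._spp = np.einsum("ij,ij->j", self._Pc, self._Pc)

    @property
    def individuals(self) -> list[str]:
        return self.genotypes.individuals

    def lod_profile(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if np.isnan(y).any():
            raise ScanError("drop individuals with missing phenotype before scanning")
        n = len(y)
        if n != self.P.shape[0]:
            raise ScanError("phenotype length does not match individuals")
        yc = y - y.mean()
        syy = float(yc @ yc)
        if syy == 0.0:
            raise ScanError("phenotype has zero variance; LOD undefined")
        sxy = yc @ self._Pc
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(self._spp > 0, sxy ** 2 / (self._spp * syy), 0.0)
        r2 = np.minimum(r2, 1.0 - 1e-15)
        return (n / 2.0) * np.log10(1.0 / (1.0 - r2))

    def scan(self, y: np.ndarray) -> pd.DataFrame:
        out = self.grid.copy()
        out["lod"] = self.lod_profile(y)
        return out

    def max_lod_many(self, Y: np.ndarray) -> np.ndarray:
        """Genome-wide maximum LOD for each column of Y (individuals × sets)."""
        Y = np.asarray(Y, dtype=float)
        n = Y.shape[0]
        Yc = Y - Y.mean(axis=0, keepdims=True)
        syy = np.einsum("ij,ij->j", Yc, Yc)
        S = self._Pc.T @ Yc                       # positions × sets
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = S ** 2 / (self._spp[:, None] * syy[None, :])
        r2 = np.where(np.isfinite(r2), r2, 0.0)
        r2 = np.minimum(r2.max(axis=0), 1.0 - 1e-15)
        return (n / 2.0) * np.log10(1.0 / (1.0 - r2))


def genome_scan(phenotypes: pd.DataFrame, genotypes: GenotypeMatrix,
                gmap: GeneticMap, step: float = 1.0) -> pd.DataFrame:
    """LOD profile for one cross; replicates enter as separate rows.

    ``phenotypes`` needs columns strain and value (one row per strain ×
    replicate); each row is matched to its strain's genotype, so biological
    replicates contribute independent observations rather than being
    averaged.
    """
    phen = phenotypes.dropna(subset=["value"])
    known = set(genotypes.individuals)
    phen = phen[phen["strain"].isin(known)]
    if phen.empty:
        raise ScanError("no phenotyped individuals overlap the genotype matrix")
    expanded = GenotypeMatrix(
        genotypes.table.loc[phen["strain"]].reset_index(drop=True).set_axis(
            range(len(phen)), axis=0),
        genotypes.meta.loc[phen["strain"]].reset_index(drop=True))
    scanner = GenomeScanner(expanded, gmap, step)
    return scanner.scan(phen["value"].to_numpy())


# ---------------------------------------------------------------------------
# Stratified permutations and the significance threshold
# ---------------------------------------------------------------------------

def stratified_permutation(y: np.ndarray, strata: Sequence,
                           rng: np.random.Generator) -> np.ndarray:
    """Shuffle phenotype values only within strata.

    With strata = tetrad × replicate group, a sample can never exchange
    values with its own biological replicate (replicates sit in different
    strata); each stratum's multiset of values is preserved exactly.
    """
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if len(strata) != len(y):
        raise ScanError("strata labels must match phenotype length")
    out = y.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) > 1:
            out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


def threshold_order_statistic(n_perm: int, alpha: float) -> int:
    """1-based order statistic used for the threshold: ceil((1-alpha)(n_perm+1))."""
    return min(n_perm, math.ceil((1.0 - alpha) * (n_perm + 1)))


def permutation_threshold(y: np.ndarray, strata: Sequence,
                          scanner, n_perm: int = 1000, alpha: float = 0.05,
                          rng: np.random.Generator | None = None) -> float:
    """Genome-wide LOD threshold from stratified phenotype permutations.

    ``scanner`` is a :class:`GenomeScanner` (fast vectorised path) or any
    callable mapping a permuted phenotype vector to its genome-wide maximum
    LOD.  The threshold is the ceil((1-alpha)(n_perm+1))-th order statistic
    of the n_perm maxima.
    """
    if n_perm < 20:
        raise ScanError("need at least 20 permutations")
    rng = np.random.default_rng() if rng is None else rng
    Y = np.column_stack([stratified_permutation(y, strata, rng)
                         for _ in range(n_perm)])
    if isinstance(scanner, GenomeScanner):
        maxima = scanner.max_lod_many(Y)
    else:
        maxima = np.array([scanner(Y[:, k]) for k in range(n_perm)])
    k = threshold_order_statistic(n_perm, alpha)
    return float(np.sort(maxima)[k - 1])


# ---------------------------------------------------------------------------
# Peaks, support intervals, regions
# ---------------------------------------------------------------------------

@dataclass
class QTLPeak:
    chrom: str
    pos_cM: float
    lod: float
    lo_cM: float
    hi_cM: float


@dataclass
class ScanResult:
    """One cross's scan: LOD profile, permutation threshold, peaks + intervals."""

    profile: pd.DataFrame  # chrom, pos_cM, lod
    threshold: float
    peaks: list[QTLPeak]


def lod_support_interval(positions: np.ndarray, lods: np.ndarray,
                         peak_index: int, drop: float = 1.5) -> tuple[float, float]:
    """Support interval around a peak: extend until the LOD falls by > ``drop``.

    The contiguous run of positions within ``drop`` LOD units of the peak is
    expanded by one position on each side (the first drop-below positions are
    included), clipped at the chromosome ends.
    """
    cutoff = lods[peak_index] - drop
    lo = peak_index
    while lo > 0 and lods[lo - 1] >= cutoff:
        lo -= 1
    hi = peak_index
    while hi < len(lods) - 1 and lods[hi + 1] >= cutoff:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lods) - 1)
    return float(positions[lo]), float(positions[hi])


def find_peaks(profile: pd.DataFrame, threshold: float,
               drop: float = 1.5) -> list[QTLPeak]:
    """Local LOD maxima above the threshold, per chromosome.

    Peaks whose support intervals overlap are merged, keeping the higher
    peak (ties broken toward the smaller cM position).
    """
    peaks: list[QTLPeak] = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        pos = sub["pos_cM"].to_numpy()
        lod = sub["lod"].to_numpy()
        n = len(lod)
        candidates = []
        for i in range(n):
            if lod[i] < threshold:
                continue
            left = lod[i - 1] if i > 0 else -np.inf
            right = lod[i + 1] if i < n - 1 else -np.inf
            if lod[i] > left and lod[i] >= right:
                candidates.append(i)
        cand_peaks = []
        for i in candidates:
            lo, hi = lod_support_interval(pos, lod, i, drop)
            cand_peaks.append(QTLPeak(str(chrom), float(pos[i]), float(lod[i]), lo, hi))
        # merge overlapping support intervals, keep the higher peak
        cand_peaks.sort(key=lambda p: (-p.lod, p.pos_cM))
        kept: list[QTLPeak] = []
        for p in cand_peaks:
            if any(p.lo_cM <= q.hi_cM and q.lo_cM <= p.hi_cM for q in kept):
                continue
            kept.append(p)
        kept.sort(key=lambda p: p.pos_cM)
        peaks.extend(kept)
    return peaks


@dataclass
class Region:
    chrom: str
    lo_cM: float
    hi_cM: float
    members: list  # the QTL intervals merged into this region


def merge_regions(intervals: Iterable[tuple[str, float, float]]) -> list[Region]:
    """Merge overlapping (chrom, lo, hi) intervals across crosses into regions.

    Overlap is transitive: a chain a∩b, b∩c lands all three in one region
    even if a and c are disjoint.  Region count is at most the QTL count.
    """
    by_chrom: dict[str, list[tuple[float, float, tuple]]] = {}
    for item in intervals:
        chrom, lo, hi = item[0], float(item[1]), float(item[2])
        if hi < lo:
            raise ScanError(f"interval with hi < lo on {chrom}")
        by_chrom.setdefault(str(chrom), []).append((lo, hi, item))
    regions: list[Region] = []
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom])
        cur_lo, cur_hi, members = ivs[0][0], ivs[0][1], [ivs[0][2]]
        for lo, hi, item in ivs[1:]:
            if lo <= cur_hi:  # inclusive endpoints count as overlap
                cur_hi = max(cur_hi, hi)
                members.append(item)
            else:
                regions.append(Region(chrom, cur_lo, cur_hi, members))
                cur_lo, cur_hi, members = lo, hi, [item]
        regions.append(Region(chrom, cur_lo, cur_hi, members))
    return regions


def scan_with_threshold(phenotypes: pd.DataFrame, genotypes: GenotypeMatrix,
                        gmap: GeneticMap, n_perm: int = 1000,
                        alpha: float = 0.05, step: float = 1.0,
                        drop: float = 1.5,
                        rng: np.random.Generator | None = None) -> ScanResult:
    """Full single-cross pipeline: scan, stratified permutations, peak calls.

    Permutation strata are tetrad × replicate group, read from the genotype
    metadata and the phenotype table's replicate column.
    """
    phen = phenotypes.dropna(subset=["value"])
    known = set(genotypes.individuals)
    phen = phen[phen["strain"].isin(known)].reset_index(drop=True)
    if phen.empty:
        raise ScanError("no phenotyped individuals overlap the genotype matrix")
    expanded = GenotypeMatrix(
        genotypes.table.loc[phen["strain"]].reset_index(drop=True),
        genotypes.meta.loc[phen["strain"]].reset_index(drop=True))
    scanner = GenomeScanner(expanded, gmap, step)
    y = phen["value"].to_numpy()
    tetrads = genotypes.meta.loc[phen["strain"], "tetrad"].to_numpy()
    reps = phen["replicate"].astype(str).to_numpy() if "replicate" in phen else \
        np.array([""] * len(phen))
    strata = np.array([f"{t}|{r}" for t, r in zip(tetrads, reps)])
    profile = scanner.scan(y)
    threshold = permutation_threshold(y, strata, scanner, n_perm, alpha, rng)
    peaks = find_peaks(profile, threshold, drop)
    return ScanResult(profile, threshold, peaks)


# ---------------------------------------------------------------------------
# R/qtl csv-format export / import
# ---------------------------------------------------------------------------

def export_rqtl_csv(phenotypes: pd.DataFrame, genotypes: GenotypeMatrix,
                    gmap: GeneticMap, stream=None,
                    pheno_name: str = "phenotype") -> str:
    """Write one cross in the R/qtl "csv" cross layout.

    Row 1: phenotype name then marker names; row 2: blank then chromosomes;
    row 3: blank then cM positions; then one row per individual (strain ×
    replicate) with the phenotype value and allele codes A/B (missing cells
    empty).
    """
    crosses = set(genotypes.meta["cross"].astype(str)) - {""}
    if len(crosses) > 1:
        raise ExportError(f"R/qtl export takes one cross, got {sorted(crosses)}")
    markers = list(genotypes.table.columns)
    mtab = gmap.table.set_index("marker")
    out = io.StringIO()
    w = csv.writer(out, lineterminator="\n")
    w.writerow([pheno_name] + markers)
    w.writerow([""] + [str(mtab.at[m, "chrom"]) for m in markers])
    w.writerow([""] + [repr(float(mtab.at[m, "pos_cM"])) for m in markers])
    code = {0.0: "A", 1.0: "B"}
    for _, row in phenotypes.iterrows():
        strain = row["strain"]
        g = genotypes.table.loc[strain]
        w.writerow([repr(float(row["value"]))] +
                   ["" if math.isnan(v) else code[float(v)] for v in g])
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_rqtl_csv(stream, cross_id: str = "") -> tuple[pd.DataFrame, GenotypeMatrix, GeneticMap]:
    """Inverse of :func:`export_rqtl_csv` (individuals named ind001, ind002, ..)."""
    text = stream.read() if hasattr(stream, "read") else stream
    rows = list(csv.reader(text.splitlines()))
    if len(rows) < 4:
        raise ExportError("R/qtl csv needs 3 header rows plus data")
    pheno_name, markers = rows[0][0], rows[0][1:]
    chroms = rows[1][1:]
    positions = [float(v) for v in rows[2][1:]]
    gmap = GeneticMap(pd.DataFrame({"marker": markers, "chrom": chroms,
                                    "pos_cM": positions}))
    code = {"A": 0.0, "B": 1.0, "": math.nan}
    phen_rows, geno_rows, names = [], [], []
    for i, rec in enumerate(rows[3:], start=1):
        name = f"ind{i:03d}"
        names.append(name)
        phen_rows.append({"strain": name, "value": float(rec[0]),
                          "replicate": "1"})
        geno_rows.append([code[v] for v in rec[1:]])
    geno = GenotypeMatrix(
        pd.DataFrame(geno_rows, index=names, columns=markers),
        pd.DataFrame({"strain": names, "cross": cross_id, "tetrad": "",
                      "replicate": ""}).set_index("strain"))
    phen = pd.DataFrame(phen_rows)
    phen.attrs["pheno_name"] = pheno_name
    return phen, geno, gmap


def load_genetic_map(stream) -> GeneticMap:
    """Read a genetic map CSV with columns marker,chrom,cM (or pos_cM)."""
    text = stream.read() if hasattr(stream, "read") else stream
    df = pd.read_csv(io.StringIO(text), comment="#")
    if "cM" in df.columns and "pos_cM" not in df.columns:
        df = df.rename(columns={"cM": "pos_cM"})
    return GeneticMap(df)


def load_genotypes(stream, meta_columns=("cross", "tetrad", "replicate")
                   ) -> GenotypeMatrix:
    """Read a genotype CSV: strain[,cross,tetrad,replicate],marker1,marker2,..."""
    text = stream.read() if hasattr(stream, "read") else stream
    df = pd.read_csv(io.StringIO(text), comment="#", dtype={"strain": str})
    df = df.set_index("strain")
    meta_cols = [c for c in meta_columns if c in df.columns]
    meta = df[meta_cols].fillna("").astype(str)
    for c in meta_columns:
        if c not in meta.columns:
            meta[c] = ""
    table = df.drop(columns=meta_cols).astype(float)
    return GenotypeMatrix(table, meta)


def write_genotypes(genotypes: GenotypeMatrix, stream=None) -> str:
    out = io.StringIO()
    markers = list(genotypes.table.columns)
    out.write("strain,cross,tetrad,replicate," + ",".join(markers) + "\n")
    for strain in genotypes.individuals:
        meta = genotypes.meta.loc[strain]
        vals = ["" if math.isnan(v) else str(int(v))
                for v in genotypes.table.loc[strain]]
        out.write(",".join([strain, meta["cross"], meta["tetrad"],
                            meta["replicate"]] + vals) + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def write_genetic_map(gmap: GeneticMap, stream=None) -> str:
    out = io.StringIO()
    out.write("marker,chrom,cM\n")
    for _, row in gmap.table.iterrows():
        out.write(f"{row['marker']},{row['chrom']},{repr(float(row['pos_cM']))}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
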
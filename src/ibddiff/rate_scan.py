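"""Case-control and one-sample IBD rate scans.

The scan walks a grid of focal positions spaced uniformly in genetic
distance (default 0.05 cM).  At each position ``m`` the IBD rate of a group
is the fraction of eligible haplotype pairs — unordered pairs of haplotypes
from distinct individuals, ``n_pairs = C(2n, 2) - n`` for ``n`` diploids —
with at least one detected segment overlapping the position.  Case and
control rates are standardized robustly (outlier positions masked at
median + 4 sd before moments are taken), their difference is re-standardized
to unit variance, and maximal runs of positions exceeding a critical value
are reported as regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .segments_io import GeneticMap, PhenotypeTable, SegmentTable, _chrom_sort_key


class ScanError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Test-position grid
# ---------------------------------------------------------------------------

@dataclass
class ScanGrid:
    """Focal test positions, uniform in cM per chromosome.

    Positions of all chromosomes are concatenated; ``chrom_slice`` gives a
    chromosome's view.  Grid positions are anchored at each chromosome's
    first map position, at ``first + k * step_cm``.
    """

    chroms: tuple
    cm: np.ndarray
    bp: np.ndarray
    step_cm: float
    _slices: dict = field(default_factory=dict, repr=False)

    @property
    def M(self) -> int:
        return len(self.cm)

    def chrom_slice(self, chrom) -> slice:
        return self._slices[str(chrom)]

    @property
    def chrom_labels(self) -> np.ndarray:
        out = np.empty(self.M, dtype=object)
        for c in self.chroms:
            out[self.chrom_slice(c)] = c
        return out


def build_grid(gmap: GeneticMap, step_cm: float = 0.05) -> ScanGrid:
    """Lay out focal positions every ``step_cm`` within each chromosome's map span."""
    if step_cm <= 0:
        raise ScanError("step_cm must be positive")
    chroms = sorted(gmap.chromosomes, key=_chrom_sort_key)
    if not chroms:
        raise ScanError("genetic map has no chromosomes")
    cms, bps, slices = [], [], {}
    offset = 0
    for chrom in chroms:
        first, last = gmap.span_cm(chrom)
        k = int(math.floor((last - first) / step_cm + 1e-9))
        pos_cm = first + step_cm * np.arange(k + 1)
        pos_bp = np.rint(gmap.cm_to_bp(chrom, pos_cm)).astype(np.int64)
        cms.append(pos_cm)
        bps.append(pos_bp)
        slices[str(chrom)] = slice(offset, offset + k + 1)
        offset += k + 1
    return ScanGrid(tuple(str(c) for c in chroms), np.concatenate(cms),
                    np.concatenate(bps), float(step_cm), slices)


# ---------------------------------------------------------------------------
# IBD rates
# ---------------------------------------------------------------------------

@dataclass
class RateSeries:
    """Per-position IBD sharing rates of one group on a grid."""

    grid: ScanGrid
    values: np.ndarray
    n_pairs: int
    group: str = ""


def n_haplotype_pairs(n_samples: int) -> int:
    """Unordered haplotype pairs between distinct diploid individuals."""
    return 2 * n_samples * (n_samples - 1)


def _union_counts(i0, i1, pair, n_positions):
    """Distinct-pair coverage counts on grid indices.

    Segments are half-open index intervals ``[i0, i1)`` tagged by pair; a
    pair contributes at most one count per position, so same-pair intervals
    are merged (segmented running-max sweep) before accumulation into a
    difference array.
    """
    if len(i0) == 0:
        return np.zeros(n_positions, dtype=np.int64)
    order = np.lexsort((i0, pair))
    p, s, e = pair[order], i0[order], i1[order]
    new = np.empty(len(p), dtype=bool)
    new[0] = True
    new[1:] = p[1:] != p[:-1]
    gid = np.cumsum(new) - 1
    big = np.int64(n_positions + 1)
    run = np.maximum.accumulate(e + gid * big) - gid * big
    prev = np.empty_like(run)
    prev[0] = 0
    prev[1:] = run[:-1]
    prev[new] = 0
    s_eff = np.maximum(s, prev)
    valid = e > s_eff
    diff = np.zeros(n_positions + 1, dtype=np.int64)
    np.add.at(diff, s_eff[valid], 1)
    np.add.at(diff, e[valid], -1)
    return np.cumsum(diff[:-1])


def ibd_rate(segments: SegmentTable, grid: ScanGrid, group_ids,
             group: str = "") -> RateSeries:
    """IBD sharing rate of a sample group at every grid position.

    The numerator at position ``m`` is the number of distinct haplotype
    pairs (both individuals in ``group_ids``, individuals distinct) with at
    least one segment whose bp interval ``[start, end)`` contains the
    position; the denominator is ``C(2n, 2) - n``.
    """
    ids = set(map(str, group_ids))
    n = len(ids)
    if n < 2:
        raise ScanError("need at least 2 samples to form haplotype pairs")
    n_pairs = n_haplotype_pairs(n)
    df = segments.data
    sel = df["ID1"].isin(ids).to_numpy() & df["ID2"].isin(ids).to_numpy()
    sub = df.loc[sel]
    values = np.zeros(grid.M)
    if len(sub):
        ids_cat = pd.concat([sub["ID1"], sub["ID2"]], ignore_index=True)
        codes, uniques = pd.factorize(ids_cat)
        half = len(sub)
        h1 = codes[:half].astype(np.int64) * 2 + (sub["HAP1"].to_numpy() - 1)
        h2 = codes[half:].astype(np.int64) * 2 + (sub["HAP2"].to_numpy() - 1)
        lo = np.minimum(h1, h2)
        hi = np.maximum(h1, h2)
        pair = pd.factorize(lo * np.int64(2 * len(uniques)) + hi)[0]
        chrom_arr = sub["CHROM"].to_numpy()
        start = sub["START"].to_numpy()
        end = sub["END"].to_numpy()
        for chrom in grid.chroms:
            csel = chrom_arr == chrom
            if not csel.any():
                continue
            sl = grid.chrom_slice(chrom)
            gbp = grid.bp[sl]
            i0 = np.searchsorted(gbp, start[csel], side="left")
            i1 = np.searchsorted(gbp, end[csel], side="left")
            keep = i1 > i0
            counts = _union_counts(i0[keep], i1[keep], pair[csel][keep], len(gbp))
            values[sl] = counts / n_pairs
    return RateSeries(grid, values, n_pairs, group)


# ---------------------------------------------------------------------------
# Robust standardization
# ---------------------------------------------------------------------------

@dataclass
class GroupStats:
    initial_median: float
    initial_sd: float
    cutoff: float          # initial_median + 4 * initial_sd
    revised_mean: float    # over non-excluded positions
    revised_sd: float


@dataclass
class StandardizationStats:
    case: GroupStats
    control: Optional[GroupStats]
    diff_mean: Optional[float]
    diff_sd: Optional[float]
    n_excluded: int


@dataclass
class ScanTrack:
    """Standardized scan tracks and the exclusion mask.

    ``z`` is the test-statistic track: the re-standardized rate difference
    for a case-control scan, or the single group's standardized rate for a
    one-sample (selection) scan.  Masked positions carry valid ``z`` values
    but are excluded from all moment and decay-parameter estimation.
    """

    grid: ScanGrid
    z: np.ndarray
    excluded: np.ndarray
    stats: StandardizationStats
    rate_case: Optional[RateSeries] = None
    rate_control: Optional[RateSeries] = None
    z_case: Optional[np.ndarray] = None
    z_control: Optional[np.ndarray] = None

    @property
    def two_sample(self) -> bool:
        return self.z_control is not None

    @property
    def z_diff(self) -> np.ndarray:
        return self.z

    def per_chrom(self, values=None):
        vals = self.z if values is None else values
        return [vals[self.grid.chrom_slice(c)] for c in self.grid.chroms]


def _group_stats(values: np.ndarray, mask_from=None):
    med = float(np.median(values))
    sd0 = float(np.std(values, ddof=1))
    cutoff = med + 4.0 * sd0
    return med, sd0, cutoff


def robust_standardize(case: RateSeries, control: RateSeries) -> ScanTrack:
    """Outlier-masked standardization of case/control rates and their difference.

    1. per-group initial median and sd over all positions; outlier cutoff
       at median + 4 sd;
    2. mask positions where *either* group's rate exceeds its cutoff;
    3. revised per-group mean/sd over unmasked positions; standardize the
       whole track (masked positions included) with the revised moments;
    4. re-standardize the difference of standardized tracks by its mean and
       sd over unmasked positions.
    """
    if case.grid is not control.grid and case.grid.M != control.grid.M:
        raise ScanError("case and control series must share a grid")
    y1, y0 = case.values, control.values
    med1, sd1_init, cut1 = _group_stats(y1)
    med0, sd0_init, cut0 = _group_stats(y0)
    excluded = (y1 > cut1) | (y0 > cut0)
    ok = ~excluded
    if not ok.any():
        raise ScanError("all positions excluded by the outlier mask")
    mu1, s1 = float(y1[ok].mean()), float(np.std(y1[ok], ddof=1))
    mu0, s0 = float(y0[ok].mean()), float(np.std(y0[ok], ddof=1))
    if s1 == 0 or s0 == 0:
        raise ScanError("revised standard deviation is zero; rates are degenerate")
    z1 = (y1 - mu1) / s1
    z0 = (y0 - mu0) / s0
    d = z1 - z0
    mu_d, s_d = float(d[ok].mean()), float(np.std(d[ok], ddof=1))
    if s_d == 0:
        raise ScanError("difference track has zero variance")
    z = (d - mu_d) / s_d
    stats = StandardizationStats(
        case=GroupStats(med1, sd1_init, cut1, mu1, s1),
        control=GroupStats(med0, sd0_init, cut0, mu0, s0),
        diff_mean=mu_d, diff_sd=s_d, n_excluded=int(excluded.sum()),
    )
    return ScanTrack(case.grid, z, excluded, stats, rate_case=case,
                     rate_control=control, z_case=z1, z_control=z0)


def standardize_single(series: RateSeries) -> ScanTrack:
    """One-sample robust standardization (selection-scan statistic)."""
    y = series.values
    med, sd_init, cut = _group_stats(y)
    excluded = y > cut
    ok = ~excluded
    if not ok.any():
        raise ScanError("all positions excluded by the outlier mask")
    mu, s = float(y[ok].mean()), float(np.std(y[ok], ddof=1))
    if s == 0:
        raise ScanError("revised standard deviation is zero; rates are degenerate")
    z = (y - mu) / s
    stats = StandardizationStats(
        case=GroupStats(med, sd_init, cut, mu, s), control=None,
        diff_mean=None, diff_sd=None, n_excluded=int(excluded.sum()),
    )
    return ScanTrack(series.grid, z, excluded, stats, rate_case=series)


def pointwise_pvalue(z):
    """Upper-tail standard-normal probability P(Z >= z)."""
    return norm.sf(z)


# ---------------------------------------------------------------------------
# Scans and regions
# ---------------------------------------------------------------------------

def case_control_scan(segments: SegmentTable, grid: ScanGrid,
                      case_ids, control_ids) -> ScanTrack:
    """Full two-sample scan: rates per group, then robust standardization."""
    case = ibd_rate(segments, grid, case_ids, group="case")
    control = ibd_rate(segments, grid, control_ids, group="control")
    return robust_standardize(case, control)


def selection_scan(segments: SegmentTable, all_ids, grid: ScanGrid) -> ScanTrack:
    """One-sample excess-IBD scan over a single sample set."""
    if len(set(all_ids)) < 2:
        raise ScanError("need at least 2 samples")
    series = ibd_rate(segments, grid, all_ids, group="all")
    return standardize_single(series)


def permute_phenotypes(phenotypes: PhenotypeTable, seed) -> PhenotypeTable:
    """Random half/half case-control relabelling (extra sample to controls)."""
    ids = sorted(map(str, phenotypes.status.index))
    if len(ids) < 4:
        raise ScanError("need at least 4 samples to permute")
    rng = np.random.Generator(np.random.PCG64(seed))
    perm = rng.permutation(len(ids))
    n_cases = len(ids) // 2
    status = np.zeros(len(ids), dtype=np.int8)
    status[perm[:n_cases]] = 1
    return PhenotypeTable(pd.Series(status, index=np.array(ids, dtype=object)))


def randomized_phenotype_scan(segments: SegmentTable, phenotypes: PhenotypeTable,
                              grid: ScanGrid, seed) -> ScanTrack:
    """Re-run the case-control scan under random phenotype labels.

    Confounders that inflate IBD sharing regardless of phenotype (sweeps,
    population structure) stay significant under relabelling, whereas true
    case-enriched signals vanish.  Uses the same segment table; labels are
    shuffled half/half with a seeded generator.
    """
    permuted = permute_phenotypes(phenotypes, seed)
    return case_control_scan(segments, grid, permuted.cases, permuted.controls)


@dataclass
class Region:
    """A maximal run of consecutive significant grid positions."""

    chrom: str
    max_z: float
    pos_bp: int
    pos_cm: float
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    size_cm: float
    p_value: float
    n_positions: int


def call_regions(track: ScanTrack, z_star: float,
                 include_excluded: bool = False) -> list:
    """Maximal runs of grid positions with ``z >= z_star``, per chromosome.

    Masked (outlier) positions cannot form or extend regions unless
    ``include_excluded`` is set.  A run of ``k`` positions at spacing
    ``step`` reports a size of ``k * step`` cM.
    """
    if not np.isfinite(z_star):
        raise ScanError("z_star must be finite")
    regions = []
    step = track.grid.step_cm
    for chrom in track.grid.chroms:
        sl = track.grid.chrom_slice(chrom)
        z = track.z[sl]
        sig = z >= z_star
        if not include_excluded:
            sig = sig & ~track.excluded[sl]
        if not sig.any():
            continue
        bounds = np.flatnonzero(np.diff(np.concatenate(([0], sig.view(np.int8), [0]))))
        cm = track.grid.cm[sl]
        bp = track.grid.bp[sl]
        for lo, hi in bounds.reshape(-1, 2):
            imax = lo + int(np.argmax(z[lo:hi]))
            regions.append(Region(
                chrom=chrom, max_z=float(z[imax]), pos_bp=int(bp[imax]),
                pos_cm=float(cm[imax]), start_bp=int(bp[lo]), end_bp=int(bp[hi - 1]),
                start_cm=float(cm[lo]), end_cm=float(cm[hi - 1]),
                size_cm=float((hi - lo) * step),
                p_value=float(norm.sf(z[imax])), n_positions=int(hi - lo),
            ))
    return regions
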
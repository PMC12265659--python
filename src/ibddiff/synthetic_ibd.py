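"""Synthetic IBD segment tables with known structure.

Emulates the output of segment detection on a case-control cohort without
running a coalescent simulation.  Each unordered haplotype pair (between
distinct individuals) receives segments from a stationary Poisson process
along the genome: starts at rate ``lambda`` per Morgan and lengths drawn as
``cutoff + Exponential(mean_length)``, mimicking a detector that only
reports segments at or above its length cutoff.  Starts are drawn on a
window extended to the left of each chromosome so that coverage is
stationary across the whole chromosome; segments are clipped at chromosome
boundaries (clipped records can fall below the cutoff, as a detector
truncating at the end of a contig would report).  Under this mechanism the
expected pair-sharing probability at any position is
``1 - exp(-lambda * (mean_length + cutoff) / 100) ~= lambda * (mean_length + cutoff) / 100``,
which serves as a closed-form oracle for the genome-average rate.

On top of the null table, two localized perturbations are available:

* a *risk locus* — a random fraction ``q`` of case-case haplotype pairs
  gains one extra segment overlapping the locus (control pairs untouched),
  the alternative the case-control scan is designed to detect;
* a *carrier confounder* — a fraction ``f`` of all haplotypes, drawn
  blind to phenotype, is designated as carriers and every carrier-carrier
  pair gains a segment overlapping the locus, emulating the excess sharing
  a recent selective sweep induces in cases and controls alike.

Default cohort shape: 1250 cases + 1250 controls on ten 100 cM chromosomes
with a 2.0 cM detection cutoff, a linear 1 cM/Mb map, and a segment rate
giving a genome-average pair-sharing probability of about 1e-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .segments_io import (GeneticMap, PhenotypeTable, SegmentTable,
                          _empty_segment_frame, linear_map)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic case-control IBD dataset."""

    n_cases: int = 1250
    n_controls: int = 1250
    chrom_lengths_cm: tuple = tuple(100.0 for _ in range(10))
    segment_rate_per_morgan: float = 0.025   # lambda: segment starts per pair per Morgan
    mean_length_cm: float = 2.0              # exponential excess over the cutoff
    cutoff_cm: float = 2.0                   # detection threshold
    risk_loci: tuple = ()                    # (chrom, pos_cm, q) triples
    confounder_loci: tuple = ()              # (chrom, pos_cm, f) triples
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 0 or self.n_controls < 0:
            raise SyntheticError("sample counts must be non-negative")
        if self.segment_rate_per_morgan < 0:
            raise SyntheticError("segment rate must be non-negative")
        if self.mean_length_cm <= 0 or self.cutoff_cm < 0:
            raise SyntheticError("length parameters must be positive")
        for _, _, q in self.risk_loci:
            if not 0 <= q <= 1:
                raise SyntheticError("risk-locus fraction q must be in [0, 1]")
        for _, _, f in self.confounder_loci:
            if not 0 <= f <= 1:
                raise SyntheticError("carrier frequency f must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def sample_ids(self):
        width = len(str(self.n_samples))
        return [f"s{i:0{width}d}" for i in range(1, self.n_samples + 1)]

    def phenotypes(self) -> PhenotypeTable:
        """Random case/control assignment, deterministic in the spec seed."""
        rng = np.random.Generator(np.random.PCG64(self.seed))
        perm = rng.permutation(self.n_samples)
        status = np.zeros(self.n_samples, dtype=np.int8)
        status[perm[:self.n_cases]] = 1
        return PhenotypeTable(pd.Series(status, index=np.array(self.sample_ids,
                                                               dtype=object)))

    def genetic_map(self) -> GeneticMap:
        return linear_map(self.chrom_lengths_cm)

    def expected_rate(self) -> float:
        """Stationary pair-sharing probability at a focal position."""
        lam = self.segment_rate_per_morgan
        mean_len_m = (self.mean_length_cm + self.cutoff_cm) / 100.0
        return -math.expm1(-lam * mean_len_m)


def _decode_pairs(k: np.ndarray, n_haps: int):
    """Map linear upper-triangle indices to (i, j) haplotype index pairs, i < j."""
    kk = k.astype(np.float64)
    b = 2 * n_haps - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * kk)) / 2.0).astype(np.int64)
    # guard against float rounding at triangle-row boundaries
    for _ in range(3):
        t = i * (2 * n_haps - 1 - i) // 2
        too_high = t > k
        too_low = (i + 1) * (2 * n_haps - 2 - i) // 2 <= k
        if not (too_high.any() or too_low.any()):
            break
        i = i - too_high.astype(np.int64) + too_low.astype(np.int64)
    t = i * (2 * n_haps - 1 - i) // 2
    j = k - t + i + 1
    return i, j


def _random_distinct_pairs(rng, size: int, n_haps: int):
    """Uniform haplotype pairs between distinct individuals (rejection on self-pairs)."""
    total = n_haps * (n_haps - 1) // 2
    i = np.empty(size, dtype=np.int64)
    j = np.empty(size, dtype=np.int64)
    need = np.arange(size)
    while len(need):
        k = rng.integers(0, total, size=len(need))
        ii, jj = _decode_pairs(k, n_haps)
        i[need], j[need] = ii, jj
        need = need[ii // 2 == jj // 2]
    return i, j


def _segments_frame(spec: SyntheticSpec, hap_i, hap_j, chrom_idx, start_cm, length_cm):
    """Assemble a hap-ibd-style frame; clip to chromosome bounds; drop empty."""
    lengths = np.asarray([spec.chrom_lengths_cm[c] for c in chrom_idx])
    end_cm = start_cm + length_cm
    start_cm = np.clip(start_cm, 0.0, None)
    end_cm = np.minimum(end_cm, lengths)
    start_bp = np.rint(start_cm * 1e6).astype(np.int64)
    end_bp = np.rint(end_cm * 1e6).astype(np.int64)
    keep = end_bp > start_bp
    ids = np.array(spec.sample_ids, dtype=object)
    frame = pd.DataFrame({
        "ID1": ids[hap_i[keep] // 2],
        "HAP1": (hap_i[keep] % 2 + 1).astype(np.int64),
        "ID2": ids[hap_j[keep] // 2],
        "HAP2": (hap_j[keep] % 2 + 1).astype(np.int64),
        "CHROM": np.array([str(c + 1) for c in chrom_idx[keep]], dtype=object),
        "START": start_bp[keep],
        "END": end_bp[keep],
        "LEN_CM": (end_cm - start_cm)[keep],
    })
    return frame


def generate_null(spec: SyntheticSpec) -> SegmentTable:
    """Null segment table: exchangeable sharing, no phenotype effect.

    Segment starts form a Poisson process at ``lambda`` per Morgan per
    haplotype pair, drawn on windows extended ``cutoff + 20 * mean_length``
    cM to the left of each chromosome so coverage is stationary everywhere
    on the chromosome.  Deterministic in ``spec.seed``.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    n_haps = 2 * spec.n_samples
    n_pairs = n_haps * (n_haps - 1) // 2 - spec.n_samples
    lam = spec.segment_rate_per_morgan
    if lam == 0 or n_pairs <= 0:
        return SegmentTable(_empty_segment_frame(), min_cm=0.0)
    margin = spec.cutoff_cm + 20.0 * spec.mean_length_cm
    windows = np.array([margin + l for l in spec.chrom_lengths_cm])  # cM
    mean_total = n_pairs * lam * windows.sum() / 100.0
    n_segs = int(rng.poisson(mean_total))
    if n_segs == 0:
        return SegmentTable(_empty_segment_frame(), min_cm=0.0)
    chrom_idx = rng.choice(len(windows), size=n_segs, p=windows / windows.sum())
    start_cm = rng.random(n_segs) * windows[chrom_idx] - margin
    length_cm = spec.cutoff_cm + rng.exponential(spec.mean_length_cm, size=n_segs)
    hap_i, hap_j = _random_distinct_pairs(rng, n_segs, n_haps)
    frame = _segments_frame(spec, hap_i, hap_j, chrom_idx, start_cm, length_cm)
    return SegmentTable(frame.reset_index(drop=True), min_cm=0.0)


def _locus_segments(spec, rng, hap_i, hap_j, chrom_idx, pos_cm):
    """One segment per pair, positioned so the locus lies inside it."""
    length_cm = spec.cutoff_cm + rng.exponential(spec.mean_length_cm, size=len(hap_i))
    start_cm = pos_cm - rng.random(len(hap_i)) * length_cm
    return _segments_frame(spec, hap_i, hap_j,
                           np.full(len(hap_i), chrom_idx, dtype=np.int64),
                           start_cm, length_cm)


def _resolve_locus(spec: SyntheticSpec, chrom, pos_cm: float) -> int:
    chrom_idx = int(str(chrom)) - 1
    if not (0 <= chrom_idx < len(spec.chrom_lengths_cm)):
        raise SyntheticError(f"locus chromosome {chrom!r} outside the genome")
    if not (0 <= pos_cm < spec.chrom_lengths_cm[chrom_idx]):
        raise SyntheticError(f"locus position {pos_cm} cM outside chromosome {chrom}")
    return chrom_idx


def inject_risk_locus(table: SegmentTable, spec: SyntheticSpec, locus,
                      seed=None) -> SegmentTable:
    """Add case-enriched sharing at a locus: a fraction ``q`` of case-case
    haplotype pairs gains one segment overlapping it.  Control pairs are
    untouched, so only the case rate moves."""
    chrom, pos_cm, q = locus
    chrom_idx = _resolve_locus(spec, chrom, pos_cm)
    if q == 0:
        return table
    rng = np.random.Generator(np.random.PCG64(spec.seed + 1 if seed is None else seed))
    pheno = spec.phenotypes()
    case_pos = np.flatnonzero(pheno.status.to_numpy() == 1)
    case_haps = np.sort(np.concatenate([2 * case_pos, 2 * case_pos + 1]))
    nh = len(case_haps)
    total = nh * (nh - 1) // 2 - len(case_pos)
    n_extra = int(rng.binomial(total, q))
    if n_extra == 0:
        return table
    li, lj = _random_distinct_pairs(rng, n_extra, nh)
    frame = _locus_segments(spec, rng, case_haps[li], case_haps[lj],
                            chrom_idx, pos_cm)
    data = pd.concat([table.data, frame], ignore_index=True)
    return replace(table, data=data)


def inject_carrier_confounder(table: SegmentTable, spec: SyntheticSpec, locus,
                              f: float, seed=None) -> SegmentTable:
    """Add phenotype-blind excess sharing at a locus.

    ``floor(f * 2n)`` carrier haplotypes are drawn uniformly across *all*
    samples; every carrier-carrier pair (between distinct individuals)
    gains a segment overlapping the locus.  Because carriers ignore
    phenotype, case and control rates inflate together — the signature of a
    sweep-like confounder.
    """
    chrom, pos_cm = locus
    chrom_idx = _resolve_locus(spec, chrom, pos_cm)
    if not 0 < f < 1:
        raise SyntheticError("carrier frequency f must be in (0, 1)")
    n_haps = 2 * spec.n_samples
    n_carriers = int(math.floor(f * n_haps))
    if n_carriers < 2:
        raise SyntheticError(f"f * 2n = {f * n_haps:.2f} yields fewer than 2 carriers")
    rng = np.random.Generator(np.random.PCG64(spec.seed + 2 if seed is None else seed))
    carriers = np.sort(rng.choice(n_haps, size=n_carriers, replace=False))
    ii, jj = np.triu_indices(n_carriers, k=1)
    hi, hj = carriers[ii], carriers[jj]
    between = hi // 2 != hj // 2
    frame = _locus_segments(spec, rng, hi[between], hj[between], chrom_idx, pos_cm)
    data = pd.concat([table.data, frame], ignore_index=True)
    return replace(table, data=data)


def generate_dataset(spec: SyntheticSpec):
    """Null table plus any risk/confounder loci the spec lists.

    Returns ``(segments, phenotypes, genetic_map)``.
    """
    table = generate_null(spec)
    for idx, locus in enumerate(spec.risk_loci):
        table = inject_risk_locus(table, spec, locus, seed=spec.seed + 101 + idx)
    for idx, (chrom, pos_cm, f) in enumerate(spec.confounder_loci):
        table = inject_carrier_confounder(table, spec, (chrom, pos_cm), f,
                                          seed=spec.seed + 201 + idx)
    return table, spec.phenotypes(), spec.genetic_map()
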
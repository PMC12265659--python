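"""Readers and writers for IBD scan inputs and outputs.

Input formats
-------------
* IBD segments: the tab-separated dialect emitted by hap-ibd / ibd-ends —
  eight columns ``ID1  HAP1  ID2  HAP2  CHROM  START  END  LEN_CM`` with
  haplotype indices in {1, 2}, physical coordinates in base pairs and segment
  length in centiMorgans.  Plain text or gzip (detected by magic bytes).
* Genetic maps: PLINK MAP, whitespace separated ``CHROM  SNP_ID  CM  BP``.
* Phenotypes: two whitespace-separated columns ``ID  STATUS`` with status
  0 (control) or 1 (case).

Segment base-pair intervals are treated as half-open ``[start, end)``: a
focal position ``p`` overlaps a segment iff ``start <= p < end``.  Segments
between the two haplotypes of one individual (homozygosity by descent) are
dropped on read, since the scan statistic concerns between-individual
sharing and the pair denominator excludes self pairs.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SEGMENT_COLUMNS = ("ID1", "HAP1", "ID2", "HAP2", "CHROM", "START", "END", "LEN_CM")


class ParseError(ValueError):
    """Malformed input record (carries a 1-based line number when known)."""


class ValidationError(ValueError):
    """Input parsed but violates a format invariant."""


def _open_text(path):
    """Open plain or gzip text, sniffing gzip by magic bytes, not extension."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# IBD segment tables
# ---------------------------------------------------------------------------

@dataclass
class SegmentTable:
    """Detected IBD segments between haplotypes of distinct individuals.

    ``data`` holds one row per segment with the hap-ibd column layout
    (:data:`SEGMENT_COLUMNS`).  ``min_cm`` is the detection cutoff that has
    been applied; ``n_dropped_self`` / ``n_dropped_short`` count the records
    removed by the self-pair and length filters.
    """

    data: pd.DataFrame
    min_cm: float = 0.0
    n_dropped_self: int = 0
    n_dropped_short: int = 0

    def __len__(self) -> int:
        return len(self.data)

    def filtered(self, min_cm: float) -> "SegmentTable":
        """Return a table with segments shorter than ``min_cm`` removed.

        Idempotent: filtering at a cutoff the table already satisfies is a
        no-op (beyond bookkeeping).
        """
        keep = self.data["LEN_CM"].to_numpy() >= min_cm
        return SegmentTable(
            data=self.data.loc[keep].reset_index(drop=True),
            min_cm=max(min_cm, self.min_cm),
            n_dropped_self=self.n_dropped_self,
            n_dropped_short=self.n_dropped_short + int((~keep).sum()),
        )

    def subset_samples(self, ids) -> "SegmentTable":
        """Segments whose two individuals both belong to ``ids``."""
        ids = set(ids)
        keep = self.data["ID1"].isin(ids) & self.data["ID2"].isin(ids)
        return replace(self, data=self.data.loc[keep].reset_index(drop=True))

    @property
    def sample_ids(self):
        return pd.unique(
            pd.concat([self.data["ID1"], self.data["ID2"]], ignore_index=True)
        )


def _empty_segment_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ID1": pd.Series(dtype=str),
            "HAP1": pd.Series(dtype=np.int64),
            "ID2": pd.Series(dtype=str),
            "HAP2": pd.Series(dtype=np.int64),
            "CHROM": pd.Series(dtype=str),
            "START": pd.Series(dtype=np.int64),
            "END": pd.Series(dtype=np.int64),
            "LEN_CM": pd.Series(dtype=float),
        }
    )


def read_ibd_segments(path, min_cm: float = 0.0) -> SegmentTable:
    """Read a hap-ibd / ibd-ends segment file.

    Records shorter than ``min_cm`` and within-individual records
    (``ID1 == ID2``) are dropped; the drop counts are retained on the
    returned table.  Row order is preserved.
    """
    with _open_text(path) as fh:
        text = fh.read()
    if text.strip() == "":
        return SegmentTable(_empty_segment_frame(), min_cm=min_cm)
    try:
        df = pd.read_csv(
            io.StringIO(text), sep="\t", header=None, dtype=str,
            comment=None, skip_blank_lines=False,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed segment file: {exc}") from exc
    if df.shape[1] != 8:
        # locate the first offending line for the error message
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line and len(line.split("\t")) != 8:
                raise ParseError(
                    f"{path}: line {lineno}: expected 8 tab-separated columns, "
                    f"found {len(line.split(chr(9)))}"
                )
        raise ParseError(f"{path}: expected 8 tab-separated columns, found {df.shape[1]}")
    bad = df.isna().any(axis=1)
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {lineno}: expected 8 tab-separated columns")
    df.columns = list(SEGMENT_COLUMNS)
    out = pd.DataFrame({"ID1": df["ID1"].astype(str), "ID2": df["ID2"].astype(str),
                        "CHROM": df["CHROM"].astype(str)})
    for col in ("HAP1", "HAP2", "START", "END", "LEN_CM"):
        kind = float if col == "LEN_CM" else np.int64
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            lineno = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            raise ParseError(
                f"{path}: line {lineno}: non-numeric value {df[col].iloc[lineno - 1]!r} "
                f"in column {col}"
            )
        out[col] = vals.to_numpy().astype(kind)
    out = out[list(SEGMENT_COLUMNS)]
    if not set(np.unique(out["HAP1"])) <= {1, 2} or not set(np.unique(out["HAP2"])) <= {1, 2}:
        raise ValidationError(f"{path}: haplotype indices must be 1 or 2")
    if (out["START"].to_numpy() >= out["END"].to_numpy()).any():
        lineno = int(np.flatnonzero(out["START"].to_numpy() >= out["END"].to_numpy())[0]) + 1
        raise ValidationError(f"{path}: line {lineno}: START must be < END")
    self_pair = (out["ID1"] == out["ID2"]).to_numpy()
    short = out["LEN_CM"].to_numpy() < min_cm
    keep = ~self_pair & ~short
    return SegmentTable(
        data=out.loc[keep].reset_index(drop=True),
        min_cm=min_cm,
        n_dropped_self=int(self_pair.sum()),
        n_dropped_short=int((short & ~self_pair).sum()),
    )


def write_ibd_segments(table: SegmentTable, path) -> None:
    table.data.to_csv(path, sep="\t", header=False, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM interpolation per chromosome.

    ``anchors`` maps chromosome name to a pair of arrays ``(bp, cm)`` sorted
    by bp, with bp strictly increasing and cM non-decreasing.  Queries
    outside the anchor span are clamped to the terminal anchor value
    (constant extrapolation).
    """

    anchors: dict = field(default_factory=dict)

    @property
    def chromosomes(self):
        return list(self.anchors)

    def _get(self, chrom):
        try:
            return self.anchors[str(chrom)]
        except KeyError:
            raise LookupError(f"chromosome {chrom!r} not in genetic map") from None

    def bp_to_cm(self, chrom, bp):
        bps, cms = self._get(chrom)
        return np.interp(bp, bps, cms)

    def cm_to_bp(self, chrom, cm):
        bps, cms = self._get(chrom)
        return np.interp(cm, cms, bps)

    def span_cm(self, chrom):
        """(first, last) cM anchor of a chromosome."""
        _, cms = self._get(chrom)
        return float(cms[0]), float(cms[-1])


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom.lstrip("chr")), chrom)
    except ValueError:
        return (1, 0, chrom)


def read_genetic_map(path) -> GeneticMap:
    """Read a PLINK MAP file (CHROM, SNP_ID, CM, BP)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] != 4:
        raise ParseError(f"{path}: expected 4 columns (CHROM ID CM BP), found {df.shape[1]}")
    df.columns = ["CHROM", "ID", "CM", "BP"]
    cm = pd.to_numeric(df["CM"], errors="coerce")
    bp = pd.to_numeric(df["BP"], errors="coerce")
    if cm.isna().any() or bp.isna().any():
        lineno = int(np.flatnonzero((cm.isna() | bp.isna()).to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {lineno}: non-numeric map coordinate")
    anchors = {}
    for chrom in sorted(df["CHROM"].astype(str).unique(), key=_chrom_sort_key):
        sel = (df["CHROM"].astype(str) == chrom).to_numpy()
        bps = bp.to_numpy()[sel].astype(np.int64)
        cms = cm.to_numpy()[sel].astype(float)
        order = np.argsort(bps, kind="stable")
        bps, cms = bps[order], cms[order]
        if len(bps) < 2:
            raise ValidationError(f"{path}: chromosome {chrom}: needs >= 2 map anchors")
        if (np.diff(bps) <= 0).any():
            raise ValidationError(f"{path}: chromosome {chrom}: duplicate bp anchor")
        if (np.diff(cms) < 0).any():
            raise ValidationError(
                f"{path}: chromosome {chrom}: cM must be non-decreasing in bp"
            )
        anchors[chrom] = (bps, cms)
    return GeneticMap(anchors)


def linear_map(chrom_lengths_cm, cm_per_mb: float = 1.0) -> GeneticMap:
    """A constant-rate map (default 1 cM/Mb) for simulated genomes."""
    anchors = {}
    for i, length in enumerate(chrom_lengths_cm, start=1):
        bp_end = int(round(length * 1e6 / cm_per_mb))
        anchors[str(i)] = (np.array([0, bp_end], dtype=np.int64),
                           np.array([0.0, float(length)]))
    return GeneticMap(anchors)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Mapping of sample id to binary status (0 control, 1 case)."""

    status: pd.Series  # index: sample id (str); values: int8 in {0, 1}

    @property
    def cases(self):
        return list(self.status.index[self.status == 1])

    @property
    def controls(self):
        return list(self.status.index[self.status == 0])

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def __len__(self) -> int:
        return len(self.status)


def read_phenotypes(path) -> PhenotypeTable:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns (ID STATUS), found {df.shape[1]}")
    ids = df[0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicated sample id {dup!r}")
    status = pd.to_numeric(df[1], errors="coerce")
    if status.isna().any() or not set(np.unique(status)) <= {0, 1}:
        bad = df[1][~status.isin([0, 1])].iloc[0]
        raise ValidationError(f"{path}: status must be 0 or 1, found {bad!r}")
    return PhenotypeTable(pd.Series(status.to_numpy().astype(np.int8), index=ids.to_numpy()))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.status.to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# Scan outputs
# ---------------------------------------------------------------------------

SCAN_COLUMNS_TWO = ("CHROM", "BP", "CM", "RATE_CASE", "RATE_CONTROL",
                    "Z_CASE", "Z_CONTROL", "Z_DIFF", "PVALUE", "EXCLUDED")
SCAN_COLUMNS_ONE = ("CHROM", "BP", "CM", "RATE", "Z", "PVALUE", "EXCLUDED")

REGION_COLUMNS = ("CHROM", "MAX_Z", "POS_BP", "POS_CM", "START_BP", "END_BP",
                  "START_CM", "END_CM", "SIZE_CM", "PVALUE", "N_POSITIONS")


def scan_frame(track) -> pd.DataFrame:
    """Tabulate a :class:`~ibddiff.rate_scan.ScanTrack` in output column order."""
    from scipy.stats import norm

    grid = track.grid
    base = {
        "CHROM": np.asarray(grid.chrom_labels),
        "BP": grid.bp,
        "CM": grid.cm,
    }
    if track.two_sample:
        base.update({
            "RATE_CASE": track.rate_case.values,
            "RATE_CONTROL": track.rate_control.values,
            "Z_CASE": track.z_case,
            "Z_CONTROL": track.z_control,
            "Z_DIFF": track.z,
        })
    else:
        base.update({"RATE": track.rate_case.values, "Z": track.z})
    base["PVALUE"] = norm.sf(track.z)
    base["EXCLUDED"] = track.excluded.astype(np.int8)
    cols = SCAN_COLUMNS_TWO if track.two_sample else SCAN_COLUMNS_ONE
    return pd.DataFrame(base)[list(cols)]


def write_scan_table(track, path) -> None:
    """Write the per-position scan table as TSV (12 significant digits)."""
    scan_frame(track).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scan_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    return df


def regions_frame(regions) -> pd.DataFrame:
    rows = [
        {
            "CHROM": r.chrom, "MAX_Z": r.max_z, "POS_BP": r.pos_bp,
            "POS_CM": r.pos_cm, "START_BP": r.start_bp, "END_BP": r.end_bp,
            "START_CM": r.start_cm, "END_CM": r.end_cm, "SIZE_CM": r.size_cm,
            "PVALUE": r.p_value, "N_POSITIONS": r.n_positions,
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=list(REGION_COLUMNS))


def write_regions(regions, tsv_path, bed_path=None) -> None:
    """Write called regions as TSV and (optionally) BED.

    BED lines are 0-based half-open; internal bp coordinates are already
    0-based point positions, so a region spanning grid points
    ``start_bp .. end_bp`` becomes ``chrom  start_bp  end_bp + 1``.
    """
    regions_frame(regions).to_csv(tsv_path, sep="\t", index=False, float_format="%.12g")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp + 1}\n")
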
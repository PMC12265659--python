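import numpy as np
import pytest

import ibddiff as ib


def write_lines(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture
def seg_file(tmp_path):
    """Write hap-ibd-style rows to a temp file and return the path."""
    def _write(rows, name="segments.tsv"):
        return write_lines(tmp_path / name, rows)
    return _write


@pytest.fixture
def two_chrom_map():
    """Two 100 cM chromosomes on a linear 1 cM/Mb map."""
    return ib.linear_map([100.0, 100.0])


@pytest.fixture
def small_dataset():
    """A small null synthetic cohort: 40+40 samples on 2 x 100 cM."""
    spec = ib.SyntheticSpec(n_cases=40, n_controls=40,
                            chrom_lengths_cm=(100.0, 100.0), seed=5)
    segments, pheno, gmap = ib.generate_dataset(spec)
    return spec, segments, pheno, gmap


def brute_force_rate(segments, grid, group_ids):
    """Reference pair-by-position double loop for IBD rates."""
    ids = set(map(str, group_ids))
    n = len(ids)
    n_pairs = 2 * n * (n - 1)
    labels = grid.chrom_labels
    values = np.zeros(grid.M)
    df = segments.data
    for m in range(grid.M):
        chrom, p = labels[m], grid.bp[m]
        pairs = set()
        for row in df.itertuples(index=False):
            if (str(row.CHROM) == chrom and row.ID1 in ids and row.ID2 in ids
                    and row.START <= p < row.END):
                a = (row.ID1, row.HAP1)
                b = (row.ID2, row.HAP2)
                pairs.add((min(a, b), max(a, b)))
        values[m] = len(pairs) / n_pairs
    return values
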
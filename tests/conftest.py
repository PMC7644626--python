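import numpy as np
import pandas as pd
import pytest

from radgut.core_io import GenotypePanel, MarkerId, PhenotypeTable


def make_phenotypes(rows):
    """rows: (line_id, dose_gy, n_total, n_smurf[, vial_id])."""
    records = []
    for row in rows:
        line_id, dose, n_total, n_smurf = row[:4]
        vial = row[4] if len(row) > 4 else ""
        records.append(
            {
                "line_id": line_id,
                "dose_gy": dose,
                "vial_id": vial,
                "n_total": n_total,
                "n_smurf": n_smurf,
            }
        )
    return PhenotypeTable(pd.DataFrame.from_records(records))


def make_panel(calls, line_ids=None, chrom="2L"):
    calls = np.asarray(calls, dtype=float)
    n_markers, n_lines = calls.shape
    line_ids = line_ids or [f"L{i + 1}" for i in range(n_lines)]
    markers = [MarkerId(chrom, 1000 * (i + 1), "SNP") for i in range(n_markers)]
    return GenotypePanel(line_ids=tuple(line_ids), markers=tuple(markers), calls=calls)


@pytest.fixture
def six_line_phen():
    """Six lines, paired 0/100 Gy, 20 flies each, varied Smurf counts."""
    rows = []
    counts0 = [1, 2, 0, 3, 1, 2]
    counts1 = [4, 6, 3, 12, 10, 14]
    for i in range(6):
        rows.append((f"L{i + 1}", 0, 20, counts0[i]))
        rows.append((f"L{i + 1}", 100, 20, counts1[i]))
    return make_phenotypes(rows)


@pytest.fixture
def six_line_panel():
    # marker 1: first three lines carry the minor allele; marker 2: alternating
    return make_panel([[1, 1, 1, 0, 0, 0], [0, 1, 0, 1, 0, 1]])
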
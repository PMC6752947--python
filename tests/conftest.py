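import numpy as np
import pandas as pd
import pytest

from muscletrace.panel import GenePanel, default_panel
from muscletrace.qpcr import CtMatrix, Lod, ct_to_expression


def make_ct(values, genes, cells, panel=None, sentinel=999.0):
    """CtMatrix from a plain array; entries >= sentinel or NaN become failed."""
    arr = np.asarray(values, dtype=float)
    fail = ~np.isfinite(arr) | (arr >= sentinel)
    idx = pd.Index(genes, name="gene")
    cols = pd.Index(cells, name="cell_id")
    return CtMatrix(
        values=pd.DataFrame(np.where(fail, np.nan, arr), index=idx, columns=cols),
        fail_mask=pd.DataFrame(fail, index=idx, columns=cols),
        panel=panel,
    )


def fixed_lod(value: int) -> Lod:
    """A LOD pinned to an integer (per-gene maxima consistent by construction)."""
    return Lod(value=value, per_gene_max=pd.Series([float(value)]))


@pytest.fixture
def panel() -> GenePanel:
    return default_panel()


@pytest.fixture
def toy_ct(panel) -> CtMatrix:
    """Handcrafted panel matrix, 3 cells (use with LOD 21).

    c1: clean cell (5 controls, 4 interest genes detected) -> retained.
    c2: only 3 controls below LOD -> discarded (controls criterion).
    c3: neurogenic contaminant, Pax3 detected -> discarded (exclusion).
    """
    genes = list(panel.genes)
    cells = ["c1", "c2", "c3"]
    base = {
        "Tbp": [14, 25, 14], "Actb": [13, 22, 13], "Hprt": [16, 15, 16],
        "Rpl13a": [14, 13, 14], "Rps29": [15, 14, 15],
        "Isl1": [16, 17, 16], "Met": [15, 18, 15], "Pax7": [17, 16, 17],
        "Myf5": [18, 17, 18], "Myod": [999, 19, 999], "Myog": [999, 999, 999],
        "Mrf4": [999, 999, 999],
        "Pax3": [999, 999, 17], "Lhx3": [999, 999, 999],
    }
    values = [base[g] for g in genes]
    return make_ct(values, genes, cells, panel=panel)


@pytest.fixture
def toy_expression(toy_ct):
    return ct_to_expression(toy_ct, fixed_lod(21))
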
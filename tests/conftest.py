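import numpy as np
import pandas as pd
import pytest

import platinsig as ps


@pytest.fixture(scope="session")
def panel():
    """Default planted-signal panel: 40 lines, 30 genes, 3 informative."""
    return ps.generate_panel(ps.PanelSpec(seed=1))


@pytest.fixture(scope="session")
def zpanel(panel):
    return ps.zscore_normalize(panel.expression)


@pytest.fixture(scope="session")
def median_labels(panel):
    return ps.label_by_threshold(panel.dose_response, panel.dose_response.median())


@pytest.fixture(scope="session")
def small_panel():
    """8-gene panel (3 informative, 5 noise) on 20 lines, for BFS-vs-oracle."""
    return ps.generate_panel(ps.PanelSpec(n_lines=20, n_genes=8, n_informative=3, seed=7))


@pytest.fixture(scope="session")
def small_xy(small_panel):
    x = ps.zscore_normalize(small_panel.expression)
    y = ps.label_by_threshold(small_panel.dose_response, small_panel.dose_response.median())
    return x, y


def make_xy(X, y01, gene_prefix="g", threshold=0.0):
    """Wrap a samples x genes array and 0/1 labels into package containers."""
    X = np.asarray(X, float)
    n, p = X.shape
    genes = [f"{gene_prefix}{j}" for j in range(p)]
    ids = [f"s{i}" for i in range(n)]
    x = ps.ExpressionMatrix(genes, ids, X.T, "zscore")
    yv = ps.LabelVector(ids, np.asarray(y01, int), threshold)
    return x, yv


@pytest.fixture
def xy_factory():
    return make_xy


@pytest.fixture(scope="session")
def mfa_blocks(panel, zpanel):
    d = panel.dose_response
    return [
        ("GE", zpanel.to_frame()),
        ("GI50", pd.DataFrame([d.gi50], index=["GI50"], columns=d.sample_ids)),
    ]
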
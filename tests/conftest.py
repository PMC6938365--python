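import numpy as np
import pandas as pd
import pytest

import factorscan as fs


@pytest.fixture(scope="session")
def synth():
    """One standard planted-truth instance shared across tests.

    Compendium of 20 factors over 2,000 genes with the planted factor's
    target-gene signals scaled 10x, plus the matching rodent-style expression
    with those targets repressed by 2 log2 units.
    """
    truth = fs.default_truth(1)
    peaks, annotation, _ = fs.generate_compendium(2000, 20, truth)
    matrix = fs.compendium_matrix(peaks, annotation)
    expr, meta = fs.generate_expression(truth, 2000)
    collapsed, cmeta = fs.collapse_to_model_medians(expr, meta)
    degs = fs.call_degs(collapsed, cmeta, 1)
    background = [g for g in expr.index if g in matrix.index]
    down = [g for g in degs.index[degs["direction"] == "down"] if g in matrix.index]
    return {
        "truth": truth,
        "matrix": matrix,
        "expr": expr,
        "meta": meta,
        "collapsed": collapsed,
        "cmeta": cmeta,
        "degs": degs,
        "background": background,
        "down": down,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_collapsed(n_genes, n_ctrl=5, n_case=5, day=1, seed=0, sd=0.25):
    """Directly build a model-median matrix + metadata for one timepoint."""
    r = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    cols = {}
    rows = []
    for cond, n in (("control", n_ctrl), ("case", n_case)):
        for m in range(n):
            name = f"m{m}|{cond}|{day}"
            cols[name] = r.normal(8, sd, n_genes)
            rows.append({"column": name, "model": f"m{m}", "condition": cond, "timepoint": day})
    collapsed = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    cmeta = pd.DataFrame(rows).set_index("column")
    return collapsed, cmeta
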
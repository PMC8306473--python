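import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import glialink as gl
from glialink.datatypes import ExpressionMatrix

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_counts(values, cell_type="OPC", genotype="WT", condition="NS"):
    """Wrap a plain array/DataFrame in a CountMatrix with dummy metadata."""
    if not isinstance(values, pd.DataFrame):
        values = np.asarray(values)
        values = pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        )
    meta = pd.DataFrame(
        {
            "cell_type": cell_type,
            "genotype": genotype,
            "condition": condition,
        },
        index=values.columns,
    )
    return gl.CountMatrix(values, meta)


def study_expression(counts, ann, pseudocount=1.0):
    """log-FPKM matrices split into the OPC and microglia blocks."""
    logf = gl.log_transform(gl.compute_fpkm(counts, ann), pseudocount=pseudocount)
    return gl.split_cell_types(logf)


def opc_group(counts, genotype, condition):
    meta = counts.metadata
    sel = meta[
        (meta.cell_type == "OPC")
        & (meta.genotype == genotype)
        & (meta.condition == condition)
    ]
    return sel.index.tolist()


@pytest.fixture(scope="session")
def small_config():
    return gl.SimulationConfig(
        n_genes=300,
        n_de_up=30,
        n_de_down=20,
        n_lr_pairs=40,
        n_active_pairs=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return gl.simulate_study(small_config)


def de_table():
    """Ten hand-written DE rows; exactly g1, g2, g3 satisfy the up-criteria
    (g1 sits on all three boundaries) and g7, g9 the down-criteria."""
    rows = [
        # gene, log2FC, log2CPM, p, p_adj
        ("g1", 0.585, 1.00, 0.010, 0.050),   # up: all boundaries inclusive
        ("g2", 2.000, 5.00, 0.001, 0.010),   # up: clear
        ("g3", 1.000, 3.00, 0.0001, 0.001),  # up: clear
        ("g4", 2.000, 5.00, 0.020, 0.051),   # fails alpha
        ("g5", 2.000, 0.99, 0.001, 0.010),   # fails abundance
        ("g6", 0.500, 5.00, 0.001, 0.010),   # fails effect size
        ("g7", -0.585, 1.00, 0.010, 0.050),  # down: boundaries inclusive
        ("g8", -0.300, 2.00, 0.001, 0.010),  # fails effect size
        ("g9", -1.000, 4.00, 0.002, 0.020),  # down: clear
        ("g10", 0.000, 0.50, 0.900, 0.950),  # null
    ]
    return pd.DataFrame(
        rows, columns=["gene", "log2FC", "log2CPM", "p", "p_adj"]
    ).assign(comparison="WT-St vs WT-NS")


@pytest.fixture()
def de_fixture():
    return de_table()


def bh_brute_force(p):
    """Independent step-up oracle: adj_i = min over ranks >= rank(i) of
    p_(r) * m / r, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def make_context(lig_values, rec_values, label="ctx"):
    """Build an InteractionContext from dicts gene -> list of sample values."""
    lig = pd.DataFrame.from_dict(lig_values, orient="index")
    lig.columns = [f"opc{j}" for j in range(lig.shape[1])]
    rec = pd.DataFrame.from_dict(rec_values, orient="index")
    rec.columns = [f"mg{j}" for j in range(rec.shape[1])]
    return gl.InteractionContext(lig, rec, label)
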
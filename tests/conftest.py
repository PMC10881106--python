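import numpy as np
import pandas as pd
import pytest

import evoindex as ev

# ---------------------------------------------------------------------------
# independent naive oracles (plain loops; no shared code with the package)
# ---------------------------------------------------------------------------


def naive_weighted_index(values, weights):
    """Brute-force weighted mean with pairwise exclusion."""
    num = den = 0.0
    n = 0
    for v, w in zip(values, weights):
        if v != v or w != w or w == 0.0:
            continue
        num += v * w
        den += w
        n += 1
    if n == 0 or den <= 0:
        raise ZeroDivisionError
    return num / den, n


def naive_index_table(gene_evo: ev.GeneEvoTable, grouped: ev.ExpressionMatrix, kind):
    """Double-loop ERI/TAI reference: dict (group, column) -> (value, n)."""
    cols = list(gene_evo.lineages) if kind == "ERI" else ["age"]
    out = {}
    shared = [g for g in gene_evo.data.index if g in set(grouped.values.index)]
    for col in cols:
        for grp in grouped.values.columns:
            vals = [gene_evo.data.loc[g, col] for g in shared]
            wts = [grouped.values.loc[g, grp] for g in shared]
            out[(grp, col)] = naive_weighted_index(vals, wts)
    return out


def welch_t_by_hand(a, b):
    """Textbook Welch statistic, df and two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def student_t_by_hand(a, b):
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * tdist.sf(abs(t), df)
    return t, float(df), p


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

CAL_REGIONS = tuple((f"C{i}", "cortical") for i in range(8)) + tuple(
    (f"N{i}", "non_cortical") for i in range(8)
)


@pytest.fixture(scope="session")
def primate_tree():
    return ev.default_tree()


@pytest.fixture
def small_config():
    """Small study used for fast Monte-Carlo checks."""
    return ev.SimConfig(
        n_genes=250, regions=CAL_REGIONS, n_samples_per_region=2, seed=42
    )


@pytest.fixture
def toy_gene_evo():
    lineages = ("L1", "L2")
    df = pd.DataFrame(
        {
            "L1": [0.1, 0.5, np.nan],
            "L2": [0.2, 0.4, 0.9],
            "age": [10.0, 20.0, 30.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return ev.GeneEvoTable(df, lineages=lineages)


@pytest.fixture
def toy_expression():
    df = pd.DataFrame(
        {"grp1": [1.0, 3.0, 2.0], "grp2": [4.0, 0.0, 1.0]},
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return ev.ExpressionMatrix(df, units="normalized")


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "region": ["AMY", "AMY", "DLPFC", "DLPFC"],
            "region_class": ["non_cortical", "non_cortical", "cortical", "cortical"],
            "window": ["w1", "w2", "w1", "w2"],
            "uniquely_mapped_reads": [20_000_000] * 4,
            "total_reads": [22_000_000] * 4,
        }
    )
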
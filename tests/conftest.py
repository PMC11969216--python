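import numpy as np
import pytest

import mutclock as mc

#: three-tip example used throughout: ((A:1,B:1):1,C:2);
THREE_TIP_NEWICK = "((A:1,B:1):1,C:2);"

#: 6-tip ultrametric tree and trait values for the frozen regression oracle
SIX_TIP_NEWICK = "((A:1,(B:0.5,C:0.5):0.5):1,((D:0.8,E:0.8):0.7,F:1.5):0.5);"
SIX_TIP_TRAITS = {
    # species: (x = log10 GT, y = log10 mu_y) — synthetic values
    "A": (0.2, -8.1),
    "B": (-0.5, -7.6),
    "C": (1.3, -9.2),
    "D": (0.8, -8.9),
    "E": (-1.1, -7.0),
    "F": (0.4, -8.3),
}


@pytest.fixture
def three_tip_tree():
    return mc.parse_newick(THREE_TIP_NEWICK)


@pytest.fixture
def six_tip_fit_inputs():
    tree = mc.parse_newick(SIX_TIP_NEWICK)
    C = mc.brownian_vcv(tree)
    x = np.array([SIX_TIP_TRAITS[s][0] for s in C.species_order])
    y = np.array([SIX_TIP_TRAITS[s][1] for s in C.species_order])
    return y, x, C


@pytest.fixture
def small_dataset():
    """Seeded synthetic dataset (40 species, 4 groups) with derived rates."""
    cfg = mc.GeneratorConfig(n_species=40, n_groups=4, seed=7)
    ds = mc.generate_dataset(cfg)
    table = ds.rates_table()
    table, tree, _ = mc.match_to_tree(table, ds.tree)
    return ds, table, tree


def dataset_xy(table):
    return table.data["log10_mu_y"].to_numpy(), table.data["log10_gt"].to_numpy()


def ols_normal_equations(y, x):
    """Brute-force OLS oracle: explicit normal equations, explicit inverse."""
    X = np.column_stack([np.ones(len(x)), x])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - 2)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    return beta, se


def brute_force_vcv(tree):
    """Independent covariance oracle: walk root paths for every tip pair."""
    leaves = list(tree.leaf_node_iter())

    def root_path(leaf):
        path, node = [], leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        return list(reversed(path))

    paths = {lf: root_path(lf) for lf in leaves}
    n = len(leaves)
    C = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is not nb:
                    break
                shared += na.edge.length or 0.0
            C[i, j] = shared
    return C, [lf.taxon.label for lf in leaves]
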
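import numpy as np
import pytest
from scipy import sparse

import fluxinfer as fi

#: fast classifier settings shared across tests (short penalty path)
FAST = dict(n_lambda=20, lambda_min_ratio=1e-2, seed=1)


def make_model(metabolites, reactions):
    """Build a MetabolicModel from a compact reaction description.

    ``reactions`` maps id -> (stoich dict, lb, ub, subsystem, objective).
    """
    met_index = {m: i for i, m in enumerate(metabolites)}
    rids = list(reactions)
    S = sparse.lil_matrix((len(metabolites), len(rids)))
    lb, ub, obj, subsys = [], [], [], []
    for j, rid in enumerate(rids):
        stoich, lo, hi, sub, o = reactions[rid]
        for mid, coeff in stoich.items():
            S[met_index[mid], j] = coeff
        lb.append(lo)
        ub.append(hi)
        subsys.append(sub)
        obj.append(o)
    return fi.MetabolicModel(
        metabolite_ids=list(metabolites),
        reaction_ids=rids,
        S=S.tocsc(),
        lower_bounds=np.array(lb),
        upper_bounds=np.array(ub),
        objective_coeffs=np.array(obj),
        subsystem=subsys,
    )


@pytest.fixture(scope="session")
def disjoint_spec():
    return fi.ToyNetworkSpec(n_carbon=3, n_nitrogen=3, overlap=0.0, seed=0)


@pytest.fixture(scope="session")
def disjoint_toy(disjoint_spec):
    return fi.generate_toy_model(disjoint_spec)


@pytest.fixture(scope="session")
def toy77_spec():
    return fi.ToyNetworkSpec(n_carbon=7, n_nitrogen=7, overlap=0.2, seed=0)


@pytest.fixture(scope="session")
def toy77(toy77_spec):
    return fi.generate_toy_model(toy77_spec)


@pytest.fixture(scope="session")
def ds77(toy77):
    """Reference simulated dataset: 7x7 conditions, 20 replicates, 1 C/N impurity."""
    model, pool = toy77
    conditions = fi.condition_grid(pool.carbon_pool, pool.nitrogen_pool)
    config = fi.SimulationConfig(conditions=conditions, replicates=20, k_C=1, k_N=1, seed=1)
    return fi.run_simulation(model, pool, config)


@pytest.fixture(scope="session")
def split77(ds77):
    return fi.split_train_test(ds77, seed=1)


@pytest.fixture(scope="session")
def sep_classifiers(split77):
    train_ds, _ = split77
    out = []
    for mode in ("separate_C", "separate_N"):
        cfg = fi.ClassifierConfig(mode=mode, **FAST)
        X, y = fi.build_features(train_ds, cfg)
        out.append(fi.train(X, y, cfg))
    return tuple(out)


@pytest.fixture(scope="session")
def joint_classifier(split77):
    train_ds, _ = split77
    cfg = fi.ClassifierConfig(mode="joint", **FAST)
    X, y = fi.build_features(train_ds, cfg)
    return fi.train(X, y, cfg)


@pytest.fixture
def chain_model():
    """EX_A (lb -10) -> transport -> internal chain -> biomass; optimum forced to 10."""
    return make_model(
        ["A_e", "A_c", "B_c"],
        {
            "EX_A_e": ({"A_e": -1}, -10, 1000, "Exchange", 0),
            "TR_A": ({"A_e": -1, "A_c": 1}, 0, 1000, "Transport", 0),
            "R_AB": ({"A_c": -1, "B_c": 1}, 0, 1000, "", 0),
            "BIOMASS": ({"B_c": -1}, 0, 1000, "Biomass", 1),
        },
    )
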
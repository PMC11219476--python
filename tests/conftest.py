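import numpy as np
import pandas as pd
import pytest

import methblocks as mb


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small seeded dataset with planted effects and some missingness."""
    cfg = mb.SimConfig(
        n_samples=60, n_cpgs=400, n_chroms=3, n_causal=8, effect_size=0.7,
        missing_rate=0.03, seed=13,
    )
    dest = tmp_path_factory.mktemp("sim_small")
    store, samples, cpgs, truth = mb.simulate_methylation(cfg, dest)
    mlist = mb.create_methlist(store, samples, cpgs)
    return {"cfg": cfg, "store": store, "samples": samples, "cpgs": cpgs,
            "truth": truth, "mlist": mlist}


@pytest.fixture()
def tiny_csv(tmp_path):
    """A 6-CpG, 3-sample delimited source spanning two chromosomes."""
    rng = np.random.default_rng(42)
    vals = rng.uniform(0.05, 0.95, size=(6, 3))
    df = pd.DataFrame(vals, columns=["A", "B", "C"])
    df.insert(0, "chrom", ["1", "1", "1", "2", "2", "2"])
    df.insert(0, "cpg_id", [f"cg{i+1:06d}" for i in range(6)])
    path = tmp_path / "source.csv"
    df.to_csv(path, index=False, float_format="%.17g")
    return path, df


def make_design(X, exposure_columns=(1,), names=None):
    from methblocks.ewas_outcome import DesignMatrix

    X = np.asarray(X, dtype=float)
    names = names or [f"c{j}" for j in range(X.shape[1])]
    return DesignMatrix(
        X=X, column_names=list(names), exposure_columns=list(exposure_columns),
        sample_ids=[f"s{i}" for i in range(X.shape[0])], dropped_samples=[],
    )
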
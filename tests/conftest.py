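import numpy as np
import pytest

import methyltraj as mt
from methyltraj.preprocess import IntensityPair, qc_pipeline


@pytest.fixture(scope="session")
def study():
    """One small simulated study shared across tests (2,000 probes, 16 samples)."""
    cfg = mt.SimulationConfig(n_probes=2000, seed=1)
    return mt.simulate_study(cfg, n_network_genes=120, scc_size=20, scc_extra_edges=15)


@pytest.fixture(scope="session")
def qc_result(study):
    pair = IntensityPair(
        methylated=study.meth,
        unmethylated=study.unmeth,
        detection_p=study.detp,
        beadcount=study.beadcount,
        probe_type=study.annotation["probe_type"],
    )
    beta, report = qc_pipeline(
        pair,
        annotation=study.annotation,
        min_median=0.25 * study.config.mean_total_intensity,
    )
    return beta, report


@pytest.fixture(scope="session")
def trajectory_result(study, qc_result):
    beta, _ = qc_result
    sel = mt.select_top_mad(beta, fraction=0.05)
    space = mt.pca_reduce(beta.loc[sel.selected_probes], n_components=2)
    traj = mt.infer_trajectory(space, k=4, seed=1)
    traj = mt.orient_pseudotime(traj, study.samples, "iPSC")
    return sel, space, traj


@pytest.fixture(scope="session")
def signature_result(study, qc_result, trajectory_result):
    import pandas as pd

    beta, _ = qc_result
    sel, _, traj = trajectory_result
    t = mt.round_pseudotime(traj.pseudotime.to_numpy())
    results, fitted = mt.fit_gam_matrix(beta.loc[sel.selected_probes], t)
    sig = mt.bonferroni_select(results)
    fitted_df = pd.DataFrame(fitted, index=sel.selected_probes)
    sig = mt.assign_modules(sig, fitted_df, n_modules=9, seed=1)
    return sig, results, fitted_df


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
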
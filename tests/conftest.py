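import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aslcbf import (
    KineticParams,
    PhantomConfig,
    build_phantom,
    simulate_asl,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    return KineticParams()


@pytest.fixture(scope="session")
def default_truth():
    """Default phantom: regional gray-matter perfusion at calibrated values."""
    return build_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def uniform_truth():
    """Phantom with a single gray-matter perfusion (43) everywhere and WM 20."""
    gm = {r: 43.0 for r in ("frontal", "parietal", "prcpcc", "temporal", "occipital", "other")}
    return build_phantom(PhantomConfig(true_gm_cbf_by_region=gm, true_wm_cbf=20.0))


@pytest.fixture(scope="session")
def noisefree_stack(default_truth, default_params):
    return simulate_asl(default_truth, default_params, noise_sd_fraction=0.0)


@pytest.fixture()
def inclusion_fixture():
    """Six subjects covering every boundary case of the follow-up filter."""
    rows = []

    def subject(sid, times):
        for t in times:
            rows.append({"subject_id": sid, "visit_time_years": t, "mmse": 25.0})

    subject("single_visit", [0.0])                   # one score: out
    subject("short_pair", [0.0, 0.5])                # span < 1 y: out
    subject("long_pair", [0.0, 1.2])                 # rule satisfied: in
    subject("exact_year", [0.0, 1.0])                # boundary span == 1 y: in
    subject("many_short", [0.0, 0.4, 0.9])           # 3 scores but span < 1 y: out
    subject("long_followup", [0.0, 1.1, 2.3, 3.0])   # in
    return pd.DataFrame(rows)


def brute_force_pvc(values, pve_gm, pve_wm, mask, stencil, condition_limit=1e8):
    """Loop-over-stencils weighted normal-equations reference for the PVC
    regression: gathers each voxel's neighbourhood explicitly and solves the
    weighted 2x2 system with ``np.linalg.solve`` — independent of the
    separable-convolution production path.  Boundary clipping is realized by
    zero padding (clipped voxels contribute zero to every sum)."""
    weights = stencil.weights
    rads = tuple(len(k) // 2 for k in stencil.axis_kernels)
    pad = [(r, r) for r in rads]
    vp = np.pad(values, pad)
    gp = np.pad(pve_gm, pad)
    wp = np.pad(pve_wm, pad)
    shape = values.shape
    gm = np.zeros(shape)
    wm = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    for idx in np.argwhere(mask):
        sl = tuple(slice(i, i + 2 * r + 1) for i, r in zip(idx, rads))
        g, w, v = gp[sl], wp[sl], vp[sl]
        a = np.array([
            [(weights * g * g).sum(), (weights * g * w).sum()],
            [(weights * g * w).sum(), (weights * w * w).sum()],
        ])
        b = np.array([(weights * g * v).sum(), (weights * w * v).sum()])
        eig = np.linalg.eigvalsh(a)
        if eig[0] <= 0 or eig[1] / eig[0] > condition_limit:
            continue
        sol = np.linalg.solve(a, b)
        gm[tuple(idx)], wm[tuple(idx)] = sol
        valid[tuple(idx)] = True
    return gm, wm, valid
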
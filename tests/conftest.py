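import numpy as np
import pytest

from neocrea import build_reference_grid, fit_parameters, packaged_anchors, run_study


@pytest.fixture(scope="session")
def calibrated():
    """Full 18-start calibration against the packaged anchor tables."""
    result = fit_parameters(packaged_anchors())
    assert result.converged
    return result


@pytest.fixture(scope="session")
def study(calibrated):
    """Replicated study tables from the calibrated parameters."""
    return run_study(build_reference_grid(), calibrated.fitted)


def euler_reference(profile, params, courses, t_end, step=1e-4):
    """Independent brute-force oracle: naive fine-step forward Euler.

    Reimplements the dynamics from scratch (own Hill clearance, own
    ibuprofen subtraction, own integration loop) so it shares no code path
    with the production integrator.  Returns concentrations on the coarse
    0.005-day grid for comparison.
    """
    vd = params.vd_per_kg * profile.birth_weight / 1000.0
    inflow = params.production_rate / (10.0 * vd)
    cl_base = params.cl_bl_raw * params.baseline_covariate_factor
    windows = [c.window for c in courses]
    n = int(round(t_end / step))
    out_every = int(round(0.005 / step))
    c = profile.initial_creatinine
    out = [c]
    for i in range(n):
        tm = (i + 0.5) * step
        cl = cl_base + params.emax * tm**params.hill / (
            params.t50**params.hill + tm**params.hill
        )
        if any(s < tm < e for s, e in windows):
            cl = max(cl - params.ibuprofen_reduction, 1e-6)
        c = c + step * (inflow - cl / vd * c)
        if (i + 1) % out_every == 0:
            out.append(c)
    return np.asarray(out)
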
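import numpy as np
import pytest

from depact.media import Grid, SkullMask, assign_properties
from depact.sensing import MeasurementFilter, make_circular_array
from depact.elastic import ForwardOperator, PMLConfig
from depact.synthetic import make_transcranial_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_skull_setup():
    """64^2 annular-skull scene used for adjoint and operator tests."""
    g = Grid.centered((64, 64), 0.5e-3)
    X, Y = g.coordinate_mesh()
    r = np.sqrt(X ** 2 + Y ** 2)
    mask = SkullMask((r > 6e-3) & (r < 8.5e-3), g)
    medium = assign_properties(mask, (1850.0, 2800.0, 1250.0), (1000.0, 1482.4))
    water = assign_properties(SkullMask(np.zeros(g.shape, bool), g),
                              (1850.0, 2800.0, 1250.0), (1000.0, 1482.4))
    sensors = make_circular_array(10.5e-3, 32)
    return {"grid": g, "mask": mask, "medium": medium, "water": water,
            "sensors": sensors, "dt": 50e-9, "nt": 120}


@pytest.fixture(scope="session")
def transcranial():
    """The standing 2D skull-shell acquisition (shared; expensive)."""
    return make_transcranial_fixture(seed=7)


@pytest.fixture(scope="session")
def transcranial_ubp(transcranial):
    from depact.reconstruct import ubp
    from depact.sensing import water_sos
    fx = transcranial
    return ubp(fx.data, fx.sensors, water_sos(fx.water_temperature_c),
               fx.roi_grid)


@pytest.fixture(scope="session")
def transcranial_fista(transcranial):
    from depact.reconstruct import fista_reconstruct
    fx = transcranial
    return fista_reconstruct(fx.data, fx.medium, fx.sensors, fx.roi,
                             fx.recommended_recon_config(), pml=fx.pml,
                             measurement_filter=fx.measurement_filter)


@pytest.fixture(scope="session")
def mismatch_sliding_cc(transcranial):
    """Sliding correlation of the adjoint image with the ground truth under
    each model perturbation of the sensitivity study."""
    from depact.reconstruct import adjoint_reconstruct
    from depact.synthetic import perturb_model
    from depact.evaluation import sliding_correlation
    fx = transcranial
    shift = 1e-2 / np.sqrt(2.0)
    variants = {
        "correct": None,
        "cs_minus10": ("cs_scale", -0.10),
        "cs_plus10": ("cs_scale", +0.10),
        "cp_minus10": ("cp_scale", -0.10),
        "cp_plus10": ("cp_scale", +0.10),
        "rot_plus10deg": ("rotate", np.deg2rad(10.0)),
        "shift_1cm": ("translate", (shift, -shift)),
        "acoustic_only": ("acoustic_only", None),
    }
    out = {}
    for name, pert in variants.items():
        if pert is None:
            med = fx.medium
        else:
            med, _ = perturb_model(fx.mask, fx.skull, fx.water, pert[0], pert[1])
        img = adjoint_reconstruct(fx.data, med, fx.sensors, roi=fx.roi,
                                  pml=fx.pml,
                                  measurement_filter=fx.measurement_filter)
        out[name] = sliding_correlation(img, fx.p0_roi, max_shift=5)
    return out
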
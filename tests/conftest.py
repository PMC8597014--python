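import numpy as np
import pytest

from acetylkinetics import (
    FitConfig,
    GeneratorConfig,
    NoiseModel,
    PhDriftModel,
    constants_preset,
    generate_dataset,
    fit_rate_constants,
)

TRI_TRUTH = constants_preset("table1")
GGM_TRUTH_2MG = constants_preset("table2-2mg")


@pytest.fixture(scope="session")
def tri_truth():
    return TRI_TRUTH


@pytest.fixture(scope="session")
def ggm_truth_2mg():
    return GGM_TRUTH_2MG


@pytest.fixture(scope="session")
def constant_ph8():
    return PhDriftModel(kind="constant", ph_start=8.0, horizon=700.0)


@pytest.fixture(scope="session")
def tri_joint_noise_free(tri_truth, constant_ph8):
    """Noise-free 1a- and 1b-start time courses, 25 points over 700 h at pH 8."""
    times = np.geomspace(1.0, 700.0, 25)
    return [
        generate_dataset(
            GeneratorConfig(
                constants=tri_truth,
                start=start,
                ph_model=constant_ph8,
                sample_times=times,
                noise=NoiseModel(kind="none"),
            )
        )
        for start in ("from_1a", "from_1b")
    ]


@pytest.fixture(scope="session")
def ggm_noise_free_2mg(ggm_truth_2mg, constant_ph8):
    return generate_dataset(
        GeneratorConfig(
            model_kind="ggm",
            constants=ggm_truth_2mg,
            start="ggm_default",
            ph_model=constant_ph8,
            sample_times=np.geomspace(1.0, 700.0, 25),
            noise=NoiseModel(kind="none"),
        )
    )


def perturbed_guess(constants, seed, scale=0.5):
    """Multiplicative +-50 % perturbation of the true constants."""
    rng = np.random.default_rng(seed)
    return {
        name: value * rng.uniform(1.0 - scale, 1.0 + scale)
        for name, value in constants.as_dict().items()
    }


@pytest.fixture(scope="session")
def tri_joint_fit_result(tri_joint_noise_free, tri_truth):
    """Joint fit of the noise-free pair from +-50 %-perturbed initial guesses."""
    config = FitConfig(
        initial_guess=perturbed_guess(tri_truth, seed=20210374),
        multistart_count=1,
    )
    return fit_rate_constants(tri_joint_noise_free, config)
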
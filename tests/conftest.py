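import numpy as np
import pytest

from fjordfe import (
    DissolutionCurve,
    RCMParams,
    build_dissolution_curve,
    field_schedule,
    simulate_dissolution,
)


@pytest.fixture(scope="session")
def schedule():
    """Full 32-h field sampling schedule."""
    return field_schedule()


@pytest.fixture(scope="session")
def reference_truth():
    """A mid-range extractable pool used across recovery tests."""
    return RCMParams(m0=30.0, a=5000.0, v=1.5)


def curve_from_truth(
    truth: RCMParams,
    schedule: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    dry_mass: float = 0.75,
    volume: float = 0.1,
) -> DissolutionCurve:
    """Simulate a vessel and rebuild the per-g-dw curve, as the pipeline does."""
    tab = simulate_dissolution(truth, schedule, noise_sd, seed, dry_mass, volume)
    return build_dissolution_curve(
        tab["time_s"].to_numpy(),
        tab["conc_uM"].to_numpy(),
        volume_l=volume,
        dry_mass_g=dry_mass,
    )


@pytest.fixture(scope="session")
def noiseless_curve(reference_truth, schedule):
    return curve_from_truth(reference_truth, schedule)
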
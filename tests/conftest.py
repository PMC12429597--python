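import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Small seeded synthetic dataset shared across tests: 60 fragments,
    12 planted (2 per response x direction, 20-point effects)."""
    from rrbsdmf.simulate import PlantedClass, SimConfig, generate_dataset

    config = SimConfig(
        n_fragments=60,
        planted_classes=tuple(
            PlantedClass(resp, d, 20.0, 2)
            for resp in ("early", "late", "gradual")
            for d in ("hyper", "hypo")
        ),
        seed=42,
    )
    genome, truth, calls = generate_dataset(config)
    return config, genome, truth, calls


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    """MethMatrix built from the small dataset via the fragment engine."""
    from rrbsdmf.detection import MethMatrix
    from rrbsdmf.fragments import aggregate_to_fragments, methylation_to_frame

    config, genome, truth, calls = small_dataset
    records = []
    for sample_calls in calls.values():
        records.extend(aggregate_to_fragments(sample_calls, genome.fragments))
    frame = methylation_to_frame(records)
    samples = pd.DataFrame(
        [
            {"sample_id": p, "participant": p, "group": g}
            for p, g in config.participants
        ]
    )
    return MethMatrix.from_long(frame, samples, config.timepoints)
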
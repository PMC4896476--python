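import pytest

from skinsense import (
    BenchmarkSpec,
    compute_descriptor_matrix,
    default_alert_library,
    generate_benchmark,
)


@pytest.fixture(scope="session")
def alert_library():
    return default_alert_library()


@pytest.fixture(scope="session")
def small_benchmark(alert_library):
    """60 synthetic molecules across all potency classes."""
    return generate_benchmark(BenchmarkSpec(n=60, seed=101), alert_library)


@pytest.fixture(scope="session")
def small_matrix(small_benchmark, alert_library):
    return compute_descriptor_matrix(
        small_benchmark, reactive_alerts=alert_library
    )
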
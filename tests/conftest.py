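import pytest
from hypothesis import HealthCheck, settings

from tagdiff.datasets import load_rss_liver_mirna
from tagdiff.tag_io import LibraryPair

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_libs() -> LibraryPair:
    """The two liver libraries' clean-read totals (A = RSS, B = normal)."""
    return LibraryPair("RSS", "normal", 9_246_256, 8_714_768)


@pytest.fixture(scope="session")
def mirna_table():
    """The packaged 22-miRNA count table and its library pair."""
    return load_rss_liver_mirna()
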
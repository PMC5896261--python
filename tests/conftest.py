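import pytest

from sortstat import correlate_statistics, generate_table, screen_features


@pytest.fixture(scope="session")
def default_screen():
    """Screen of the default seeded synthetic table (shared: ~2 s to build)."""
    table = generate_table()
    result = screen_features(table)
    return result


@pytest.fixture(scope="session")
def default_correlations(default_screen):
    return correlate_statistics(default_screen, method="spearman")
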
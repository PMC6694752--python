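import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for ptf_oracle

from gridsol.fixtures import FixtureSpec, generate_input_stack, generate_template_set


@pytest.fixture(scope="session")
def small_stack():
    """Seeded synthetic input stack, 80x80 fine -> 8x8 coarse."""
    return generate_input_stack(FixtureSpec(shape=(80, 80), seed=7))


@pytest.fixture(scope="session")
def three_zone_stack():
    """Preset with clayey / loamy / sandy vertical zones."""
    return generate_input_stack(
        FixtureSpec(shape=(60, 90), seed=11, preset="three-zone",
                    nodata_fraction=0.0)
    )


@pytest.fixture(scope="session")
def template_dir(tmp_path_factory):
    """Directory holding the 27 synthetic template *.SOL files."""
    d = tmp_path_factory.mktemp("templates")
    generate_template_set(3, d)
    return d
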
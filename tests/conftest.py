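import io

import pytest

from sonq import fixtures, query_gen
from sonq.template_io import read_template, write_template


@pytest.fixture
def niti_dson():
    """The example dSON, queries ungenerated."""
    return fixtures.build_niti_dson()


@pytest.fixture
def niti_generated():
    """The example dSON with English queries generated."""
    dson = fixtures.build_niti_dson()
    report = query_gen.generate_all(
        dson, query_gen.GenerationOptions(languages=("en",))
    )
    assert not report.errors
    return dson


@pytest.fixture
def niti_workbook_bytes():
    buf = io.BytesIO()
    fixtures.build_niti_workbook(buf)
    return buf.getvalue()


def roundtrip_via_template(dson):
    buf = io.BytesIO()
    write_template(dson, buf)
    buf.seek(0)
    return read_template(buf)
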
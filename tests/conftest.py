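import base64
import struct
import textwrap

import numpy as np
import pytest

from apvpeaks.hpso import HpsoConfig

_DUMMY_BOUNDS = ((0.0, 1.0),) * 6


@pytest.fixture
def fast_hpso():
    """Reduced-budget swarm config used throughout the unit tests."""
    return HpsoConfig(bounds=_DUMMY_BOUNDS, n_particles=40, max_iter=300, patience=30)


def write_mzml(path, mz, intensity):
    """Write a minimal single-spectrum mzML file (64-bit, uncompressed)."""

    def encode(arr):
        raw = struct.pack("<%dd" % len(arr), *arr)
        return base64.b64encode(raw).decode()

    body = textwrap.dedent(
        """\
        <?xml version="1.0" encoding="utf-8"?>
        <mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
          <run id="run1">
            <spectrumList count="1">
              <spectrum index="0" id="scan=1" defaultArrayLength="{n}">
                <binaryDataArrayList count="2">
                  <binaryDataArray>
                    <cvParam accession="MS:1000523" name="64-bit float"/>
                    <cvParam accession="MS:1000576" name="no compression"/>
                    <cvParam accession="MS:1000514" name="m/z array"/>
                    <binary>{mz}</binary>
                  </binaryDataArray>
                  <binaryDataArray>
                    <cvParam accession="MS:1000523" name="64-bit float"/>
                    <cvParam accession="MS:1000576" name="no compression"/>
                    <cvParam accession="MS:1000515" name="intensity array"/>
                    <binary>{inten}</binary>
                  </binaryDataArray>
                </binaryDataArrayList>
              </spectrum>
            </spectrumList>
          </run>
        </mzML>
        """
    ).format(n=len(mz), mz=encode(mz), inten=encode(intensity))
    path.write_text(body)


@pytest.fixture
def mzml_writer():
    return write_mzml


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
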
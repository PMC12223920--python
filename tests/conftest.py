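import numpy as np
import pytest

from etherdnp.spectra import AcquisitionMeta, Spectrum1D


@pytest.fixture
def uniform_axis_spectrum() -> Spectrum1D:
    """A small flat spectrum on the fixture axis 200 ... 200-400*(1023/1024)."""
    n = 1024
    ppm = 200.0 - np.arange(n) * (400.0 / n)
    return Spectrum1D(ppm_axis=ppm, intensity=np.zeros(n),
                      meta=AcquisitionMeta(label="fixture"))


@pytest.fixture
def bruker_dir(tmp_path):
    """Minimal Bruker processed dataset: SW 400 ppm, offset 200 ppm, 1024 pts.

    Written as int32 with NC_proc scaling, the common TopSpin layout.
    """
    n = 1024
    sf = 100.6
    procno = tmp_path / "10" / "pdata" / "1"
    procno.mkdir(parents=True)
    (procno / "procs").write_text(
        "##TITLE= Parameter file, TopSpin\n"
        f"##$SI= {n}\n"
        f"##$SW_p= {400.0 * sf}\n"
        f"##$SF= {sf}\n"
        "##$OFFSET= 200.0\n"
        "##$BYTORDP= 0\n"
        "##$DTYPP= 0\n"
        "##$NC_proc= -3\n"
    )
    rng = np.random.default_rng(7)
    data = rng.integers(-2**20, 2**20, n, dtype=np.int32)
    (procno / "1r").write_bytes(data.astype("<i4").tobytes())
    return tmp_path / "10", data
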
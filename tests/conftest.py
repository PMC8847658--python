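import numpy as np
import pytest

from netstab import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    """Small iid-Gaussian recording: 5 channels, 2 s at 500 Hz."""
    return Recording(
        subject_id="noise",
        data=rng.standard_normal((5, 1000)),
        sampling_rate_hz=500.0,
        channel_labels=[f"ch{i}" for i in range(5)],
    )


def make_network(weights):
    """Symmetric zero-diagonal matrix from an upper-triangle dict {(j,k): w}."""
    n = 1 + max(max(jk) for jk in weights)
    mat = np.zeros((n, n))
    for (j, k), w in weights.items():
        mat[j, k] = mat[k, j] = w
    return mat


def random_network(n, rng):
    tri = rng.random((n, n))
    mat = np.triu(tri, 1)
    mat = mat + mat.T
    return mat


def write_minimal_edf(path, data, sfreq, labels):
    """Hand-rolled EDF writer for test fixtures (16-bit, one data record/s).

    Produces a spec-conforming European Data Format file so the reader can
    be exercised without any binary fixture in the repository.
    """
    n_sig, n_samp = data.shape
    assert n_samp % int(sfreq) == 0
    spr = int(sfreq)  # samples per 1-second record
    n_rec = n_samp // spr
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(s, width):
        s = str(s)[:width]
        return s + " " * (width - len(s))

    header = (
        pad("0", 8)
        + pad("X X X X", 80)
        + pad("X X X X", 80)
        + pad("01.01.20", 8)
        + pad("00.00.00", 8)
        + pad(str(256 * (1 + n_sig)), 8)
        + pad("", 44)
        + pad(str(n_rec), 8)
        + pad("1", 8)
        + pad(str(n_sig), 4)
    )
    fields = [
        (labels, 16),
        (["" for _ in range(n_sig)], 80),
        (["uV" for _ in range(n_sig)], 8),
        ([repr(phys_min) for _ in range(n_sig)], 8),
        ([repr(phys_max) for _ in range(n_sig)], 8),
        ([str(dig_min) for _ in range(n_sig)], 8),
        ([str(dig_max) for _ in range(n_sig)], 8),
        (["" for _ in range(n_sig)], 80),
        ([str(spr) for _ in range(n_sig)], 8),
        (["" for _ in range(n_sig)], 32),
    ]
    for values, width in fields:
        header += "".join(pad(v, width) for v in values)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.clip(np.round(data / scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for r in range(n_rec):
            for s in range(n_sig):
                fh.write(digital[s, r * spr : (r + 1) * spr].tobytes())
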
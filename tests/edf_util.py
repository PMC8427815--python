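"""Minimal EDF writer for test fixtures (synthetic; written at test time).

Implements just enough of the European Data Format header + int16 record
layout to produce files standard readers accept.  Only used to build tiny
import fixtures; the package itself never writes EDF.
"""

import numpy as np

PHYS_MIN, PHYS_MAX = -3276.8, 3276.7
DIG_MIN, DIG_MAX = -32768, 32767


def write_minimal_edf(path, signals, ch_names, sfreq):
    """Write ``signals`` (n_channels, n_samples) in microvolts, one 1-s data
    record per ``sfreq`` samples; n_samples must divide evenly."""
    signals = np.asarray(signals, dtype=float)
    n_ch, n_samp = signals.shape
    assert n_samp % sfreq == 0, "test fixture requires whole data records"
    n_rec = n_samp // sfreq

    def pad(text, width):
        return str(text).ljust(width)[:width].encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 * (1 + n_ch), 8),
            pad("", 44),
            pad(n_rec, 8),
            pad("1", 8),
            pad(n_ch, 4),
        ]
        + [pad(name, 16) for name in ch_names]
        + [pad("", 80)] * n_ch
        + [pad("uV", 8)] * n_ch
        + [pad(PHYS_MIN, 8)] * n_ch
        + [pad(PHYS_MAX, 8)] * n_ch
        + [pad(DIG_MIN, 8)] * n_ch
        + [pad(DIG_MAX, 8)] * n_ch
        + [pad("", 80)] * n_ch
        + [pad(sfreq, 8)] * n_ch
        + [pad("", 32)] * n_ch
    )
    scale = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.round((signals - PHYS_MIN) * scale + DIG_MIN).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            for ch in range(n_ch):
                fh.write(digital[ch, rec * sfreq : (rec + 1) * sfreq].tobytes())
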
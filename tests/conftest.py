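"""Shared fixtures: small seeded synthetic trial sets and a BrainVision writer.

Everything is generated at test time; nothing binary is stored in the repo.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from mi3d import SynthParams, generate


def write_brainvision(directory: Path, stem: str, data: np.ndarray,
                      channel_names: list[str], fs: float,
                      events: list[tuple[int, int]]) -> Path:
    """Write a minimal BrainVision triplet (.vhdr/.vmrk/.eeg).

    Data is stored multiplexed IEEE float32 in microvolts with resolution 1;
    stimulus markers use 1-based positions ("S<code>").  Returns the .vhdr
    path.
    """
    directory = Path(directory)
    vhdr = [
        "Brain Vision Data Exchange Header File Version 1.0", "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(channel_names)}",
        f"SamplingInterval={1e6 / fs:.0f}", "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32", "",
        "[Channel Infos]",
    ]
    vhdr += [f"Ch{i + 1}={n},,1,µV" for i, n in enumerate(channel_names)]
    (directory / f"{stem}.vhdr").write_text("\n".join(vhdr) + "\n",
                                            encoding="utf-8")
    vmrk = [
        "Brain Vision Data Exchange Marker File, Version 1.0", "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg", "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    vmrk += [f"Mk{j + 2}=Stimulus,S{code:>3},{sample + 1},1,0"
             for j, (sample, code) in enumerate(events)]
    (directory / f"{stem}.vmrk").write_text("\n".join(vmrk) + "\n",
                                            encoding="utf-8")
    np.asarray(data, dtype=np.float32).T.tofile(directory / f"{stem}.eeg")
    return directory / f"{stem}.vhdr"


@pytest.fixture(scope="session")
def small_ts():
    """16-channel, 10 trials/class, snr 1 — quick four-class fixture."""
    ts, truth = generate(SynthParams(n_channels=16, trials_per_class=10,
                                     snr=1.0, seed=1))
    return ts, truth


@pytest.fixture(scope="session")
def binary_ts(small_ts):
    ts, _ = small_ts
    return ts.select(np.isin(ts.labels, (1, 2)))
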
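"""Brute-force run-length chord oracle shared by the chord test suites."""

import numpy as np


def rle_chords(mask, phase="pore"):
    """Chord lengths of one phase along the three axes, by explicit scan.

    Returns ``(lengths, touches)`` where ``touches`` marks runs abutting
    the volume boundary.
    """
    m = mask if phase == "pore" else ~mask
    lengths, touches = [], []
    for axis in range(3):
        moved = np.moveaxis(m, axis, -1)
        for row in moved.reshape(-1, moved.shape[-1]):
            run = 0
            for i, v in enumerate(row):
                if v:
                    run += 1
                elif run:
                    lengths.append(run)
                    touches.append(run == i)  # a run ending at i started at i-run
                    run = 0
            if run:
                lengths.append(run)
                touches.append(True)
    return np.array(lengths), np.array(touches, dtype=bool)
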
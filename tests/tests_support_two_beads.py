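"""Shared helper: a minimal two-bead membrane for pair-potential tests."""

import numpy as np

from mnpsteer.membrane import ForceFieldParams, MembraneModel


def make_two_beads(r, eps=0.35, sigma=4.6, q1=0.0, q2=0.0):
    pos = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    return MembraneModel(
        positions=pos,
        types=np.array(["T", "T"]),
        bonds=np.zeros((0, 2), dtype=int),
        angles=np.zeros((0, 3), dtype=int),
        dihedrals=np.zeros((0, 4), dtype=int),
        impropers=np.zeros((0, 4), dtype=int),
        params=ForceFieldParams(),
        lateral_size=(20.0, 20.0),
        masses=np.array([80.0, 80.0]),
        charges=np.array([q1, q2]),
        eps=np.array([eps, eps]),
        sigma=np.array([sigma, sigma]),
        anchor_idx=np.zeros(0, dtype=int),
        anchor_ref=np.zeros((0, 3)),
    )
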
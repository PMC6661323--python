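"""Shared fixtures: small connectomes and helper factories."""

from __future__ import annotations

import numpy as np
import pytest

from connectodelay.connectome import Connectome, coupling_matrix
from connectodelay.synthetic import SyntheticSpec, generate_connectome


@pytest.fixture
def conn2():
    """Minimal valid 2-node connectome (one inter-hemispheric link)."""
    return Connectome(
        weights=np.array([[0.0, 3.0], [3.0, 0.0]]),
        tract_lengths=np.array([[0.0, 50.0], [50.0, 0.0]]),
        hemisphere=np.array(["L", "R"]),
    )


@pytest.fixture
def conn4():
    """4-node toy, two per hemisphere, hand-set weights and lengths."""
    w = np.array(
        [
            [0.0, 2.0, 1.0, 0.5],
            [2.0, 0.0, 0.0, 3.0],
            [1.0, 0.0, 0.0, 4.0],
            [0.5, 3.0, 4.0, 0.0],
        ]
    )
    lg = np.array(
        [
            [0.0, 30.0, 90.0, 110.0],
            [30.0, 0.0, 0.0, 80.0],
            [90.0, 0.0, 0.0, 40.0],
            [110.0, 80.0, 40.0, 0.0],
        ]
    )
    return Connectome(weights=w, tract_lengths=lg,
                      hemisphere=np.array(["L", "L", "R", "R"]))


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic connectome reused across simulation tests."""
    return generate_connectome(SyntheticSpec(n_per_hemisphere=4, seed=3))


def make_files(tmp_path, weights, lengths, labels, delimiter=" "):
    """Write the three connectome files and return their paths."""
    wp = tmp_path / "weights.txt"
    lp = tmp_path / "lengths.txt"
    bp = tmp_path / "labels.txt"
    np.savetxt(wp, np.asarray(weights), delimiter=delimiter)
    np.savetxt(lp, np.asarray(lengths), delimiter=delimiter)
    bp.write_text("\n".join(labels) + "\n")
    return wp, lp, bp
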
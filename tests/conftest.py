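from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from duophase.sv_signatures import ReadSignature

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_sig(read_id="r0", hp=None, pc=0.0, vc=0, ps=None) -> ReadSignature:
    if hp is None:
        return ReadSignature(read_id=read_id, hp=None, pc=0.0, vc=vc, phase_set=None)
    return ReadSignature(read_id=read_id, hp=hp, pc=pc, vc=vc, phase_set=ps if ps is not None else 1)


def random_signatures(rng: np.random.Generator, n_min=1, n_max=20) -> list[ReadSignature]:
    """A random signature list with at least one supporting read."""
    n = int(rng.integers(n_min, n_max + 1))
    sigs = []
    for i in range(n):
        vc = int(rng.choice([0, 0, 1, 1, 2]))
        if rng.random() < 0.75:
            sigs.append(make_sig(f"r{i}", hp=int(rng.integers(1, 3)),
                                 pc=float(rng.integers(0, 20000)), vc=vc,
                                 ps=int(rng.integers(1, 3))))
        else:
            sigs.append(make_sig(f"r{i}", vc=vc))
    if not any(s.vc > 0 for s in sigs):
        sigs[0] = make_sig("r0", hp=1, pc=float(rng.integers(0, 20000)), vc=1)
    return sigs
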
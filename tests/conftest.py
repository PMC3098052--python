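from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from intergene.model import AlignmentHit, Orf
from intergene.simulate import SimulationConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """The default synthetic pan-genome: 4 families x 2 replicons, 10 planted
    missing-gene families, 5 absent annotations, 10 shadow ORFs, no noise."""
    return generate(SimulationConfig(seed=11))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=length, p=p))


def make_hit(
    query_id="q",
    subject_id="s",
    e_value=1e-10,
    I=100.0,
    avg_cov=100.0,
    q_len=100,
    s_len=100,
) -> AlignmentHit:
    """Construct a hit with a prescribed I and avg_cov (symmetric spans)."""
    n_id = round(I * q_len * s_len / (50 * (q_len + s_len)))
    span_q = round(avg_cov * q_len / 100)
    span_s = round(avg_cov * s_len / 100)
    hit = AlignmentHit(query_id, subject_id, e_value, n_id, span_q, span_s, q_len, s_len)
    assert abs(hit.I - I) < 1.0 and abs(hit.avg_cov - avg_cov) < 1.0
    return hit


def make_orf(replicon_id="FAMQ_R1", start=0, end=99, strand="+", orf_id=None) -> Orf:
    nt = "ATG" + "AAA" * ((end - start) // 3 - 1)
    return Orf(
        orf_id=orf_id or f"{replicon_id}|{strand}|{start}-{end}",
        replicon_id=replicon_id,
        start=start,
        end=end,
        strand=strand,
        nt_seq=nt,
        aa_seq="M" + "K" * ((end - start) // 3 - 1),
    )
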
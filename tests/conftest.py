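import numpy as np
import pytest

from smaugkit.fold import FoldingModel


@pytest.fixture(scope="session")
def model() -> FoldingModel:
    return FoldingModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_hairpin_construct(loop: str = "CUGGC", stem: str = "CGCGG",
                           context_len: int = 250, site_pos: int = 122) -> tuple[str, int]:
    """Planted stem-loop centred in a pairing-inert poly-A context; returns
    (sequence, loop start position)."""
    from smaugkit.simulate import revcomp
    hp = stem + loop + revcomp(stem)
    ctx = "A" * context_len
    start = site_pos - len(stem)
    seq = ctx[:start] + hp + ctx[start + len(hp):]
    assert len(seq) == context_len and seq[site_pos:site_pos + 4] == loop[:4]
    return seq, site_pos
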
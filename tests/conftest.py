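import numpy as np
import pytest

from readsieve.seedcodes import Mask, encode, parse_mask

_COMP = str.maketrans("ACGTacgt", "TGCATGCA")


def revcomp_str(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_extract(seq: str, mask: Mask) -> list[tuple[int, int]]:
    """Independent per-window recomputation of canonical gapped codes."""
    s = seq.upper()
    w = mask.width_w
    out = []
    for i in range(len(s) - w + 1):
        win = s[i:i + w]
        if any(c not in "ACGT" for c in win):
            continue
        sig = "".join(win[j] for j in mask.kappa)
        rc_win = revcomp_str(win)
        sig_rc = "".join(rc_win[j] for j in mask.kappa)
        out.append((i, max(encode(sig), encode(sig_rc))))
    return out


@pytest.fixture(scope="session")
def small_mask() -> Mask:
    return parse_mask("##_#_##")


@pytest.fixture(scope="session")
def default_mask() -> Mask:
    from readsieve.seedcodes import DEFAULT_MASK

    return parse_mask(DEFAULT_MASK)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
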
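import numpy as np
import pytest

from sprecall import Lexicon

# the published six-word illustration: frequencies, reference-population
# size and minimum, and the per-interval counts the source reports
WORKED_FREQS = (1.69, 42.43, 5.14, 0.88, 0.88, 5.2)
WORKED_WORDS = ("plongeur", "cercle", "brouette", "esquimau", "poireau", "oie")
WORKED_T = 24530
WORKED_FMIN = 0.07
WORKED_N = 30


def _engineered_lexicon() -> Lexicon:
    """A synthetic 24,530-word lexicon whose closed-interval counts match
    the published worked example: 12,513 words in [0.07, 1.69], 6,204 in
    [1.69, 42.43], 10,037 in [0.07, 0.88] and 29 in [5.14, 5.2]."""
    blocks = [
        (0.07, 1),
        (0.5, 10035),
        (0.88, 1),     # [0.07, 0.88] -> 10,037
        (1.2, 2475),
        (1.69, 1),     # [0.07, 1.69] -> 12,513
        (2.0, 6173),
        (5.17, 29),    # [5.14, 5.2]  -> 29
        (42.43, 1),    # [1.69, 42.43] -> 6,204
        (100.0, 5814), # pads the total to 24,530
    ]
    freqs = np.concatenate([np.full(n, f) for f, n in blocks])
    words = np.array([f"syn{i:05d}" for i in range(freqs.size)], dtype=object)
    return Lexicon(words=words, freqs=freqs)


@pytest.fixture(scope="session")
def worked_lexicon() -> Lexicon:
    return _engineered_lexicon()


@pytest.fixture
def tiny_lexicon() -> Lexicon:
    freqs = np.array([0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 13.0, 21.0, 34.0, 55.0])
    words = np.array([f"w{i}" for i in range(10)], dtype=object)
    return Lexicon(words=words, freqs=freqs)
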
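import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for dp_oracle


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def mutate(seq, rng, n_sub=0, n_del=0, n_ins=0):
    """Plant a fixed number of random edits into a sequence."""
    s = list(seq)
    idx = rng.choice(len(s), size=min(len(s), n_sub + n_del + n_ins),
                     replace=False)
    subs, dels, ins = idx[:n_sub], idx[n_sub:n_sub + n_del], idx[n_sub + n_del:]
    for k in subs:
        s[k] = rng.choice([b for b in "ACGT" if b != s[k]])
    for k in dels:
        s[k] = ""
    for k in ins:
        s[k] = s[k] + rng.choice(list("ACGT"))
    return "".join(s)
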
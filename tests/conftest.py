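import numpy as np
import pytest

import lhekit as lk
from lhekit.readout import AmpliconRef


@pytest.fixture(scope="session")
def ani_site():
    return lk.ANI_SITE


@pytest.fixture(scope="session")
def xid_site():
    return lk.XID_SITE


@pytest.fixture(scope="session")
def amplicon_ref(xid_site):
    """Synthetic amplicon: the XID site centered between 50 bp random flanks."""
    rng = np.random.default_rng(12345)
    left = "".join(rng.choice(list("ACGT"), 50))
    right = "".join(rng.choice(list("ACGT"), 50))
    return AmpliconRef(left + xid_site.sequence + right, site_span=(50, 70))


@pytest.fixture(scope="session")
def donor_ref(amplicon_ref):
    """Same amplicon with a 2-base donor signature outside the cut window."""
    seq = amplicon_ref.sequence
    sig = []
    for idx in (52, 67):  # inside site span, outside the central four bases
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq[idx]]
        sig.append((idx, alt))
    return AmpliconRef(
        seq, site_span=amplicon_ref.site_span, donor_signature=tuple(sig)
    )


def random_site(rng, length=20, name="rand"):
    return lk.TargetSite(name, "".join(rng.choice(list("ACGT"), length)))
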
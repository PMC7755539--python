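import numpy as np
import pytest

from thelr import bfv
from thelr.ring import derive_rng
from thelr.sigmoid import build_integerized


@pytest.fixture(scope="session")
def g3():
    return build_integerized()


class KeyContext:
    """Parameter sets plus a full set of party keys for both param sets."""

    def __init__(self, profile: str, z: int, seed: int = 7):
        self.p1, self.p2 = bfv.setup_params(profile)
        self.z = z
        self.crs1 = bfv.keygen_common(self.p1, seed)
        self.crs2 = bfv.keygen_common(self.p2, seed)
        self.keys1 = [bfv.keygen_party(self.p1, self.crs1, f"p{i}",
                                       derive_rng(seed, "kg1", i))
                      for i in range(z)]
        self.keys2 = [bfv.keygen_party(self.p2, self.crs2, f"p{i}",
                                       derive_rng(seed, "kg2", i))
                      for i in range(z)]
        self.pk1 = bfv.combine_public_keys(self.keys1, self.crs1)
        self.pk2 = bfv.combine_public_keys(self.keys2, self.crs2)
        self.s_co = bfv.combined_secret(self.keys1)
        self.seed = seed
        self._rlk = None

    @property
    def rlk(self):
        if self._rlk is None:   # single-key reference path (fast) for op tests
            self._rlk = bfv.relin_keygen_single(
                self.p1, self.s_co, np.random.default_rng(self.seed))
        return self._rlk

    def decrypt(self, ct, rng=None):
        rng = rng or np.random.default_rng(0)
        shares = [bfv.partial_decrypt(ct, k, rng) for k in self.keys1]
        return bfv.combine_decrypt(ct, shares, expected_parties=self.z)


@pytest.fixture(scope="session")
def tiny3():
    return KeyContext("tiny", z=3)


@pytest.fixture(scope="session")
def mini3():
    return KeyContext("mini", z=3)


@pytest.fixture(scope="session")
def mini3_protocol_rlk(mini3):
    return bfv.relin_keygen_protocol(mini3.keys1, mini3.keys2, mini3.p1,
                                     mini3.p2, mini3.pk2, 42)
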
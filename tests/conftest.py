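from functools import lru_cache

import pytest

from capsidlattice import build_capsid, build_icosahedron


@lru_cache(maxsize=None)
def _capsid(h, k, handedness="laevo"):
    return build_capsid((h, k), handedness=handedness)


@pytest.fixture(scope="session")
def capsid():
    """Cached capsid factory: capsid(h, k[, handedness])."""
    return _capsid


@pytest.fixture(scope="session")
def ico():
    return build_icosahedron()
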
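"""Named child random streams.

All randomness in the package derives from one root integer seed.  A child
stream is identified by the root seed plus one or more string labels; the
labels are hashed with CRC-32 so that adding a new stream never perturbs any
existing one.  The contract is::

    rng = child_rng(seed, "label1", "label2")
      ==  numpy.random.default_rng(
              numpy.random.SeedSequence([seed, crc32(b"label1"), crc32(b"label2")]))

which is stable across platforms and numpy versions.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np


def child_seed_sequence(seed: int, *labels: str) -> np.random.SeedSequence:
    """SeedSequence for the child stream named by ``labels`` under ``seed``."""
    entropy = [int(seed)] + [crc32(lbl.encode("utf-8")) for lbl in labels]
    return np.random.SeedSequence(entropy)


def child_rng(seed: int, *labels: str) -> np.random.Generator:
    """A ``numpy.random.Generator`` for the named child stream."""
    return np.random.default_rng(child_seed_sequence(seed, *labels))
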
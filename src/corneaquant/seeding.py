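"""Deterministic seed derivation.

One global seed drives the whole pipeline; each stage (and each group within a
stage) gets its own substream derived by hashing the stage name, so stages can
be rerun independently yet reproducibly and no stage ever reads OS entropy.
"""

from __future__ import annotations

import zlib


def derive_seed(global_seed: int, *names: str) -> int:
    """Derive a stage seed from the global seed and one or more stage names.

    Uses CRC32 of the joined names mixed with the global seed; the result is
    always in ``[0, 2**31)`` so it is valid for every RNG constructor.
    """
    tag = zlib.crc32("/".join(names).encode("utf-8"))
    return (int(global_seed) * 2654435761 + tag) % (2**31)
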
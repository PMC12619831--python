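"""Deterministic stage-salted seed derivation.

Every stochastic stage of the pipeline draws its seed from the single
user-supplied run seed combined with the stage name, so that reruns are
bit-identical and stages are decoupled (changing the permutation count of
one stage never shifts another stage's stream).
"""

from __future__ import annotations

import zlib

_MOD = 2**31 - 1


def salted_seed(base_seed: int, stage: str) -> int:
    """Derive a stage-specific seed below 2**31 from ``base_seed``."""
    return (int(base_seed) * 1000003 + zlib.crc32(stage.encode("utf-8"))) % _MOD
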
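"""Deterministic per-stage random substreams derived from one root seed."""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named pipeline stage, independent across stage names.

    Uses a ``SeedSequence`` keyed on ``(seed, crc32(stage))`` so adding or
    reordering stages never perturbs the streams of other stages.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
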
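"""Reproducible hierarchical random streams.

All randomness in the toolkit flows from one root seed through named
substreams: the same ``(root_seed, path)`` always reproduces the same draws,
independent of how many sibling streams were consumed before it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RNGStream:
    root_seed: int
    path: tuple[int, ...] = ()

    def child(self, *indices: int) -> "RNGStream":
        return RNGStream(self.root_seed, self.path + tuple(int(i) for i in indices))

    def generator(self) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=int(self.root_seed), spawn_key=self.path)
        return np.random.default_rng(ss)
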
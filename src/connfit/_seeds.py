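"""Named random substreams derived from a single master seed.

Every stochastic stage draws from ``numpy.random.Generator`` instances built
from a ``SeedSequence`` whose entropy is ``[master_seed, stream_id, *keys]``.
Streams are therefore independent of execution order and of each other, which
makes per-(region, domain, permutation) seeding parallel-safe: worker count
cannot change any result.
"""

from __future__ import annotations

import numpy as np

# Stream identifiers. Values are arbitrary but frozen: changing them changes
# every generated dataset.
STREAM_PARCELLATION = 11
STREAM_TIMESERIES = 12
STREAM_MIXING = 13
STREAM_WEIGHTS = 14
STREAM_ACTIVATION_NOISE = 15
STREAM_PLANTED_R2 = 16
STREAM_CV_FOLDS = 17
STREAM_PERMUTATION = 18
STREAM_BOOTSTRAP = 19


def substream(master_seed: int, stream_id: int, *keys: int) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``.

    ``keys`` extend the entropy pool, e.g. ``(subject, run)`` or
    ``(region_id, domain_id, perm_index)``.
    """
    entropy = [int(master_seed), int(stream_id), *(int(k) for k in keys)]
    return np.random.default_rng(np.random.SeedSequence(entropy))
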
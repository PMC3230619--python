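"""Weighted sampling without replacement for passive particle relocation.

During passive rebalancing the surplus particles of a layer are picked one
at a time, each draw proportional to the remaining particles' weights
(tracer particles carry weight ``weight``, non-marked particles weight 1).
The number of tracer particles among the ``k`` picks then follows
Wallenius' noncentral hypergeometric distribution.

Rather than looping over single draws, we use the exponential-clocks
representation of successive sampling: give every particle an independent
Exp(weight) key and take the ``k`` smallest. By the memorylessness of the
exponential this is distributionally identical to the sequential procedure,
and it vectorises.
"""

from __future__ import annotations

import numpy as np

from .errors import ConsistencyError

__all__ = ["draw_tracer_moves"]


def draw_tracer_moves(
    n_tracer: int,
    n_other: int,
    k: int,
    weight: float,
    rng: np.random.Generator,
) -> int:
    """Number of tracer particles among ``k`` particles removed from a pool.

    The pool holds ``n_tracer`` tracer particles (selection weight
    ``weight``) and ``n_other`` non-marked particles (weight 1); particles
    are removed sequentially without replacement, each with probability
    proportional to its weight. Returns how many of the removed particles
    are tracers — a Wallenius noncentral hypergeometric variate (plain
    hypergeometric when ``weight == 1``).
    """
    if k <= 0:
        return 0
    total = n_tracer + n_other
    if k > total:
        raise ConsistencyError(
            f"cannot remove {k} particles from a pool of {total}"
        )
    if n_tracer == 0:
        return 0
    if n_other == 0:
        return k
    if k == total:
        return int(n_tracer)
    if weight == 1.0:
        return int(rng.hypergeometric(n_tracer, n_other, k))
    # Exp(rate=weight) has scale 1/weight: larger weight -> earlier pick.
    keys_tracer = rng.exponential(1.0 / weight, n_tracer)
    keys_other = rng.exponential(1.0, n_other)
    pool = np.concatenate([keys_tracer, keys_other])
    threshold = np.partition(pool, k - 1)[k - 1]
    return int(np.count_nonzero(keys_tracer <= threshold))
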
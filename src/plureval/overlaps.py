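"""DEG-set overlap statistics.

Overlap of two DEG sets drawn from a common background of expressed genes is
tested with the exact upper-tail hypergeometric probability P(X >= k)
(reported alongside its continuity-corrected normal approximation) and
summarized by the representation factor k / (n1 * n2 / N). For genes shared
between two analyses with up/down labels, direction concordance is tested
with a two-sided exact binomial test at rate 1/2 on the discordant count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import ValidationError


@dataclass
class OverlapResult:
    n1: int
    n2: int
    background: int
    overlap: int
    expected: float
    representation_factor: float
    p_exact: float
    p_normal: float
    same_direction: int | None = None
    opposite_direction: int | None = None
    direction_binomial_p: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _directions(genes) -> dict:
    if isinstance(genes, dict):
        return genes
    return {}


def overlap_test(set1, set2, background) -> OverlapResult:
    """Hypergeometric over-representation test of two gene sets.

    ``set1`` and ``set2`` may be plain id collections or dicts mapping id to
    an 'up'/'down' direction label (enabling the concordance split);
    ``background`` is the set of genes expressed in both underlying analyses.
    """
    d1, d2 = _directions(set1), _directions(set2)
    s1, s2, bg = set(set1), set(set2), set(background)
    if len(bg) == 0:
        raise ValidationError("empty background")
    if not s1 <= bg or not s2 <= bg:
        raise ValidationError("DEG sets must be contained in the background")
    n1, n2, n = len(s1), len(s2), len(bg)
    shared = s1 & s2
    k = len(shared)
    expected = n1 * n2 / n
    rep = k / expected if expected > 0 else np.nan
    p_exact = float(stats.hypergeom.sf(k - 1, n, n1, n2))

    var = n1 * n2 * (n - n1) * (n - n2) / (n**2 * (n - 1)) if n > 1 else 0.0
    if var > 0:
        p_normal = float(stats.norm.sf((k - 0.5 - expected) / np.sqrt(var)))
    else:
        p_normal = 1.0 if k <= expected else 0.0

    same = opp = None
    bin_p = None
    if d1 and d2:
        same, opp, bin_p = direction_concordance(d1, d2, shared)
    return OverlapResult(
        n1=n1,
        n2=n2,
        background=n,
        overlap=k,
        expected=expected,
        representation_factor=rep,
        p_exact=p_exact,
        p_normal=p_normal,
        same_direction=same,
        opposite_direction=opp,
        direction_binomial_p=bin_p,
    )


def direction_concordance(dirs1: dict, dirs2: dict, shared=None):
    """Concordant/discordant counts of shared DEGs and a binomial test.

    Every shared gene must carry an 'up' or 'down' label in both analyses.
    Returns (same, opposite, two-sided binomial p at rate 1/2 on the
    discordant count); the p-value is NaN for an empty shared set.
    """
    if shared is None:
        shared = set(dirs1) & set(dirs2)
    same = opp = 0
    for g in shared:
        a, b = dirs1[g], dirs2[g]
        if a not in ("up", "down") or b not in ("up", "down"):
            raise ValidationError(f"gene {g!r} lacks an up/down label")
        if a == b:
            same += 1
        else:
            opp += 1
    n = same + opp
    if n == 0:
        return 0, 0, float("nan")
    p = float(stats.binomtest(opp, n, 0.5, alternative="two-sided").pvalue)
    return same, opp, p
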
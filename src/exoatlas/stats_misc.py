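"""Small self-contained statistics: gene-set enrichment and RWC.

``module_enrichment`` tests whether a co-expression module is enriched
in a target gene set within a stated universe, using Fisher's exact
test on the 2x2 membership table and the sample (cross-product) odds
ratio.  ``relative_water_content`` is the standard leaf water status
formula RWC (%) = (TFW - DW) * 100 / (TW - DW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats


@dataclass
class EnrichmentResult:
    """2x2 enrichment table with odds ratio and two-sided Fisher p."""

    a: int  # module & target
    b: int  # module only
    c: int  # target only
    d: int  # neither
    odds_ratio: float
    p: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def table(self):
        return np.array([[self.a, self.b], [self.c, self.d]])


def module_enrichment(module, target, universe) -> EnrichmentResult:
    """Fisher's exact enrichment of ``module`` in ``target`` over ``universe``.

    Both gene lists must be subsets of the universe.  The odds ratio is
    the sample estimate (a*d)/(b*c), infinite when b*c = 0 and a*d > 0.
    The p-value is the two-sided Fisher exact probability (sum of
    hypergeometric point probabilities no larger than the observed
    table's).
    """
    mod, tgt, uni = set(module), set(target), set(universe)
    for name, s in (("module", mod), ("target", tgt)):
        extra = s - uni
        if extra:
            raise ValueError(
                f"{name} genes outside the universe: {sorted(extra)[:10]}"
            )
    a = len(mod & tgt)
    b = len(mod - tgt)
    c = len(tgt - mod)
    d = len(uni) - a - b - c

    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(a=a, b=b, c=c, d=d, odds_ratio=float(odds), p=float(p))


def relative_water_content(tfw: float, tw: float, dw: float) -> float:
    """RWC (%) = (TFW - DW) * 100 / (TW - DW); requires TW > DW."""
    if tw <= dw:
        raise ValueError("turgid weight must exceed dry weight")
    return (tfw - dw) * 100.0 / (tw - dw)
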
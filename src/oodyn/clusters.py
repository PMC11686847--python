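"""The nine maternal-transcript trajectory categories over GV → MII → D3.

A transcript's trajectory is summarised by its status at each of the two
stage transitions (GV→MII, MII→D3): ``degraded`` (down by at least the
fold-change threshold), ``elevated`` (up by at least the threshold), or
``stable``.  The 3 × 3 truth table of the two statuses defines clusters
I–IX.  Signed steps use -1 for degraded, 0 for stable, +1 for elevated.
"""

from __future__ import annotations

CLUSTERS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")

#: cluster -> (signed GV→MII step, signed MII→D3 step)
CLUSTER_STEPS: dict[str, tuple[int, int]] = {
    "I": (-1, 0),    # degraded during maturation, stable post-fertilisation
    "II": (0, -1),   # stable during maturation, degraded in day-3 embryos
    "III": (-1, -1), # continuous degradation
    "IV": (0, 0),    # stable throughout
    "V": (1, 0),     # elevated during maturation, then stable
    "VI": (0, 1),    # stable, then elevated post-fertilisation (ZGA)
    "VII": (1, 1),   # consistently elevated
    "VIII": (-1, 1), # degraded during maturation, elevated post-fertilisation
    "IX": (1, -1),   # elevated during maturation, degraded post-fertilisation
}

_SIGN_TO_STATUS = {-1: "degraded", 0: "stable", 1: "elevated"}

#: (status at GV→MII, status at MII→D3) -> cluster label
STATUS_TO_CLUSTER: dict[tuple[str, str], str] = {
    (_SIGN_TO_STATUS[s1], _SIGN_TO_STATUS[s2]): c
    for c, (s1, s2) in CLUSTER_STEPS.items()
}
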
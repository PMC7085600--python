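"""Longest-common-subsequence matching between observed segments and templates.

LCS length is computed bottom-up over the classic (m+1) x (n+1) dynamic
programming matrix.  Because a subsequence may skip symbols, LCS tolerates
the speed-dependent stretching of the symbol runs: a slow throw and a fast
throw of the same action differ only in run lengths, and both score high
against the same template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .templates import StepTemplate


def lcs_matrix(a: str, b: str) -> np.ndarray:
    """Full DP matrix of LCS lengths; cell (m, n) is the LCS of a and b.

    Row 0 and column 0 are zero; ``M[i, j] = M[i-1, j-1] + 1`` when
    ``a[i-1] == b[j-1]`` and ``max(M[i-1, j], M[i, j-1])`` otherwise.
    """
    m, n = len(a), len(b)
    mat = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        ai = a[i - 1]
        prev = mat[i - 1]
        row = mat[i]
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                row[j] = prev[j - 1] + 1
            else:
                pj = prev[j]
                rj = row[j - 1]
                row[j] = pj if pj >= rj else rj
    return mat


def lcs_length(a: str, b: str) -> int:
    """LCS length via a lean two-row sweep of the same recursion."""
    if not a or not b:
        return 0
    # iterate over the shorter string's rows
    if len(b) > len(a):
        a, b = b, a
    prev = [0] * (len(b) + 1)
    cur = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                pj = prev[j]
                cj = cur[j - 1]
                cur[j] = pj if pj >= cj else cj
        prev, cur = cur, prev
    return prev[-1]


@dataclass(frozen=True)
class SimilarityScore:
    """LCS length normalized by the template length."""

    lcs_len: int
    template_len: int

    @property
    def ratio(self) -> float:
        return self.lcs_len / self.template_len


def similarity(segment: str, template_expanded: str) -> SimilarityScore:
    """Score a segment against a concrete (already expanded) template string."""
    if not template_expanded:
        raise ValueError("template must be non-empty")
    return SimilarityScore(lcs_length(segment, template_expanded), len(template_expanded))


def expand_classes(classes: Sequence[str], segment: str) -> str:
    """Expand an ordered class list against an observed segment.

    When every class occurs in the segment, each class is repeated as often
    as its symbol occurs, so the score measures how much of the segment's
    template-alphabet content appears in the right order — foreign symbols
    (filter transits, noise glitches) are simply unmatched, which is the
    stretch- and outlier-tolerance LCS is chosen for, and the ratio is
    independent of throwing speed.  When a class is absent the expansion
    falls back to an even split of the full segment length, capping the
    achievable ratio well below 1 — absence is what the score must punish.
    """
    n = len(segment)
    k = len(classes)
    if n == 0 or k == 0:
        return ""
    counts = [segment.count(c) for c in classes]
    if min(counts) == 0:
        shares = [n // k] * k
        for i in range(n - sum(shares)):
            shares[i] += 1
        return "".join(c * s for c, s in zip(classes, shares))
    return "".join(c * s for c, s in zip(classes, counts))


def class_similarity(segment: str, classes: Sequence[str]) -> SimilarityScore:
    """Similarity of a segment against an ordered class list.

    A cheap alphabet screen runs first: if none of the template's classes
    occurs in the segment at all, the DP is skipped and the score is zero —
    sequences that do not conform to the database are not worth aligning.
    """
    expanded = expand_classes(classes, segment)
    if not expanded:
        return SimilarityScore(0, max(1, len(segment) or 1))
    if not any(c in segment for c in classes):
        return SimilarityScore(0, len(expanded))
    return similarity(segment, expanded)


def match_step(pair_segment, tmpl: StepTemplate, theta: float = 0.7) -> bool:
    """Dual-channel template match: both channels must reach ``theta``.

    ``pair_segment`` is a ThrowSequencePair (or any object with ``forearm``
    and ``upper`` strings) covering one candidate window; the template's
    classes are taken in temporal order and expanded to the segment length
    on each channel.  The step is recognized only when the forearm and the
    upper arm simultaneously meet the threshold.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    f = class_similarity(pair_segment.forearm, tmpl.temporal_forearm)
    if f.ratio < theta:
        return False
    u = class_similarity(pair_segment.upper, tmpl.temporal_upper)
    return u.ratio >= theta
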
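"""Order-sensitive word-report scoring.

A reported word counts as correct only when it matches a target word exactly
(no credit for morphological variants) and appears in the same relative order
as in the target; intervening omissions are allowed. This is precisely the
longest common subsequence (LCS) between target and response token lists,
optionally under a homophone equivalence map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["ReportScore", "normalize_tokens", "score_report"]

_TOKEN_RE = re.compile(r"[a-z0-9']+")


@dataclass(frozen=True)
class ReportScore:
    n_correct: int
    n_total: int
    matched_positions: tuple = field(default_factory=tuple)

    @property
    def proportion(self) -> float:
        return self.n_correct / self.n_total


def normalize_tokens(text: str) -> list[str]:
    """Lower-case, strip punctuation and split on whitespace.

    Internal apostrophes are retained (``"it's" -> ["it's"]``); leading and
    trailing apostrophes are stripped.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    return [t.strip("'") for t in tokens if t.strip("'")]


def _equivalent(a: str, b: str, homophones: dict | None) -> bool:
    if a == b:
        return True
    if homophones is None:
        return False
    # map each token to a canonical form; tokens sharing a canonical form match
    return homophones.get(a, a) == homophones.get(b, b)


def score_report(target, response, homophones: dict | None = None) -> ReportScore:
    """Score a word report against its target sentence.

    Parameters
    ----------
    target, response
        Token lists (see :func:`normalize_tokens`).
    homophones
        Optional map from token to canonical form; tokens with the same
        canonical form are treated as equal (homonyms score as correct).

    Returns
    -------
    ReportScore
        ``n_correct`` is the LCS length, ``n_total`` the target length and
        ``matched_positions`` the (target_index, response_index) pairs of one
        maximal order-preserving matching.
    """
    target = list(target)
    response = list(response)
    if not target:
        raise ValueError("target must be non-empty")
    nt, nr = len(target), len(response)
    # standard LCS dynamic programme
    dp = [[0] * (nr + 1) for _ in range(nt + 1)]
    for i in range(1, nt + 1):
        row, prev = dp[i], dp[i - 1]
        ti = target[i - 1]
        for j in range(1, nr + 1):
            if _equivalent(ti, response[j - 1], homophones):
                row[j] = prev[j - 1] + 1
            else:
                row[j] = max(prev[j], row[j - 1])
    # backtrack one optimal alignment
    pairs = []
    i, j = nt, nr
    while i > 0 and j > 0:
        if _equivalent(target[i - 1], response[j - 1], homophones) \
                and dp[i][j] == dp[i - 1][j - 1] + 1:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif dp[i - 1][j] >= dp[i][j - 1]:
            i -= 1
        else:
            j -= 1
    return ReportScore(n_correct=dp[nt][nr], n_total=nt,
                       matched_positions=tuple(reversed(pairs)))
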
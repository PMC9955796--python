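"""Independent reference implementations used only as test oracles.

These deliberately take a different route from the package code: the
pattern oracle translates pattern *text* straight to a Python regex, and
the clustering oracle is a naive O(n^3) agglomerative loop over explicit
member sets.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "ACFILMVW"

_TOKEN = re.compile(r"\[([^\]]*)\]|X|Φ|([A-Z])|-")
_REPEAT = re.compile(r"\((\d+)\)")


def pattern_text_to_regex(text: str, hydrophobic: str = HYDROPHOBIC) -> re.Pattern:
    """Translate extended-PROSITE pattern text directly to a lookahead regex."""
    pos = 0
    parts: list[str] = []
    while pos < len(text):
        ch = text[pos]
        if ch == "-":
            pos += 1
            continue
        if ch == "[":
            close = text.index("]", pos)
            body = text[pos + 1 : close]
            residues = set()
            for c in body:
                residues |= set(hydrophobic) if c == "Φ" else {c}
            piece = "[" + "".join(sorted(residues)) + "]"
            pos = close + 1
        elif ch == "X":
            piece = "[" + AA + "]"
            pos += 1
        elif ch == "Φ":
            piece = "[" + "".join(sorted(set(hydrophobic))) + "]"
            pos += 1
        else:
            piece = ch
            pos += 1
        m = _REPEAT.match(text, pos)
        if m:
            piece = piece + "{" + m.group(1) + "}"
            pos = m.end()
        parts.append(piece)
    return re.compile("(?=(" + "".join(parts) + "))")


def regex_match_starts(sequence: str, matcher: re.Pattern) -> list[int]:
    """1-based start positions of all (overlapping) matches."""
    return [m.start() + 1 for m in matcher.finditer(sequence)]


def brute_force_complete_linkage(values: np.ndarray):
    """Naive agglomerative clustering, Euclidean metric, complete linkage.

    Returns a list of merges [(members_a, members_b, height)] with members
    given as frozensets of leaf indices; ties broken by the lowest pair of
    cluster creation indices.
    """
    n = values.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(
                np.linalg.norm(values[i] - values[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges
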
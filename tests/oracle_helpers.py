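"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: distances come from a
full matrix, votes from collections.Counter, AUC from exhaustive pair
enumeration.
"""

from collections import Counter

import numpy as np


def brute_force_consensus(ref, labels, query, k, min_votes):
    """Full-distance-matrix k-NN vote counter.

    Returns (assigned_label_or_None, vote_count_dict, n_match) per query row.
    Ties in distance break by ascending reference index; a label is assigned
    only when it uniquely holds the maximal vote count and that count reaches
    min_votes.
    """
    ref = np.asarray(ref, float)
    query = np.asarray(query, float)
    labels = list(labels)
    out = []
    for q in query:
        d2 = ((ref - q) ** 2).sum(axis=1)
        order = sorted(range(len(ref)), key=lambda i: (d2[i], i))[:k]
        votes = Counter(labels[i] for i in order)
        top = max(votes.values())
        winners = [lab for lab, c in votes.items() if c == top]
        if top >= min_votes and len(winners) == 1:
            out.append((winners[0], dict(votes), top))
        else:
            out.append((None, dict(votes), top))
    return out


def exhaustive_auc(scores, outcome):
    """AUC by enumerating every (positive, negative) pair."""
    scores = np.asarray(scores, float)
    outcome = np.asarray(outcome, int)
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))
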
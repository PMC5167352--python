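"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a quantity by a different route than the package:
exhaustive enumeration for the classification rule, replicate-expansion
weighting for the stratified estimator, and the tie-corrected rank
statistic for the AUC.
"""

import itertools

import numpy as np
from scipy.stats import rankdata

from handscreen.frascati import FRASCATI_DOMAINS


def oracle_hand_label(tests, symptomatic, fail=-1.0, severe=-2.0):
    """Exhaustive subset/assignment evaluation of the diagnostic rules.

    *tests* is a sequence of objects with ``z`` and ``domains``.  For each
    threshold, enumerate every pair of failed tests and every assignment
    of one (Frascati) domain per test; the rule is met iff some assignment
    uses two distinct domains.
    """

    def rule_met(threshold):
        failed = [t for t in tests if t.z <= threshold]
        for a, b in itertools.combinations(failed, 2):
            for da, db in itertools.product(a.domains, b.domains):
                if (
                    da != db
                    and da in FRASCATI_DOMAINS
                    and db in FRASCATI_DOMAINS
                ):
                    return True
        return False

    if rule_met(severe):
        return "HAD"
    if rule_met(fail):
        return "MND" if symptomatic else "ANI"
    return "NCN"


def oracle_weighted_prevalence(strata, subtype=None):
    """Replicate-expansion estimate: each evaluated record stands for
    n_i/m_i screened participants; the estimate is the weighted case mass
    over the total weight (= N)."""
    case_weight = 0.0
    total_weight = 0.0
    for s in strata:
        total_weight += s.n_screened
        if s.m_evaluated == 0:
            continue
        w = s.n_screened / s.m_evaluated
        if subtype is None:
            e = sum(s.cases.values())
        else:
            e = s.cases.get(subtype, 0)
        case_weight += e * w
    return case_weight / total_weight


def oracle_auc(scores, labels):
    """Tie-corrected Mann-Whitney AUC with positivity = low score.

    AUC = P(score_diseased < score_healthy) + 0.5 P(equal), computed from
    mid-ranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    ranks = rankdata(s)  # average ranks handle ties
    r_neg = ranks[~y].sum()
    u = r_neg - n_neg * (n_neg + 1) / 2
    return u / (n_pos * n_neg)
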
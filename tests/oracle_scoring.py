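"""Independent brute-force evaluation of the weighted benefit score.

Deliberately written from the verbal rules alone -- raw response states in,
plain Python arithmetic out -- so it shares no code path with the package
implementation it is used to check.
"""

import math

NA = "NA"          # the "does/did not apply" answer
MISS = None        # an unanswered cell


def brute_force_pbi(imp_states, ben_states, items):
    """Return (value | None, n_items_used, denominator).

    ``imp_states`` / ``ben_states`` are per-item raw answers: an int 0-4,
    NA, or MISS.  Importance NA counts as 0; benefit NA counts as missing.
    An item contributes only when both recoded values are observed; the
    score needs at least half the item set (rounded up) to contribute and
    a positive summed importance.
    """
    num = 0.0
    den = 0.0
    used = 0
    for item_id in items:
        raw_imp = imp_states[item_id - 1]
        raw_ben = ben_states[item_id - 1]
        imp = 0 if raw_imp == NA else raw_imp
        ben = MISS if raw_ben == NA else raw_ben
        if imp is MISS or ben is MISS:
            continue
        num += imp * ben
        den += imp
        used += 1
    if used < math.ceil(len(list(items)) / 2) or den == 0:
        return None, used, den
    return num / den, used, den
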
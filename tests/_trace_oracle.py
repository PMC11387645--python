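"""Independent step-by-step trace of the hybrid model for oracle checks.

Deliberately written with plain Python floats and dicts, composing the
update equations one literal step at a time, so it shares no code with the
package's vectorized/compiled likelihood path.
"""

import math


def trace_loglik(alpha, lam, beta, w, pi, rho, trials, p_common, scale):
    """Return (total_loglik, per-trial records) for a list of
    (a1, s2, a2, points) tuples; s2 is 1 (state B) or 2 (state C).

    Stage-1 response keys coincide with action identities (fixed stimulus
    positions), so the rep and resp indicators agree.
    """
    q = {(s, a): 0.0 for s in (0, 1, 2) for a in (0, 1)}
    prev_choice = None
    total = 0.0
    records = []
    for (a1, s2, a2, points) in trials:
        r = points * scale
        best_b = max(q[(1, 0)], q[(1, 1)])
        best_c = max(q[(2, 0)], q[(2, 1)])
        q_mb = {0: p_common * best_b + (1.0 - p_common) * best_c,
                1: (1.0 - p_common) * best_b + p_common * best_c}
        u = {}
        for a in (0, 1):
            q_net = w * q_mb[a] + (1.0 - w) * q[(0, a)]
            rep = 1.0 if prev_choice == a else 0.0
            u[a] = beta * (q_net + pi * rep + rho * rep)
        ll1 = u[a1] - math.log(math.exp(u[0]) + math.exp(u[1]))
        v = {a: beta * q[(s2, a)] for a in (0, 1)}
        ll2 = v[a2] - math.log(math.exp(v[0]) + math.exp(v[1]))
        delta1 = q[(s2, a2)] - q[(0, a1)]
        delta2 = r - q[(s2, a2)]
        q[(0, a1)] = q[(0, a1)] + alpha * delta1 + alpha * lam * delta2
        q[(s2, a2)] = q[(s2, a2)] + alpha * delta2
        total += ll1 + ll2
        records.append({"ll1": ll1, "ll2": ll2, "delta1": delta1, "delta2": delta2})
        prev_choice = a1
    return total, records
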
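"""Independent brute-force oracle for the entropy scores.

Deliberately naive: pure-Python loops, ``math.fsum``, straight transcription
of the definitions. Kept free of any import from the package under test so
it can never inherit its bugs.
"""

import math


def oracle_scores(x, blocks):
    """Entropy decomposition and scores for one gene.

    ``x`` is a list of nonnegative per-cell values, ``blocks`` a list of
    index lists covering every cell exactly once.
    """
    total = math.fsum(x)
    assert total > 0
    p = [v / total for v in x]
    e_t = -math.fsum(pi * math.log(pi) for pi in p if pi > 0)

    p_c, e_c = [], []
    for block in blocks:
        s = math.fsum(x[i] for i in block)
        p_c.append(s / total)
        if s > 0:
            q = [x[i] / s for i in block]
            e_c.append(-math.fsum(qi * math.log(qi) for qi in q if qi > 0))
        else:
            e_c.append(0.0)
    e_w = math.fsum(pc * ec for pc, ec in zip(p_c, e_c))
    e_b = e_t - e_w

    r = len(blocks)
    out = {"e_t": e_t, "e_b": e_b, "e_w": e_w, "p_c": p_c, "e_c": e_c}
    if e_t == 0:
        out.update(psi=None, psi_blocks=None, zeta=None)
        return out
    if e_w == 0:
        psi = 0.0
        comp = list(p_c)
    else:
        psi = e_w / e_t
        comp = [pc * ec / e_w for pc, ec in zip(p_c, e_c)]
    h = -math.fsum(c * math.log(c) for c in comp if c > 0)
    out.update(psi=psi, psi_blocks=comp, zeta=1.0 - h / math.log(r))
    return out
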
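"""Independent oracle computations shared across test modules."""

import math

import pvcausal as pv


def true_model_probs(reports, gen) -> pv.ProbabilityTable:
    """Exact endpoint probabilities from the generating logistic model,
    bypassing any fitted classifier."""
    probs = {}
    for r in reports:
        logit = gen.intercept
        for (f, t), eff in gen.effects.items():
            if t in r.terms(f):
                logit += eff
        for ((f1, t1), (f2, t2)), eff in gen.interaction_effects.items():
            if t1 in r.terms(f1) and t2 in r.terms(f2):
                logit += eff
        probs[r.report_id] = 1.0 / (1.0 + math.exp(-logit))
    return pv.ProbabilityTable(probs)
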
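"""Independent literal transcription of the moisture-retention regressions.

Written against the published equation table, scalar ``math`` arithmetic
only, term-by-term in the printed order, kept deliberately separate from
the package implementation so it can serve as an oracle in tests.
Inputs: S and C as decimal fractions, OM in mass %.
"""

import math


def oracle_theta1500(S, C, OM):
    theta1500t = (-0.024 * S + 0.487 * C + 0.006 * OM
                  + 0.005 * (S * OM) - 0.013 * (C * OM)
                  + 0.068 * (S * C) + 0.031)
    return theta1500t + (0.14 * theta1500t - 0.02)


def oracle_theta33(S, C, OM):
    theta33t = (-0.251 * S + 0.195 * C + 0.011 * OM
                + 0.006 * (S * OM) - 0.027 * (C * OM)
                + 0.452 * (S * C) + 0.299)
    return theta33t + (1.283 * (theta33t) ** 2 - 0.374 * theta33t - 0.015)


def oracle_thetaS33(S, C, OM):
    t = (0.278 * S + 0.034 * C + 0.022 * OM
         - 0.018 * (S * OM) - 0.027 * (C * OM)
         - 0.584 * (S * C) + 0.078)
    return t + (0.636 * t - 0.107)


def oracle_thetaS(S, C, OM):
    return oracle_theta33(S, C, OM) + oracle_thetaS33(S, C, OM) - 0.097 * S + 0.043


def oracle_B(theta33, theta1500):
    return (math.log(1500.0) - math.log(33.0)) / (math.log(theta33) - math.log(theta1500))


def oracle_lambda(theta33, theta1500):
    return 1.0 / oracle_B(theta33, theta1500)


def oracle_KS(theta1500, theta33, thetaS):
    lam = oracle_lambda(theta33, theta1500)
    return 1930.0 * (thetaS - theta33) ** (3.0 - lam)
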
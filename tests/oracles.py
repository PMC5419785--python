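"""Independent scalar oracles for curve evaluation.

Coded from the formulas with python's math module only — deliberately
sharing no code with the package's vectorized evaluator.
"""

import math


def double_logistic(params, x):
    a, b, c, d = params
    return 1.0 / (1.0 + math.exp(-a * (x - b))) - 1.0 / (
        1.0 + math.exp(-c * (x - d))
    )


def cubic(params, x):
    a, b, c, d = params
    return a + b * x + c * x * x + d * x * x * x


def rational_quad(params, x):
    a, b, c, d = params
    return (a + b * x) / (c * x + d * x * x + 1.0)


def rational_power(params, x):
    a, b, c, d = params
    xd = x**d
    return (a * b + c * xd) / (b + xd)


def logistic3(params, x):
    a, b, c = params
    return a / (1.0 + b * math.exp(-c * x))


ORACLES = {
    "double_logistic": double_logistic,
    "cubic": cubic,
    "rational_quad": rational_quad,
    "rational_power": rational_power,
    "logistic3": logistic3,
}
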
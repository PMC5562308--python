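"""Independent brute-force oracles used by the tests.

These are written against the defining integrals / mass balances, not
against the package's implementation paths, so they can serve as
cross-checks.
"""

import numpy as np
from scipy.integrate import quad

from cuaging.isotope import AM_CU_65, AM_CU_NAT, IR_NAT_DEFAULT, IR_SP_DEFAULT


def scaled_erfc_oracle(x):
    """Quadrature oracle for S(x) = exp(x)·erfc(sqrt(x)).

    Substituting t = sqrt(x) + u in erfc's defining integral gives
    S(x) = 2/sqrt(pi) * int_0^inf exp(-2*sqrt(x)*u - u^2) du, which stays
    finite for arbitrarily large x.
    """
    z = np.sqrt(x)
    val, _ = quad(lambda u: np.exp(-2.0 * z * u - u * u), 0.0, np.inf)
    return 2.0 / np.sqrt(np.pi) * val


def forward_ir_meas(e_star, spike_total, ir_nat=IR_NAT_DEFAULT, ir_sp=IR_SP_DEFAULT):
    """Forward two-pool isotope mixing: the 63/65 ratio measured in solution.

    An exchangeable pool of ``e_star`` mg/kg natural-composition Cu mixes
    with ``spike_total`` mg/kg of 65Cu carrying a 63/65 ratio ``ir_sp``;
    amounts are tracked isotope by isotope.
    """
    n65_spike = spike_total / AM_CU_65
    n63_spike = ir_sp * n65_spike
    n_nat = e_star / AM_CU_NAT
    n65_nat = n_nat / (1.0 + ir_nat)
    n63_nat = n_nat * ir_nat / (1.0 + ir_nat)
    return (n63_nat + n63_spike) / (n65_nat + n65_spike)
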
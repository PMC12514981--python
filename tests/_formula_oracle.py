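"""Independent direct-arithmetic oracle for the lens-feature formulas.

Coded straight from the algebra, without importing the package, so the tests
can check the implementation against a second, independently written route.
Scalar-only on purpose.
"""

import math


def corneal_radius(km):
    return 337.5 / km


def lopt(al):
    return al + 0.65696 - 0.02029 * al


def iol_emmetropia(al, acd, r, na=1.336, dn=0.333):
    L = lopt(al)
    return 1000.0 * na * (na * r - dn * L) / ((L - acd) * (na * r - dn * acd))


def iol_myopia(al, acd, r, se, na=1.336, dn=0.333):
    L = lopt(al)
    A = na * r - dn * L
    num = 1000.0 * na * (A - 0.001 * se * (12.0 * A + L * r))
    den = (L - acd) * (na * r - dn * acd - 0.001 * se * (12.0 * A + acd * r))
    return num / den


def contact_lens_power(se):
    return se / (1.0 - 0.012 * se)


def corrected_corneal_radius_cl(km, fc):
    return 337.5 / (km + fc)


def iol_contact_lens(al, acd, km, se):
    return iol_emmetropia(al, acd, corrected_corneal_radius_cl(km, contact_lens_power(se)))


def anterior_surface_power(f_total, lt, fp=9.26, n_lens=1.40):
    return (f_total - fp) / (1.0 - (lt / 1000.0 / n_lens) * fp)


def thick_lens_total(fa, fp, lt, n_lens=1.40):
    return fa + fp - (lt / 1000.0 / n_lens) * fa * fp


def anterior_radius(fa, n_lens=1.40, na=1.336):
    return 1000.0 * (n_lens - na) / fa


def power_vectors(c, axis_deg):
    two_alpha = math.radians(2.0 * axis_deg)
    return -c / 2.0 * math.cos(two_alpha), -c / 2.0 * math.sin(two_alpha)


def spherical_equivalent(s, c):
    return s + c / 2.0
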
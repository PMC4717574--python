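"""Closed-form assortative-mating theory for a standardized trait.

Under the ante-dependence model A_i -> P_i -> P_partner (one's additive
genetic value affects one's phenotype, which drives the partner's
phenotype), the partner's phenotype is P_m = b P_i + E_m with b = r_p for
standardized traits, so

* the expected heritability of "partner's phenotype" treated as one's own
  trait is h_Pm^2 = r_p^2 h^2;
* the expected correlation of breeding values among mates is m = r_p h^2;
* at equilibrium, removing the directional-disequilibrium contribution of
  assortment (V_A0 = (1 - m) V_A,eq with constant environmental variance)
  gives the random-mating heritability h0^2 = h^2 (1 - m) / (1 - m h^2).

Note on the h0^2 denominator: with equilibrium phenotypic variance
normalized to 1, V_A0 = h^2 (1 - m) and V_E = 1 - h^2 give
h0^2 = V_A0 / (V_A0 + V_E) = h^2 (1 - m) / (1 - m h^2).  A (1 + m h^2)
denominator is sometimes quoted but is inconsistent with this variance
accounting (it would give 0.55 rather than 0.76 at h^2 = 0.8, m = 0.2);
this module uses the variance-accounting form.
"""

from __future__ import annotations

from .exceptions import ConfigError

__all__ = [
    "expected_mate_choice_h2",
    "random_mating_h2",
    "heritability_increase_pct",
    "expected_breeding_value_correlation",
    "theory_table",
]


def _check_unit(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ConfigError(f"{name} = {value} outside [{lo}, {hi}]")


def expected_mate_choice_h2(r_p: float, h2: float) -> float:
    """Expected heritability of the partner's phenotype, r_p^2 h^2."""
    _check_unit("r_p", abs(r_p))
    _check_unit("h2", h2)
    return r_p**2 * h2


def random_mating_h2(h2: float, m: float) -> float:
    """Heritability under random mating implied by the equilibrium h^2.

    h0^2 = h^2 (1 - m) / (1 - m h^2), the disequilibrium-removal form
    (see module docstring): the additive variance loses its fraction m of
    between-locus coupling, the environmental variance is unchanged.
    """
    _check_unit("h2", h2)
    if not (0.0 <= m < 1.0):
        raise ConfigError(f"m = {m} outside [0, 1)")
    return h2 * (1.0 - m) / (1.0 - m * h2)


def heritability_increase_pct(h2_eq: float, h2_random: float) -> float:
    """Percent increase of equilibrium over random-mating heritability."""
    if h2_random <= 0.0:
        raise ConfigError("h2_random must be positive")
    return 100.0 * (h2_eq - h2_random) / h2_random


def expected_breeding_value_correlation(r_p: float, h2: float) -> float:
    """Expected correlation of mates' breeding values, m = r_p h^2."""
    _check_unit("r_p", abs(r_p))
    _check_unit("h2", h2)
    return r_p * h2


def theory_table(h2: float, r_p: float, m: float = None) -> dict:
    """The four theory scalars for given (h^2, r_p[, m]); m defaults to r_p h^2."""
    if m is None:
        m = expected_breeding_value_correlation(r_p, h2)
    h2_rand = random_mating_h2(h2, m)
    return {
        "expected_mate_choice_h2": expected_mate_choice_h2(r_p, h2),
        "expected_breeding_value_correlation": m,
        "random_mating_h2": h2_rand,
        "heritability_increase_pct": heritability_increase_pct(h2, h2_rand),
    }
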